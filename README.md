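# circatx — circadian transcriptome analysis toolkit

`circatx` is a Python library for analysing diurnal (24-h) gene-expression
time courses and the physiology recorded alongside them.  It is aimed at
chronobiology and endocrinology groups who profile a tissue every few hours
across the day in two or more treatment groups — for example control,
hormone-depleted and hormone-treated animals — and need to answer, gene by
gene:

* **Is it rhythmic?**  Nonparametric JTK-style screening with an exact
  rank-statistic null, plus parametric cosinor regression.
* **How does the rhythm differ between groups?**  Joint two-group cosinor
  fits that estimate and test differences in mesor (rhythm-adjusted mean),
  amplitude, and peak phase.
* **Which genes are differentially expressed?**  Global, per-timepoint and
  *robust* (consistent at every timepoint) differential expression with a
  dual FDR + fold-change gate.
* **Which genes report hormone state?**  A "tuning gene" biomarker panel:
  genes whose mesor moves in opposite directions under low- and
  high-hormone states, rankable by effect size and testable for
  pathway over-representation.

A first-class synthetic-data generator plants known mesor/amplitude/phase
effects so every claim the toolkit makes can be verified against ground
truth — sensitivity, false-discovery rate, estimator bias and confidence
interval coverage are all measured, not assumed.

## The model

Expression of gene *g* in group *j* at Zeitgeber time *t* (hours after
lights-on) is modelled as

```
y(t) = M + A·cos(2π(t − φ)/τ) + ε,   ε ~ N(0, σ²),  τ = 24 h
```

with mesor *M*, amplitude *A* ≥ 0 and acrophase *φ* ∈ [0, 24).  Single-group
fits use the linearisation `y ~ 1 + sin(2πt/24) + cos(2πt/24)`; rhythmicity
is the joint F-test of the sine/cosine terms.  Two groups are compared with
the joint nonlinear model

```
y = (k + k₁G) + (α + α₁G)·cos(2π(t − φ − φ₁G)/24),   G ∈ {0, 1}
```

so `k₁`, `α₁`, `φ₁` are the between-group differences, tested by Wald
t-statistics.  `φ₁` is wrapped to (−12, 12] (positive = delay) and is only
tested when the gene is rhythmic in *both* groups.

The nonparametric screen correlates each gene's values with lagged
reference cosines via Kendall's S, using the exact Jonckheere–Terpstra
permutation null (dynamic-programming convolution of Mann–Whitney blocks)
for replicated, tied designs.

## Worked example

`examples/` contains one narrative script per capability.  For instance,
`python examples/02_rhythm_screen.py` simulates 400 genes (30% rhythmic) at
the default design — 3 groups, ZT 2/6/10/14/18/22, n = 4 — screens the
control group and prints:

```
rhythmic at adj-p < 0.05: 121 / 400 genes
  sensitivity on truly rhythmic genes: 1.000
  false calls among flat genes: 0.004
```

121 genes pass the BH-adjusted 0.05 cutoff; all truly rhythmic genes are
found and essentially no flat gene is miscalled.  And
`python examples/04_differential_expression.py` prints the per-scope DEG
tally for a planted-shift comparison:

```
   scope  n_significant  n_up  n_down
  global             30  15.0    15.0
temporal             30   NaN     NaN
  robust             23   NaN     NaN
planted shifts recovered globally: 30 / 30
```

All 30 planted shifts are recovered globally (FDR < 0.1 and ≥ 1.5-fold);
23 of them are additionally *robust* — significant with the same direction
at every single timepoint, the behaviour wanted of a sampling-time-free
marker.

The other examples cover simulation (`01`), differential rhythm and mean
phase shifts (`03`), tuning-panel selection and ranking (`05`),
over-representation analysis (`06`) and telemetry/calorimetry utilities
(`07`).  A thin CLI (`circatx simulate|rhythm|cosinor|compare|deg|run-all`)
wraps the same functions for shell use.

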