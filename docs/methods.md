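# Methods

This note documents the statistical models, the numerical choices, and what
the synthetic-data tests do and do not demonstrate.

## Rhythm model and cosinor estimation

All rhythm analysis fixes the period at τ = 24 h and models a gene's log2
expression as `y(t) = M + A·cos(2π(t−φ)/τ) + ε` with Gaussian noise.  Time
is Zeitgeber time (ZT): hours after lights-on in a 12:12 light–dark cycle,
half-open on [0, 24).  Phases and phase differences computed internally are
wrapped modulo the period; user-supplied sample sheets must already satisfy
0 ≤ ZT < 24 and are rejected otherwise rather than silently folded.

`fit_cosinor` solves the linearised model `y ~ 1 + sin(2πt/τ) + cos(2πt/τ)`
by least squares.  With coefficients (β_s, β_c), the amplitude is
`A = √(β_s² + β_c²)` (non-negative by construction: a sign flip of the
waveform appears as a half-period phase shift, never as negative A) and the
acrophase is `φ = (τ/2π)·atan2(β_s, β_c) mod τ`, the clock time of the
fitted maximum.  Rhythmicity is the exact F-test of β_s = β_c = 0.
Standard errors for A and φ come from the delta method; when Â ≈ 0 the
phase is non-identifiable, its SE is reported as infinite, and the fit is
flagged.  A perfect (zero-residual) fit reports the smallest representable
p with an `exact_fit` flag instead of dividing by zero.  The fit requires
≥ 4 observations on ≥ 3 distinct times; missing values are dropped
pairwise, so unbalanced designs (e.g. discarded low-quality arrays) are
handled without imputation.

## Two-group differential rhythm

`compare_rhythms` fits the joint nonlinear model
`y = (k + k₁G) + (α + α₁G)·cos(2π(t − φ − φ₁G)/τ)` over the pooled data of
both groups (G = 0/1), by Levenberg–Marquardt least squares initialised
analytically from the two per-group linear fits.  Because that
initialisation is the exact solution of the separable problem, convergence
is immediate in practice; as a safety net up to 8 restarts jitter the
reference phase by τ/8, and a non-converged gene is returned flagged with
its per-group fits retained rather than silently dropped.

Wald tests (estimate / asymptotic SE against a t reference with n − 6
degrees of freedom, six model parameters) give p-values for the mesor
difference k₁, amplitude difference α₁ and phase difference φ₁.  Mesor and
amplitude are estimated and tested for every gene irrespective of
rhythmicity; the phase difference — wrapped to (−12, 12], positive = the
second group peaks later — is only reported when both groups are
individually rhythmic at the gating α (default 0.05, the per-group F-test),
because the phase of an arrhythmic profile is meaningless.  No multiplicity
correction is applied to the three difference p-values by default; an
optional BH flag exists at the batch level.  Simulation at the default
design (below) shows the estimators unbiased (< 2% bias at effects
k₁ = 0.5, α₁ = −0.3, φ₁ = 2 h, σ = 0.3) with 95% Wald intervals covering
at 0.95 ± 0.02.

`mean_phase_shift` averages wrapped phase differences over the
phase-comparable genes and tests the mean against zero with a one-sample
t-test; an all-identical input (zero variance) is reported at the p = 0 or
p = 1 boundary with an exactness flag.  At very low signal-to-noise the
±12 h wrapping attenuates individual estimates toward zero, so the mean
shift of a weakly rhythmic set is a conservative estimate.

## Nonparametric rhythmicity screen

The JTK-style screen correlates each gene with reference cosines of fixed
24-h period at every lag on the sampling grid (lag step = the sampling
interval, inferred from the data unless given).  For one lag, Kendall's S
is computed between the observed values and the reference ordering;
replicates within a timepoint — and distinct timepoints whose reference
values coincide, which happens on symmetric grids — are tied in the
reference and contribute nothing.  The null distribution of S under random
ordering is computed exactly for designs up to 30 observations as the
convolution of Mann–Whitney U blocks (the classical q-binomial
factorisation of the Jonckheere–Terpstra statistic), verified in the tests
against exhaustive permutation enumeration; larger designs use a
tie-corrected, continuity-corrected normal approximation.

Per-lag p-values are two-sided.  A lag and its half-period mirror produce
the identical two-sided test (the reference ordering reverses and S changes
sign), so a full-period scan of L lags contains only L/2 distinct tests;
the per-gene p-value is the minimal per-lag p Bonferroni-corrected by that
count.  Measured on one million simulated null genes at the default design,
the rejection rate at raw p < 0.05 is 0.040 — slightly conservative, the
residual gap being the discreteness of the exact null (the rejection
region steps from an attainable per-test level of 0.0146 to 0.0170).
Detection power at amplitude/noise = 2 with n = 4 × 6 exceeds 0.99.  The
best lag is the minimal-p lag, ties broken toward the most positive S (the
in-phase match), which makes the estimate deterministic and equivariant
under sign reversal (anti-phase data moves the best lag by 12 h).
Downstream rhythmic/non-rhythmic classification uses BH-adjusted p < 0.05
across genes; the raw-p threshold is also exposed since both conventions
are common in figure legends.

## Differential expression

Group comparisons use Welch's unequal-variance t-test throughout (the
safer reading whenever "Student's t" is reported alongside Welch-corrected
pairwise testing).  Significance requires both BH q < 0.1 *and*
|log2 fold change| ≥ log2(1.5) ≈ 0.58; the gate applies to the point
estimate, inclusive.  Per-timepoint analysis applies the identical
procedure within each ZT stratum with BH within the stratum (strata are
separate families; pooling would couple timepoints).  Robust DEGs are
genes significant in every stratum with one direction throughout — the
empty set is a perfectly valid outcome for subtle treatments.  Features
with fewer than two complete samples in a group are flagged untestable and
excluded from the BH family rather than given fake p-values.

## Tuning-gene panel

A tuning gene satisfies, at level α in both contrasts (control vs low
state, control vs high state): a significant mesor difference, with
opposite signs in the two contrasts.  No effect-size floor is applied by
default (`min_abs_dmesor = 0`); the threshold is exposed for stricter
panels.  The mesor-only subset removes genes with a significant amplitude
difference in either contrast or a significant phase difference where
phase is comparable — waveform changes would confound a level-based state
readout.  Ranking: within each contrast genes are ranked by descending
|Δmesor| (rank 1 = largest); the combined rank is the mean of the two, with
ties broken by the high-state rank and then the gene id so the ordering is
total.  The mean-of-ranks combination is a deliberate choice among equally
defensible rules (min-rank, product) — it weights both contrasts equally
and is what the brute-force oracle in the tests implements independently.

Pathway-level temporal profiles subtract each gene's control-group mesor
from its log2 values (a log2 fold change relative to the control midline)
and average per gene set, group and timepoint.  Panel validation against
external gene lists is exact set arithmetic with case-insensitive symbol
matching, reporting the overlap percentage relative to the query.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability with
the analysis universe (all features surviving probe curation, not the
genome — the standard background choice).  Admission to BH correction
requires ≥ 5 overlapping genes, relaxed to ≥ 2 when the query has fewer
than 100 genes.  Semantic redundancy reduction of related processes is out
of scope here (it needs the ontology graph).

## Probe handling

Probes mapping to more than one gene are removed before gene-level calls;
unambiguous probes are relabelled `gene::probe` so multi-probe genes stay
distinguishable.  Analyses run at probe level; a gene-level call requires
all of a gene's probes to agree in direction, the conservative aggregation
when no explicit rule is available.

## Physiology utilities

Telemetry traces (minutes since recording start) are binned by averaging,
optionally folding days modulo 24 h first; empty bins are NaN.  Light
phase is ZT 0–12, dark ZT 12–24; day/night comparison is one mean per
animal per window, compared by unpaired Welch t-test, with the p-value
suppressed for a single animal.  Heat production uses the caloric
equivalent `(4.44 + 1.43·RQ)·VO₂` (mW from ml O₂/h); RQ outside
[0.5, 1.3] warns rather than errors since the formula itself is defined
everywhere.  Dose-trend testing correlates per-animal means against
ordinal group codes by Spearman rank correlation with an exact permutation
p (all n! orderings) for n ≤ 10 animals, asymptotic beyond.  Note that with
multiple animals per group the ordinal codes are tied, so ρ = 1 is not
attainable even for a perfect trend.  The Pfaffl qPCR ratio
`E_t^ΔCt_t / E_ref^ΔCt_ref` validates efficiencies in (1, 2.2].

## Synthetic-data generator

The generator emulates a three-group (control / low / high hormone state)
diurnal profiling design: sampling every 4 h at ZT 2–22 (the grid
deliberately avoids assuming a ZT0 collection), 4 replicates per timepoint
with per-(group, timepoint) overrides to express discarded arrays, and
additive Gaussian noise on the log2 scale (default σ = 0.25, a typical
residual SD for expression arrays).  By default 30% of non-planted genes
are rhythmic, with mesors uniform on [4, 10] log2 units, amplitudes on
[0.4, 1.5] and phases uniform over the day.  Planted effect blocks modify
the treatment groups: mesor shifts of ±0.8 log2 units, amplitude scaling
×2, phase delays of +2 h, and "tuning" genes whose mesor moves +0.8 in one
treatment and −0.8 in the other (directions alternating).  All randomness
flows through a single PCG64 generator seeded from the config; identical
configs give bit-identical matrices.

What the generator does **not** emulate: probe-level cross-hybridisation,
array batch effects, intensity-dependent (heteroscedastic) noise,
count-based RNA-seq error, correlated genes, and non-sinusoidal waveforms.
Passing recovery tests on this generator therefore demonstrates the
statistical machinery is correct under its stated model, not that real
microarray data meet those assumptions; on real data the dual rhythm
methods (parametric and rank-based) are the built-in cross-check.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations to keep
sampling error small relative to each asserted band: 500 replicates for
estimator bias/coverage, 1,000-gene screens with 50 planted effects for
sensitivity/FDR, and pooled batches (up to 2 × 10⁶ null genes in the
calibration test) where a rate must be resolved to ~10⁻⁴.  All tests are
seeded; hypothesis-based property tests run derandomised.  Output tables
are written with fixed column order and %.6g precision, and carry the seed
and a config hash in a header comment so result directories are
self-describing.
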