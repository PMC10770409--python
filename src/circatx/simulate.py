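"""Synthetic diurnal-transcriptome and telemetry generator with ground truth.

Emulates a three-group (control / low-hormone / high-hormone) liver profiling
design: tissues sampled every 4 h across the day (ZT 2, 6, 10, 14, 18, 22),
3-4 replicates per timepoint, expression on the log2 scale with additive
Gaussian noise.  A configurable fraction of genes is rhythmic with cosine
profiles; planted effect blocks perturb mesor, amplitude, or phase in the
treatment groups, and a "tuning" block moves the mesor in opposite
directions under the low- and high-hormone states.  Every feature's true
parameters are recorded in a ground-truth table so downstream stages have a
parameter-recovery and sensitivity/FDR test surface.

All randomness flows through one :class:`numpy.random.Generator` (PCG64)
seeded from the config, so identical configs reproduce identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import ExpressionSet

__all__ = [
    "SimConfig",
    "Trace",
    "simulate_expression",
    "simulate_trace",
    "truth_confusion",
    "PLANTED_CLASSES",
]

PLANTED_CLASSES = (
    "null_flat",
    "null_rhythmic",
    "mesor_up",
    "mesor_down",
    "amp_change",
    "phase_shift",
    "tuning_opposite",
)


@dataclass
class SimConfig:
    """Design and effect-size configuration for the expression simulator.

    Defaults mirror the emulated study: groups CON (control), MMI (low
    hormone), T3 (high hormone); sampling every 4 h at ZT 2-22; four
    replicates per timepoint; log2-scale Gaussian noise.  ``n_reps`` may be
    overridden per (group, zt) via ``rep_overrides`` to express removed
    arrays / unbalanced designs.
    """

    n_features: int = 1000
    zt_grid: tuple[float, ...] = (2.0, 6.0, 10.0, 14.0, 18.0, 22.0)
    n_reps: int = 4
    rep_overrides: dict = field(default_factory=dict)  # (group, zt) -> n
    groups: tuple[str, ...] = ("CON", "MMI", "T3")
    noise_sd: float = 0.25
    frac_rhythmic: float = 0.3
    # planted effect blocks: class -> count
    n_mesor_up: int = 0
    n_mesor_down: int = 0
    n_amp_change: int = 0
    n_phase_shift: int = 0
    n_tuning_opposite: int = 0
    # effect magnitudes
    mesor_effect: float = 0.8       # log2 units
    amp_effect_ratio: float = 2.0   # multiplicative on amplitude
    phase_effect_h: float = 2.0     # hours, positive = delay
    # baseline parameter ranges
    mesor_range: tuple[float, float] = (4.0, 10.0)
    amp_range: tuple[float, float] = (0.4, 1.5)
    seed: int = 0

    def validate(self) -> None:
        zts = np.asarray(self.zt_grid, float)
        if len(np.unique(zts)) != len(zts) or ((zts < 0) | (zts >= 24)).any():
            raise ValueError("zt_grid values must be distinct and in [0, 24)")
        if not (0 <= self.frac_rhythmic <= 1):
            raise ValueError("frac_rhythmic must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        n_planted = (self.n_mesor_up + self.n_mesor_down + self.n_amp_change
                     + self.n_phase_shift + self.n_tuning_opposite)
        if n_planted > self.n_features:
            raise ValueError(
                f"effect blocks ({n_planted}) exceed n_features ({self.n_features})"
            )

    def n_rep(self, group: str, zt: float) -> int:
        return int(self.rep_overrides.get((group, zt), self.n_reps))


@dataclass
class Trace:
    """A telemetry trace: timestamps in minutes since recording start."""

    animal_id: str
    minutes: np.ndarray
    values: np.ndarray
    variable: str = "value"

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, float)
        self.values = np.asarray(self.values, float)
        if len(self.minutes) != len(self.values):
            raise ValueError("minutes and values must have equal length")
        if np.any(np.diff(self.minutes) <= 0):
            raise ValueError("timestamps must be strictly increasing")


def _cosine(t: np.ndarray, mesor: float, amp: float, phase: float,
            period: float = 24.0) -> np.ndarray:
    return mesor + amp * np.cos(2 * np.pi * (t - phase) / period)


def _assign_classes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Planted effect blocks occupy the head of the feature list; the rest
    splits into rhythmic/flat nulls by ``frac_rhythmic``."""
    classes = np.empty(cfg.n_features, dtype=object)
    i = 0
    for cls, n in [("mesor_up", cfg.n_mesor_up), ("mesor_down", cfg.n_mesor_down),
                   ("amp_change", cfg.n_amp_change),
                   ("phase_shift", cfg.n_phase_shift),
                   ("tuning_opposite", cfg.n_tuning_opposite)]:
        classes[i:i + n] = cls
        i += n
    n_rest = cfg.n_features - i
    n_rhythmic = int(round(cfg.frac_rhythmic * n_rest))
    rest = np.array(["null_rhythmic"] * n_rhythmic
                    + ["null_flat"] * (n_rest - n_rhythmic), dtype=object)
    rng.shuffle(rest)
    classes[i:] = rest
    return classes


def simulate_expression(cfg: SimConfig) -> tuple[dict[str, ExpressionSet], pd.DataFrame]:
    """Simulate one ExpressionSet per group plus the ground-truth ledger.

    Each observation is ``M_g + A_g * cos(2*pi*(zt - phi_g)/24) + eps`` with
    ``eps ~ Normal(0, noise_sd^2)``.  The returned truth table has one row
    per feature: its planted class and the true (M, A, phi) per group.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    features = [f"gene{i:05d}" for i in range(cfg.n_features)]
    classes = _assign_classes(cfg, rng)

    mesor = rng.uniform(*cfg.mesor_range, cfg.n_features)
    amp = rng.uniform(*cfg.amp_range, cfg.n_features)
    phase = rng.uniform(0, 24, cfg.n_features)

    control = cfg.groups[0]
    treatments = list(cfg.groups[1:])
    # per-group true parameter arrays
    M = {g: mesor.copy() for g in cfg.groups}
    A = {g: amp.copy() for g in cfg.groups}
    PHI = {g: phase.copy() for g in cfg.groups}

    flat = classes == "null_flat"
    for g in cfg.groups:
        A[g][flat] = 0.0
        PHI[g][flat] = 0.0

    # alternate tuning directions: even index down-low/up-high, odd the reverse
    tuning_sign = np.where(np.arange(cfg.n_features) % 2 == 0, -1.0, 1.0)
    for idx, cls in enumerate(classes):
        if cls == "mesor_up":
            for g in treatments:
                M[g][idx] += cfg.mesor_effect
        elif cls == "mesor_down":
            for g in treatments:
                M[g][idx] -= cfg.mesor_effect
        elif cls == "amp_change":
            for g in treatments:
                A[g][idx] *= cfg.amp_effect_ratio
        elif cls == "phase_shift":
            for g in treatments:
                PHI[g][idx] = (PHI[g][idx] + cfg.phase_effect_h) % 24
        elif cls == "tuning_opposite":
            if len(treatments) < 2:
                raise ValueError("tuning_opposite needs at least 3 groups")
            s = tuning_sign[idx]
            M[treatments[0]][idx] += s * cfg.mesor_effect
            M[treatments[1]][idx] -= s * cfg.mesor_effect

    sets: dict[str, ExpressionSet] = {}
    for g in cfg.groups:
        cols, rows_meta = [], []
        for zt in cfg.zt_grid:
            for r in range(1, cfg.n_rep(g, zt) + 1):
                rows_meta.append({"sample_id": f"{g}_ZT{int(zt):02d}_{r}",
                                  "group": g, "zt": float(zt), "replicate": r})
                cols.append(float(zt))
        zts = np.asarray(cols)
        signal = (M[g][:, None]
                  + A[g][:, None] * np.cos(2 * np.pi * (zts[None, :] - PHI[g][:, None]) / 24))
        noise = rng.normal(0.0, cfg.noise_sd, signal.shape) if cfg.noise_sd > 0 else 0.0
        mat = pd.DataFrame(signal + noise, index=features,
                           columns=[m["sample_id"] for m in rows_meta])
        sets[g] = ExpressionSet(mat, pd.DataFrame(rows_meta))

    truth = pd.DataFrame({"feature": features, "planted_class": classes})
    for g in cfg.groups:
        truth[f"M_{g}"] = M[g]
        truth[f"A_{g}"] = A[g]
        truth[f"phi_{g}"] = PHI[g]
    return sets, truth


def simulate_trace(mean_level: float, amplitude: float, phase: float,
                   bin_minutes: int = 1, days: int = 2,
                   noise_sd: float = 0.0, seed: int = 0,
                   animal_id: str = "animal", variable: str = "value") -> Trace:
    """Simulate a telemetry trace: a 24-h sinusoid plus Gaussian noise.

    ``phase`` is the peak time in hours.  Samples fall at bin centres; the
    trace spans ``days`` full days, so its length is ``days*1440/bin_minutes``.
    """
    if 1440 % bin_minutes != 0:
        raise ValueError(f"bin_minutes={bin_minutes} must divide 1440")
    n = days * 1440 // bin_minutes
    minutes = np.arange(n) * bin_minutes + bin_minutes / 2.0
    hours = minutes / 60.0
    vals = _cosine(hours, mean_level, amplitude, phase)
    if noise_sd > 0:
        vals = vals + np.random.default_rng(seed).normal(0, noise_sd, n)
    return Trace(animal_id, minutes, vals, variable)


def truth_confusion(truth: pd.DataFrame, calls, positive_classes) -> dict:
    """Sensitivity, specificity and empirical FDR of a per-feature call set.

    ``calls`` is any iterable of feature ids flagged positive; the planted
    truth defines positives as features whose ``planted_class`` is in
    ``positive_classes``.  When there are no calls, FDR is undefined and is
    reported as 0.0 with ``fdr_defined=False``.
    """
    if isinstance(positive_classes, str):
        positive_classes = [positive_classes]
    calls = set(calls)
    known = set(truth["feature"])
    unknown = calls - known
    if unknown:
        raise KeyError(f"calls reference unknown features: {sorted(unknown)[:5]}")
    positives = set(truth.loc[truth["planted_class"].isin(positive_classes), "feature"])
    negatives = known - positives
    tp = len(calls & positives)
    fp = len(calls & negatives)
    sens = tp / len(positives) if positives else float("nan")
    spec = (len(negatives) - fp) / len(negatives) if negatives else float("nan")
    fdr_defined = len(calls) > 0
    fdr = fp / len(calls) if fdr_defined else 0.0
    return {"sensitivity": sens, "specificity": spec, "fdr": fdr,
            "fdr_defined": fdr_defined, "tp": tp, "fp": fp,
            "n_calls": len(calls), "n_positives": len(positives)}


def truth_to_table(truth: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth ledger in the TSV layout written alongside matrices."""
    return truth.copy()
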