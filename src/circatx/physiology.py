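"""Telemetry and indirect-calorimetry computations.

Utilities for continuously recorded physiology (locomotor activity, core
body temperature, oxygen consumption, respiratory quotient): time binning
with day folding, light/dark (ZT 0-12 vs 12-24) phase summaries with Welch
comparison across animals, the caloric-equivalent heat-production formula
``heat (mW) = (4.44 + 1.43*RQ) * VO2 (ml O2/h)``, an ordinal dose-trend
Spearman correlation with an exact permutation p-value for small cohorts,
and the Pfaffl efficiency-corrected relative-expression ratio for qPCR.

Traces carry timestamps in minutes since recording start; folding to
Zeitgeber time assumes the recording is aligned so minute 0 = lights on
(pass ``lights_on_minute`` otherwise).  Cosinor analysis of binned traces
reuses the cosinor module unchanged.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import Trace

__all__ = [
    "DayNightSummary",
    "bin_trace",
    "day_night_summary",
    "heat_production",
    "dose_trend_correlation",
    "pfaffl_ratio",
]


@dataclass
class DayNightSummary:
    light_mean: float
    dark_mean: float
    difference: float   # dark - light
    p: float | None     # Welch two-sided across animals; None if suppressed
    n_animals: int


def bin_trace(trace: Trace, bin_minutes: int = 60,
              average_days: bool = True) -> Trace:
    """Average a trace into fixed-width time bins.

    With ``average_days`` the timestamps are folded modulo 24 h first, so
    multiple recorded days are averaged into one representative day (the
    usual presentation of multi-day telemetry).  Empty bins are NaN.
    Binned timestamps are bin centres.
    """
    if 1440 % bin_minutes != 0:
        raise ValueError(f"bin_minutes={bin_minutes} must divide 1440")
    minutes = trace.minutes % 1440 if average_days else trace.minutes
    span = 1440 if average_days else int(np.ceil((trace.minutes.max() + 1) / 1440) * 1440)
    n_bins = span // bin_minutes
    idx = (minutes // bin_minutes).astype(int)
    sums = np.bincount(idx, weights=np.nan_to_num(trace.values), minlength=n_bins)
    cnts = np.bincount(idx, weights=np.isfinite(trace.values).astype(float),
                       minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(cnts > 0, sums / cnts, np.nan)
    centres = np.arange(n_bins) * bin_minutes + bin_minutes / 2.0
    return Trace(trace.animal_id, centres, means, trace.variable)


def _window_mean(trace: Trace, lo_h: float, hi_h: float,
                 lights_on_minute: float) -> float:
    zt_h = ((trace.minutes - lights_on_minute) / 60.0) % 24
    mask = (zt_h >= lo_h) & (zt_h < hi_h) & np.isfinite(trace.values)
    return float(trace.values[mask].mean()) if mask.any() else float("nan")


def day_night_summary(traces: list[Trace],
                      lights_on_minute: float = 0.0) -> DayNightSummary:
    """Light-phase vs dark-phase comparison across animals.

    Each animal contributes one mean per window (light = ZT 0-12, dark =
    ZT 12-24); windows are compared with an unpaired Welch t-test.  With a
    single animal the means are still reported but the p-value is
    suppressed (None).
    """
    light = np.array([_window_mean(t, 0, 12, lights_on_minute) for t in traces])
    dark = np.array([_window_mean(t, 12, 24, lights_on_minute) for t in traces])
    ok = np.isfinite(light) & np.isfinite(dark)
    light, dark = light[ok], dark[ok]
    n = len(light)
    if n == 0:
        raise ValueError("no animal covers both light and dark windows")
    lm, dm = float(light.mean()), float(dark.mean())
    if n < 2:
        return DayNightSummary(lm, dm, dm - lm, None, n)
    if np.allclose(light, light[0]) and np.allclose(dark, dark[0]):
        p = 1.0 if np.isclose(lm, dm) else 0.0
    else:
        p = float(stats.ttest_ind(dark, light, equal_var=False).pvalue)
    return DayNightSummary(lm, dm, dm - lm, p, n)


def heat_production(rq, vo2, rq_window: tuple[float, float] | None = (0.5, 1.3)):
    """Caloric-equivalent heat production in mW from RQ and VO2 (ml O2/h).

    ``heat = (4.44 + 1.43 * RQ) * VO2``.  RQ values outside the sanity
    window trigger a warning (physiological RQ lies between ~0.7 for pure
    fat and ~1.0 for pure carbohydrate oxidation); negative VO2 is an error.
    """
    rq_arr = np.asarray(rq, float)
    vo2_arr = np.asarray(vo2, float)
    if np.any(vo2_arr < 0):
        raise ValueError("VO2 must be non-negative")
    if rq_window is not None:
        lo, hi = rq_window
        if np.any((rq_arr < lo) | (rq_arr > hi)):
            warnings.warn(f"RQ outside the sanity window [{lo}, {hi}]")
    heat = (4.44 + 1.43 * rq_arr) * vo2_arr
    return float(heat) if np.isscalar(rq) and np.isscalar(vo2) else heat


def _spearman_exact_p(codes: np.ndarray, means: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p: P(|rho_perm| >= |rho_obs|) over all orderings."""
    xr = stats.rankdata(codes)
    yr = stats.rankdata(means)
    xr = xr - xr.mean()
    yr = yr - yr.mean()
    denom = np.sqrt((xr ** 2).sum() * (yr ** 2).sum())
    obs = abs(xr @ yr)
    count = total = 0
    for perm in itertools.permutations(range(len(yr))):
        num = abs(xr @ yr[list(perm)])
        count += num >= obs - 1e-9 * denom
        total += 1
    return count / total


def dose_trend_correlation(group_order: list[str],
                           per_animal_means: dict[str, list[float]],
                           exact_limit: int = 10) -> tuple[float, float]:
    """Spearman correlation of animal means against ordinal dose codes.

    ``group_order`` lists the groups from lowest to highest hormone state
    (e.g. low < control < high); every animal contributes its mean.  The
    p-value is an exact permutation tail for n <= ``exact_limit`` animals,
    asymptotic otherwise.  Being a rank statistic, rho is invariant to any
    strictly monotone transform of the means.
    """
    present = [g for g in group_order if g in per_animal_means and len(per_animal_means[g])]
    if len(present) < 2:
        raise ValueError("dose trend needs >= 2 groups with animals")
    codes, means = [], []
    for code, g in enumerate(group_order):
        for v in per_animal_means.get(g, []):
            codes.append(code)
            means.append(float(v))
    codes = np.asarray(codes, float)
    means = np.asarray(means, float)
    if len(means) < 3:
        raise ValueError("dose trend needs >= 3 animals")
    rho, p_asym = stats.spearmanr(codes, means)
    if len(means) <= exact_limit:
        p = _spearman_exact_p(codes, means, rho)
    else:
        p = float(p_asym)
    return float(rho), p


def pfaffl_ratio(e_target: float, dct_target: float,
                 e_ref: float, dct_ref: float) -> float:
    """Efficiency-corrected qPCR relative expression.

    ``ratio = E_target ** dCt_target / E_ref ** dCt_ref`` with
    amplification efficiencies E in (1, 2.2] (2 = perfect doubling) and
    dCt the control-minus-treated cycle-threshold differences.
    """
    for name, e in (("e_target", e_target), ("e_ref", e_ref)):
        if not (1.0 < e <= 2.2):
            raise ValueError(f"{name}={e} outside the valid range (1, 2.2]")
    return float(e_target ** dct_target / e_ref ** dct_ref)
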