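"""Cosinor rhythmometry: single-group fits and two-group rhythm comparison.

The rhythm model is the fixed-period (24 h) cosinor

    y(t) = M + A * cos(2*pi*(t - phi)/tau),   A >= 0,  phi in [0, tau)

estimated through its linearization ``y ~ 1 + sin(2*pi*t/tau) +
cos(2*pi*t/tau)``: with beta_s, beta_c the sine/cosine coefficients,
``A = sqrt(beta_s^2 + beta_c^2)`` and ``phi = (tau/2*pi) * atan2(beta_s,
beta_c) mod tau``, so the fitted curve peaks at t = phi (the acrophase).
Rhythmicity is the joint F-test of beta_s = beta_c = 0.

Two groups are compared by a joint nonlinear least-squares fit

    y = (k + k1*G) + (a + a1*G) * cos(2*pi*(t - phi - phi1*G)/tau)

with G the 0/1 group indicator, so k1, a1, phi1 are the between-group
differences in mesor, amplitude and phase.  Wald t-tests (estimate over
asymptotic SE, residual degrees of freedom) give the three p-values.  The
phase difference is only tested when both groups are individually rhythmic;
its sign convention is positive = group-1 peak later (a phase delay).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import ExpressionSet

__all__ = [
    "RhythmFit",
    "DiffRhythmResult",
    "fit_cosinor",
    "compare_rhythms",
    "mean_phase_shift",
    "batch_fit",
    "batch_compare",
    "wrap_phase_diff",
]

TINY_P = 5e-324  # smallest subnormal double; stands in for an exact fit


def wrap_phase_diff(dphi: float, period: float = 24.0) -> float:
    """Wrap a phase difference to the half-open interval (-period/2, period/2]."""
    w = ((dphi + period / 2) % period) - period / 2
    if w == -period / 2:
        w = period / 2
    return w


@dataclass
class RhythmFit:
    """Single-group cosinor estimates for one feature."""

    mesor: float
    amplitude: float
    phase: float
    p_rhythm: float
    se_mesor: float
    se_amplitude: float
    se_phase: float
    n_obs: int
    period: float = 24.0
    exact_fit: bool = False
    amp_identifiable: bool = True


@dataclass
class DiffRhythmResult:
    """Between-group differences in rhythm parameters for one feature."""

    dmesor: float            # k1: group1 - group0 mesor, log2 units
    damplitude: float        # a1: group1 - group0 amplitude, log2 units
    dphase: float            # phi1: hours in (-12, 12], positive = delay
    p_mesor: float
    p_amplitude: float
    p_phase: float           # NaN unless phase_comparable
    se_dmesor: float
    se_damplitude: float
    se_dphase: float
    dof: int
    rhythmic_in_g0: bool
    rhythmic_in_g1: bool
    phase_comparable: bool
    fit_g0: RhythmFit | None = None
    fit_g1: RhythmFit | None = None
    converged: bool = True


def _design(times: np.ndarray, period: float) -> np.ndarray:
    w = 2 * np.pi * times / period
    return np.column_stack([np.ones_like(times), np.sin(w), np.cos(w)])


def fit_cosinor(times, values, period: float = 24.0) -> RhythmFit:
    """Least-squares cosinor fit of one series.

    Requires at least 4 complete (time, value) pairs spanning at least 3
    distinct timepoints (otherwise the sin/cos design is rank deficient).
    Missing values are dropped pairwise.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    n = len(y)
    if n < 4 or len(np.unique(np.round(t % period, 9))) < 3:
        raise ValueError(
            f"cosinor fit needs >= 4 observations on >= 3 distinct times, got n={n}"
        )
    X = _design(t, period)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    df = n - 3
    mesor, bs, bc = beta
    amp = math.hypot(bs, bc)
    phase = (period / (2 * math.pi)) * math.atan2(bs, bc) % period

    exact = rss <= max(tss, 1.0) * 1e-24
    if exact:
        p = 1.0 if amp <= 1e-12 else TINY_P
        sigma2 = 0.0
    else:
        f = ((tss - rss) / 2) / (rss / df)
        p = float(stats.f.sf(f, 2, df))
        sigma2 = rss / df

    XtX_inv = np.linalg.inv(X.T @ X)
    cov = sigma2 * XtX_inv
    se_m = math.sqrt(max(cov[0, 0], 0.0))
    identifiable = amp > 1e-9
    if identifiable:
        gA = np.array([0.0, bs / amp, bc / amp])
        gP = np.array([0.0, bc / amp**2, -bs / amp**2]) * (period / (2 * math.pi))
        se_a = math.sqrt(max(gA @ cov @ gA, 0.0))
        se_p = math.sqrt(max(gP @ cov @ gP, 0.0))
    else:
        se_a = math.sqrt(max(cov[1, 1] + cov[2, 2], 0.0))
        se_p = float("inf")
    return RhythmFit(float(mesor), float(amp), float(phase), p, se_m, se_a, se_p,
                     n, period, exact, identifiable)


def _joint_residuals(params, t, y, g, period):
    k, k1, a, a1, phi, phi1 = params
    mes = k + k1 * g
    amp = a + a1 * g
    ph = phi + phi1 * g
    return y - (mes + amp * np.cos(2 * np.pi * (t - ph) / period))


def compare_rhythms(times0, values0, times1, values1, period: float = 24.0,
                    rhythm_alpha: float = 0.05) -> DiffRhythmResult:
    """Joint nonlinear two-group cosinor fit and Wald tests of the differences.

    Mesor and amplitude differences are estimated and tested irrespective of
    rhythmicity; the phase difference is wrapped to (-12, 12] and its p-value
    reported only when both groups are individually rhythmic at
    ``rhythm_alpha`` (phase is meaningless for an arrhythmic profile).
    """
    f0 = fit_cosinor(times0, values0, period)
    f1 = fit_cosinor(times1, values1, period)

    t0 = np.asarray(times0, float)
    y0 = np.asarray(values0, float)
    t1 = np.asarray(times1, float)
    y1 = np.asarray(values1, float)
    ok0 = np.isfinite(t0) & np.isfinite(y0)
    ok1 = np.isfinite(t1) & np.isfinite(y1)
    t = np.concatenate([t0[ok0], t1[ok1]])
    y = np.concatenate([y0[ok0], y1[ok1]])
    g = np.concatenate([np.zeros(ok0.sum()), np.ones(ok1.sum())])

    dphi0 = wrap_phase_diff(f1.phase - f0.phase, period)
    x0 = np.array([f0.mesor, f1.mesor - f0.mesor, f0.amplitude,
                   f1.amplitude - f0.amplitude, f0.phase, dphi0])

    best = None
    rng_jitters = [0.0] + [(j + 1) * period / 8 for j in range(8)]
    for jit in rng_jitters:
        start = x0.copy()
        start[4] = (x0[4] + jit) % period
        sol = optimize.least_squares(_joint_residuals, start,
                                     args=(t, y, g, period), method="lm",
                                     max_nfev=2000)
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol
        if best.success and jit == 0.0:
            break
    sol = best
    converged = bool(sol.success)

    k, k1, a, a1, phi, phi1 = sol.x
    # normalize: per-group amplitudes non-negative (sign flip = half-period
    # phase shift); with per-group initialization this is a rare safety net
    amp0, ph0 = a, phi
    amp1, ph1 = a + a1, phi + phi1
    if amp0 < 0:
        amp0, ph0 = -amp0, ph0 + period / 2
    if amp1 < 0:
        amp1, ph1 = -amp1, ph1 + period / 2
    est_damp = amp1 - amp0
    est_dphase = wrap_phase_diff(ph1 - ph0, period)

    n = len(y)
    dof = n - 6
    resid = _joint_residuals(sol.x, t, y, g, period)
    rss = float(resid @ resid)
    sigma2 = rss / dof if dof > 0 else float("nan")
    J = sol.jac
    try:
        cov = sigma2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(6, np.nan)
        converged = False

    def wald_p(est, s):
        if not np.isfinite(s) or s == 0:
            return TINY_P if est != 0 else 1.0
        return float(2 * stats.t.sf(abs(est / s), dof))

    p_mesor = wald_p(sol.x[1], se[1])
    p_amp = wald_p(sol.x[3], se[3])

    r0 = f0.p_rhythm < rhythm_alpha
    r1 = f1.p_rhythm < rhythm_alpha
    comparable = bool(r0 and r1 and f0.amp_identifiable and f1.amp_identifiable)
    p_phase = wald_p(est_dphase, se[5]) if comparable else float("nan")

    return DiffRhythmResult(float(sol.x[1]), float(est_damp), float(est_dphase),
                            p_mesor, p_amp, p_phase,
                            float(se[1]), float(se[3]), float(se[5]), int(dof),
                            bool(r0), bool(r1), comparable, f0, f1, converged)


def mean_phase_shift(dphases, period: float = 24.0) -> tuple[float, float, bool]:
    """Mean wrapped phase difference and a one-sample t-test against zero.

    Accepts either raw phase-difference values or DiffRhythmResult records
    (non-comparable records are excluded).  Returns ``(mean, p, exact)`` where
    ``exact`` flags a degenerate all-identical sample whose p-value is
    reported at the boundary rather than from the t distribution.
    """
    vals = []
    for d in dphases:
        if isinstance(d, DiffRhythmResult):
            if d.phase_comparable:
                vals.append(d.dphase)
        else:
            vals.append(float(d))
    if len(vals) < 2:
        raise ValueError("mean_phase_shift needs >= 2 comparable phase differences")
    x = np.asarray(vals, float)
    mean = float(x.mean())
    if np.allclose(x, x[0]):
        return mean, (1.0 if abs(mean) < 1e-12 else 0.0), True
    tstat = stats.ttest_1samp(x, 0.0)
    return mean, float(tstat.pvalue), False


# ---------------------------------------------------------------------------
# batch APIs over ExpressionSets
# ---------------------------------------------------------------------------

def batch_fit(es: ExpressionSet, period: float = 24.0) -> pd.DataFrame:
    """Per-feature cosinor fits of one group's ExpressionSet."""
    t = es.zt
    rows = []
    for feat in es.features:
        y = es.values.loc[feat].to_numpy()
        f = fit_cosinor(t, y, period)
        rows.append({"feature": feat, "mesor": f.mesor, "amplitude": f.amplitude,
                     "phase": f.phase, "p_rhythm": f.p_rhythm,
                     "se_mesor": f.se_mesor, "se_amplitude": f.se_amplitude,
                     "se_phase": f.se_phase, "n_obs": f.n_obs})
    return pd.DataFrame(rows)


def batch_compare(es0: ExpressionSet, es1: ExpressionSet, period: float = 24.0,
                  rhythm_alpha: float = 0.05,
                  bh_adjust_differences: bool = False) -> pd.DataFrame:
    """Per-feature two-group rhythm comparison (group1 minus group0).

    Features must match between the two sets.  One row per feature with the
    parameter differences, their p-values and the gating flags.  The three
    difference p-values are reported uncorrected by default (the common
    practice for pairwise differential-rhythm screens); set
    ``bh_adjust_differences`` to add BH q-value columns across features
    (``q_mesor``, ``q_amplitude``, ``q_phase``; phase adjusted within the
    phase-comparable family).
    """
    if es0.features != es1.features:
        raise ValueError("feature lists differ between the two groups")
    t0, t1 = es0.zt, es1.zt
    rows = []
    for feat in es0.features:
        r = compare_rhythms(t0, es0.values.loc[feat].to_numpy(),
                            t1, es1.values.loc[feat].to_numpy(),
                            period, rhythm_alpha)
        rows.append({
            "feature": feat,
            "mesor_g0": r.fit_g0.mesor, "amplitude_g0": r.fit_g0.amplitude,
            "phase_g0": r.fit_g0.phase, "p_rhythm_g0": r.fit_g0.p_rhythm,
            "mesor_g1": r.fit_g1.mesor, "amplitude_g1": r.fit_g1.amplitude,
            "phase_g1": r.fit_g1.phase, "p_rhythm_g1": r.fit_g1.p_rhythm,
            "dmesor": r.dmesor, "damplitude": r.damplitude, "dphase": r.dphase,
            "p_mesor": r.p_mesor, "p_amplitude": r.p_amplitude,
            "p_phase": r.p_phase, "se_dmesor": r.se_dmesor,
            "se_damplitude": r.se_damplitude, "se_dphase": r.se_dphase,
            "rhythmic_in_g0": r.rhythmic_in_g0, "rhythmic_in_g1": r.rhythmic_in_g1,
            "phase_comparable": r.phase_comparable, "converged": r.converged,
        })
    out = pd.DataFrame(rows)
    if bh_adjust_differences:
        from .jtk import bh_adjust
        out["q_mesor"] = bh_adjust(out["p_mesor"])
        out["q_amplitude"] = bh_adjust(out["p_amplitude"])
        out["q_phase"] = np.nan
        comp = out["phase_comparable"].to_numpy()
        if comp.any():
            out.loc[comp, "q_phase"] = bh_adjust(out.loc[comp, "p_phase"])
    return out
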