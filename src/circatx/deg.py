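"""Differential expression: global, per-timepoint, and robust calls.

Global DEGs pool all timepoints of each group and compare treated against
control with a Welch two-sample t-test per feature, Benjamini-Hochberg
correction across features, and a dual gate: q below the FDR threshold
(default 0.1) AND an absolute log2 fold change of at least log2(1.5)
(~0.58).  Per-timepoint DEGs apply the identical procedure within each ZT
stratum separately (BH within stratum).  Robust (time-independent) DEGs are
the features significant at *every* timepoint with the same direction
throughout — the strongest, sampling-time-free evidence of a group effect.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionSet
from .jtk import bh_adjust

__all__ = ["global_deg", "per_zt_deg", "robust_degs", "deg_summary",
           "FC_THRESHOLD_LOG2"]

FC_THRESHOLD_LOG2 = math.log2(1.5)  # the 1.5-fold gate, ~0.58 in log2 units


def _deg_core(ctrl: np.ndarray, trt: np.ndarray, features,
              scope: str, q_threshold: float, fc_threshold: float) -> pd.DataFrame:
    """Welch t + BH + fold-change gate on two feature x sample matrices."""
    n_c = np.isfinite(ctrl).sum(axis=1)
    n_t = np.isfinite(trt).sum(axis=1)
    testable = (n_c >= 2) & (n_t >= 2)
    log2fc = np.nanmean(trt, axis=1) - np.nanmean(ctrl, axis=1)
    tstat = np.full(len(features), np.nan)
    p = np.full(len(features), np.nan)
    if testable.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(trt[testable], ctrl[testable], axis=1,
                                  equal_var=False, nan_policy="omit")
        tstat[testable] = res.statistic
        p[testable] = res.pvalue
    # zero-variance pairs can yield nan p; treat identical groups as p = 1
    bad = testable & ~np.isfinite(p)
    p[bad] = 1.0
    q = np.full(len(features), np.nan)
    if testable.any():
        q[testable] = bh_adjust(p[testable])
    significant = testable & (q < q_threshold) & (np.abs(log2fc) >= fc_threshold)
    direction = np.where(log2fc > 0, "up", "down")
    return pd.DataFrame({
        "feature": features, "scope": scope, "log2fc": log2fc,
        "t_stat": tstat, "p": p, "q": q,
        "significant": significant, "direction": direction,
        "testable": testable,
    })


def global_deg(es_control: ExpressionSet, es_treated: ExpressionSet,
               q_threshold: float = 0.1,
               fc_threshold: float = FC_THRESHOLD_LOG2) -> pd.DataFrame:
    """Global DEG table (all timepoints pooled per group).

    log2fc is treated minus control mean.  Features with fewer than two
    complete samples in either group are flagged untestable and excluded
    from the BH adjustment.
    """
    if es_control.features != es_treated.features:
        raise ValueError("feature lists differ between control and treated sets")
    return _deg_core(es_control.values.to_numpy(), es_treated.values.to_numpy(),
                     es_control.features, "global", q_threshold, fc_threshold)


def per_zt_deg(es_control: ExpressionSet, es_treated: ExpressionSet,
               q_threshold: float = 0.1,
               fc_threshold: float = FC_THRESHOLD_LOG2) -> pd.DataFrame:
    """Per-timepoint DEG tables, stacked, with ``scope`` = the ZT as string.

    Strata present in only one group are skipped with a warning; BH runs
    within each stratum independently.
    """
    if es_control.features != es_treated.features:
        raise ValueError("feature lists differ between control and treated sets")
    zts_c = set(es_control.samples["zt"])
    zts_t = set(es_treated.samples["zt"])
    shared = sorted(zts_c & zts_t)
    for zt in sorted(zts_c ^ zts_t):
        warnings.warn(f"ZT {zt} present in only one group; stratum skipped")
    out = []
    for zt in shared:
        c_mask = (es_control.samples["zt"] == zt).to_numpy()
        t_mask = (es_treated.samples["zt"] == zt).to_numpy()
        out.append(_deg_core(es_control.values.to_numpy()[:, c_mask],
                             es_treated.values.to_numpy()[:, t_mask],
                             es_control.features, f"{zt:g}",
                             q_threshold, fc_threshold))
    if not out:
        raise ValueError("no shared ZT strata between the groups")
    return pd.concat(out, ignore_index=True)


def robust_degs(per_zt: pd.DataFrame) -> list[str]:
    """Features significant in every ZT stratum with one consistent direction.

    An empty list is a valid outcome (subtle treatments may have no
    time-independent responder at all).
    """
    strata = sorted(per_zt["scope"].unique())
    robust = []
    for feat, sub in per_zt.groupby("feature", sort=False):
        if set(sub["scope"]) != set(strata):
            continue
        if sub["significant"].all() and sub["direction"].nunique() == 1:
            robust.append(feat)
    return robust


def deg_summary(global_table: pd.DataFrame, per_zt: pd.DataFrame) -> pd.DataFrame:
    """Per-scope significant counts plus the robust (all-ZT-consistent) count.

    The tabular equivalent of the Venn/UpSet tallies: one row per scope with
    up/down splits, a ``temporal`` row (significant in >= 1 stratum) and a
    ``robust`` row.
    """
    rows = []
    for scope, sub in pd.concat([global_table, per_zt]).groupby("scope"):
        sig = sub[sub["significant"]]
        rows.append({"scope": scope, "n_significant": len(sig),
                     "n_up": int((sig["direction"] == "up").sum()),
                     "n_down": int((sig["direction"] == "down").sum())})
    temporal = per_zt.loc[per_zt["significant"], "feature"].unique()
    rows.append({"scope": "temporal", "n_significant": len(temporal),
                 "n_up": np.nan, "n_down": np.nan})
    rob = robust_degs(per_zt)
    rows.append({"scope": "robust", "n_significant": len(rob),
                 "n_up": np.nan, "n_down": np.nan})
    return pd.DataFrame(rows)
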