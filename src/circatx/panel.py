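"""Hormone-state "tuning gene" biomarker selection.

A tuning gene reports tissue hormone state at any fixed sampling time: its
expression mesor (rhythm-adjusted mean) moves in *opposite* directions under
the low-hormone and high-hormone states relative to control.  Selection
therefore requires a significant mesor difference in both contrasts
(control vs low, control vs high) with opposite signs.  A stricter
"mesor-only" subset removes genes that also show amplitude or phase
differences in either contrast, avoiding confounding of the state readout
by waveform changes.  Genes are ranked by absolute mesor change within each
contrast and combined by mean rank.

Also provides control-mesor-normalized per-gene-set temporal profiles and
the list-overlap arithmetic used to validate a panel against external gene
sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ExpressionSet

__all__ = [
    "OverlapResult",
    "select_tuning_genes",
    "mesor_only_subset",
    "rank_panel",
    "normalize_to_control_mesor",
    "overlap_score",
]


@dataclass
class OverlapResult:
    n_query: int
    n_reference: int
    n_intersect: int
    percent: float  # 100 * intersect / query


def _indexed(diff: pd.DataFrame) -> pd.DataFrame:
    return diff.set_index("feature")


def select_tuning_genes(diff_low: pd.DataFrame, diff_high: pd.DataFrame,
                        alpha: float = 0.05,
                        min_abs_dmesor: float = 0.0) -> pd.DataFrame:
    """Select dose-consistent mesor responders across the two contrasts.

    ``diff_low`` / ``diff_high`` are batch_compare tables (control vs low,
    control vs high).  A gene is kept when its mesor difference is
    significant at ``alpha`` in BOTH contrasts, the two differences have
    opposite signs, and both exceed ``min_abs_dmesor`` in magnitude.
    """
    lo = _indexed(diff_low)
    hi = _indexed(diff_high)
    only = set(lo.index) ^ set(hi.index)
    if only:
        warnings.warn(f"{len(only)} features present in a single contrast; excluded")
    shared = [f for f in lo.index if f in hi.index]
    lo, hi = lo.loc[shared], hi.loc[shared]
    keep = ((lo["p_mesor"] < alpha) & (hi["p_mesor"] < alpha)
            & (np.sign(lo["dmesor"]) * np.sign(hi["dmesor"]) < 0)
            & (lo["dmesor"].abs() >= min_abs_dmesor)
            & (hi["dmesor"].abs() >= min_abs_dmesor))
    sel = pd.DataFrame({
        "feature": lo.index[keep],
        "dir_low": np.where(lo.loc[keep, "dmesor"] > 0, "up", "down"),
        "dir_high": np.where(hi.loc[keep, "dmesor"] > 0, "up", "down"),
        "dmesor_low": lo.loc[keep, "dmesor"].to_numpy(),
        "dmesor_high": hi.loc[keep, "dmesor"].to_numpy(),
        "mesor_only": False,
    }).reset_index(drop=True)
    return sel


def mesor_only_subset(panel: pd.DataFrame, diff_low: pd.DataFrame,
                      diff_high: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Panel genes with no amplitude or phase difference in either contrast.

    Amplitude must be non-significant (p >= alpha) in both contrasts; phase
    must be non-significant or not comparable (a gene not rhythmic in both
    groups has no testable phase).  Sets ``mesor_only=True`` on the result.
    """
    if panel.empty:
        return panel.copy()
    lo = _indexed(diff_low).loc[panel["feature"]]
    hi = _indexed(diff_high).loc[panel["feature"]]

    def phase_quiet(d):
        return (~d["phase_comparable"].astype(bool)
                | (d["p_phase"].fillna(1.0) >= alpha))

    keep = ((lo["p_amplitude"] >= alpha).to_numpy()
            & (hi["p_amplitude"] >= alpha).to_numpy()
            & phase_quiet(lo).to_numpy() & phase_quiet(hi).to_numpy())
    out = panel.loc[keep].copy().reset_index(drop=True)
    out["mesor_only"] = True
    return out


def rank_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Rank panel genes by absolute mesor change, largest first.

    ``rank_low`` and ``rank_high`` rank |dmesor| within each contrast
    (rank 1 = largest change); ``rank_combined`` is their mean.  The output
    is sorted by rank_combined with ties broken by rank_high, then feature
    id, so the ordering is total and reproducible.
    """
    if panel.empty:
        raise ValueError("cannot rank an empty panel")
    out = panel.copy()
    out["rank_low"] = out["dmesor_low"].abs().rank(ascending=False, method="min").astype(int)
    out["rank_high"] = out["dmesor_high"].abs().rank(ascending=False, method="min").astype(int)
    out["rank_combined"] = (out["rank_low"] + out["rank_high"]) / 2.0
    out = out.sort_values(["rank_combined", "rank_high", "feature"],
                          kind="stable").reset_index(drop=True)
    return out


def normalize_to_control_mesor(es: ExpressionSet, control_fits: pd.DataFrame,
                               gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Mean per-gene-set temporal profiles after control-mesor normalization.

    Each feature's log2 values are centred on its control-group mesor (a
    log2 difference, i.e. a fold change relative to the control midline),
    then averaged per gene set, per group, per timepoint.  ``control_fits``
    is a batch_fit table of the control group.
    """
    mesors = control_fits.set_index("feature")["mesor"]
    rows = []
    for set_id, members in gene_sets.items():
        missing = [m for m in members if m not in mesors.index or m not in es.values.index]
        if missing:
            raise KeyError(f"gene set {set_id!r}: no control fit for {missing[:5]}")
        centred = es.values.loc[members].sub(mesors.loc[members], axis=0)
        meta = es.samples
        for (group, zt), idx in meta.groupby(["group", "zt"]).groups.items():
            cols = meta.loc[idx, "sample_id"]
            rows.append({"set": set_id, "group": group, "zt": zt,
                         "mean_log2_rel": float(centred[cols].to_numpy().mean())})
    return pd.DataFrame(rows)


def overlap_score(query, reference) -> OverlapResult:
    """Exact overlap of two gene lists, percent relative to the query.

    Symbols are deduplicated case-insensitively before counting.
    """
    q = {str(g).lower() for g in query}
    r = {str(g).lower() for g in reference}
    if not q:
        raise ValueError("empty query: overlap percent undefined")
    inter = len(q & r)
    return OverlapResult(len(q), len(r), inter, 100.0 * inter / len(q))
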