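"""Hypergeometric over-representation analysis (ORA) of gene lists.

For a query list of n genes drawn from a universe of N, a gene set covering
K universe genes, and an observed overlap of k, the enrichment p-value is
the upper-tail hypergeometric probability P(X >= k).  Gene-count admission
rules gate which sets enter multiple-testing correction: a set needs an
overlap of at least ``min_count`` genes (default 5), relaxed to
``small_query_min_count`` (default 2) when the query itself is small
(fewer than ``small_query_limit`` genes).  BH correction runs across
admitted sets only.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy.stats import hypergeom

from .jtk import bh_adjust

__all__ = ["read_gmt", "ora"]


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file: set id, description, then member genes, tab-separated."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    return sets


def ora(query, sets: dict, universe, min_count: int = 5,
        small_query_min_count: int = 2, small_query_limit: int = 100) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set against ``universe``.

    ``sets`` maps set id to either a member list or a ``(description,
    members)`` pair as returned by :func:`read_gmt`.  Query genes outside
    the universe are dropped with a warning; set members are intersected
    with the universe before testing.  Returns one row per set sorted by p,
    with the admission flag and BH q-values across admitted sets.
    """
    uni = {str(g).lower() for g in universe}
    if not uni:
        raise ValueError("empty universe")
    q_raw = {str(g).lower() for g in query}
    if not q_raw:
        raise ValueError("empty query")
    stray = q_raw - uni
    if stray:
        warnings.warn(f"{len(stray)} query genes outside the universe; dropped")
    q = q_raw & uni
    if not q:
        raise ValueError("no query gene inside the universe")
    n, N = len(q), len(uni)
    threshold = small_query_min_count if len(q) < small_query_limit else min_count

    rows = []
    for set_id, val in sets.items():
        members = val[1] if isinstance(val, tuple) else val
        s = {str(g).lower() for g in members} & uni
        K = len(s)
        k = len(s & q)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": set_id, "set_size": K, "query_size": n,
                     "universe_size": N, "overlap": k, "p": p,
                     "admitted": k >= threshold})
    out = pd.DataFrame(rows)
    out["q"] = float("nan")
    adm = out["admitted"].to_numpy()
    if adm.any():
        out.loc[adm, "q"] = bh_adjust(out.loc[adm, "p"].to_numpy())
    return out.sort_values("p", kind="stable").reset_index(drop=True)
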