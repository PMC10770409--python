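"""Shared data model and tabular I/O.

The substrate of every analysis stage is an :class:`ExpressionSet`: a
features x samples matrix of log2 expression intensities together with a
per-sample annotation table (group label, Zeitgeber time, replicate).
Zeitgeber time (ZT) is measured in hours after lights-on and lives on the
half-open interval [0, 24); ZT0 is "lights on".

Probe-level arrays can carry several probes per gene and probes that map
ambiguously to more than one gene.  Ambiguous probes are removed before any
gene-level call; unambiguous multi-probe genes are kept distinguishable by
relabelling probes as ``gene::probe``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleSheetError",
    "ExpressionSet",
    "read_sample_sheet",
    "read_expression_set",
    "read_annotation",
    "collapse_to_genes",
    "write_results",
    "read_results",
]

SAMPLE_COLUMNS = ["sample_id", "group", "zt", "replicate"]


class SampleSheetError(ValueError):
    """Raised when a sample sheet or matrix violates the data contract."""


def _validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise SampleSheetError(f"sample sheet missing columns: {missing}")
    samples = samples[SAMPLE_COLUMNS].copy()
    dup = samples["sample_id"][samples["sample_id"].duplicated()]
    if len(dup):
        raise SampleSheetError(f"duplicate sample ids: {sorted(set(dup))}")
    if samples["group"].isna().any() or (samples["group"].astype(str) == "").any():
        raise SampleSheetError("empty group label in sample sheet")
    zt = pd.to_numeric(samples["zt"], errors="coerce")
    if zt.isna().any():
        bad = samples.loc[zt.isna(), "sample_id"].tolist()
        raise SampleSheetError(f"non-numeric zt for samples: {bad}")
    out = (zt < 0) | (zt >= 24)
    if out.any():
        bad = samples.loc[out, ["sample_id", "zt"]].to_dict("records")
        raise SampleSheetError(f"zt outside [0, 24): {bad}")
    samples["zt"] = zt.astype(float)
    samples["replicate"] = pd.to_numeric(samples["replicate"]).astype(int)
    if (samples["replicate"] < 1).any():
        raise SampleSheetError("replicate numbers must be positive integers")
    return samples.reset_index(drop=True)


@dataclass
class ExpressionSet:
    """Log2 expression matrix plus per-sample metadata.

    Parameters
    ----------
    values
        Feature x sample matrix (rows indexed by feature id, columns by
        sample id), log2 scale.  NaN marks missing values.
    samples
        One row per sample with columns ``sample_id, group, zt, replicate``,
        in the same order as the matrix columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = _validate_samples(self.samples)
        if list(self.values.columns) != list(self.samples["sample_id"]):
            # align matrix columns to sheet order; unknown columns are an error
            sheet_ids = list(self.samples["sample_id"])
            mat_ids = list(self.values.columns)
            orphans = sorted(set(mat_ids) ^ set(sheet_ids))
            if orphans:
                raise SampleSheetError(
                    f"samples present in only one of matrix/sheet: {orphans}"
                )
            self.values = self.values[sheet_ids]
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise SampleSheetError(f"duplicate feature ids: {sorted(set(dups))}")
        self.values = self.values.astype(float)

    # -- convenience accessors -------------------------------------------
    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def zt(self) -> np.ndarray:
        """Per-sample Zeitgeber times, aligned with matrix columns."""
        return self.samples["zt"].to_numpy()

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.samples["group"]))

    def subset_group(self, group: str) -> "ExpressionSet":
        mask = (self.samples["group"] == group).to_numpy()
        if not mask.any():
            raise KeyError(f"group {group!r} not present")
        return ExpressionSet(
            self.values.loc[:, mask], self.samples.loc[mask].reset_index(drop=True)
        )

    def subset_features(self, features) -> "ExpressionSet":
        return ExpressionSet(self.values.loc[list(features)], self.samples.copy())


def read_sample_sheet(sheet_path) -> pd.DataFrame:
    return _validate_samples(pd.read_csv(sheet_path))


def read_expression_set(matrix_path, sheet_path) -> ExpressionSet:
    """Read a feature x sample TSV plus its CSV sample sheet.

    The matrix's first column holds feature ids and its header names the
    samples; the sheet must describe exactly the same samples.  The returned
    set follows the sheet's sample order.
    """
    samples = read_sample_sheet(sheet_path)
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    for col in mat.columns:
        coerced = pd.to_numeric(mat[col], errors="coerce")
        bad = coerced.isna() & mat[col].notna() & (mat[col].astype(str).str.strip() != "")
        bad &= ~mat[col].astype(str).str.lower().isin(["nan", "na"])
        if bad.any():
            row = mat.index[bad.to_numpy().argmax()]
            raise SampleSheetError(
                f"non-numeric expression value at feature {row!r}, sample {col!r}"
            )
        mat[col] = coerced
    return ExpressionSet(mat, samples)


def read_annotation(path) -> pd.DataFrame:
    """Read a probe annotation TSV (columns ``probe_id, gene_symbol``).

    Returns one row per probe with an ``ambiguous`` flag: True iff the probe
    maps to more than one distinct gene symbol in the source table.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_symbol"} <= set(raw.columns):
        raise SampleSheetError("annotation needs columns probe_id, gene_symbol")
    n_genes = raw.groupby("probe_id")["gene_symbol"].nunique()
    ann = (
        raw.drop_duplicates("probe_id")
        .set_index("probe_id")[["gene_symbol"]]
        .assign(ambiguous=(n_genes > 1))
    )
    ann["ambiguous"] = ann["ambiguous"].fillna(False)
    return ann.reset_index()


def collapse_to_genes(
    es: ExpressionSet, annotation: pd.DataFrame
) -> tuple[ExpressionSet, pd.DataFrame]:
    """Remove ambiguous probes and relabel the rest as ``gene::probe``.

    Probes mapping to more than one gene are dropped (they cannot support a
    gene-level call); probes of multi-probe genes stay distinguishable via
    the composite label.  Returns the curated set and a report of dropped
    probes with the reason.  Expression values of retained probes are never
    altered.
    """
    ann = annotation.set_index("probe_id")
    unknown = [f for f in es.features if f not in ann.index]
    if unknown:
        raise KeyError(f"probes without annotation: {unknown[:10]}")
    dropped = []
    keep, labels = [], []
    for probe in es.features:
        if bool(ann.at[probe, "ambiguous"]):
            dropped.append({"probe_id": probe, "reason": "ambiguous"})
        else:
            keep.append(probe)
            labels.append(f"{ann.at[probe, 'gene_symbol']}::{probe}")
    report = pd.DataFrame(dropped, columns=["probe_id", "reason"])
    values = es.values.loc[keep].copy()
    values.index = labels
    return ExpressionSet(values, es.samples.copy()), report


def gene_of(feature: str) -> str:
    """Gene symbol of a ``gene::probe`` composite label (identity otherwise)."""
    return feature.split("::", 1)[0]


def gene_level_calls(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate probe-level calls (``gene::probe`` features) to genes.

    A gene is called only when *all* of its called probes agree in
    direction; genes whose probes disagree are flagged discordant and
    excluded from the call (the conservative aggregation when no explicit
    summarisation rule is available).  ``table`` needs columns ``feature``,
    ``significant`` and ``direction``; returns one row per gene with the
    call, direction, probe count and the discordant flag.
    """
    need = {"feature", "significant", "direction"}
    if not need <= set(table.columns):
        raise ValueError(f"gene_level_calls needs columns {sorted(need)}")
    rows = []
    genes = table.assign(gene=table["feature"].map(gene_of))
    for gene, sub in genes.groupby("gene", sort=True):
        sig = sub[sub["significant"]]
        directions = set(sig["direction"])
        discordant = len(directions) > 1
        rows.append({
            "gene": gene,
            "n_probes": len(sub),
            "n_significant_probes": len(sig),
            "discordant": discordant,
            "called": bool(len(sig) == len(sub) and len(sub) > 0 and not discordant),
            "direction": directions.pop() if len(directions) == 1 else "",
        })
    return pd.DataFrame(rows)


FLOAT_FORMAT = "%.6g"


def write_results(table: pd.DataFrame, path, float_format: str = FLOAT_FORMAT,
                  header_comment: str | None = None) -> None:
    """Write a result table as TSV with a deterministic column order.

    Floating values are written at fixed precision so that re-reading
    reproduces them to that precision; an optional ``# comment`` header line
    records provenance (seed, config hash).
    """
    buf = io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    table.to_csv(buf, sep="\t", index=False, float_format=float_format)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
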