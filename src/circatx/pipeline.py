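"""End-to-end orchestration of the analysis stages.

``run_all`` chains: (optional) simulation -> JTK rhythmicity screen per
group -> cosinor batch fits -> differential rhythm comparison per contrast
-> global / per-ZT / robust DEG calling -> tuning-gene panel (selection,
mesor-only subset, ranking) -> optional enrichment -> TSV reports.  Every
output carries the config hash and seed in a header comment so a result
directory is self-describing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cosinor, deg, enrich, jtk, panel
from .datamodel import ExpressionSet, read_expression_set, write_results
from .simulate import SimConfig, simulate_expression

log = logging.getLogger("circatx")

__all__ = ["PipelineConfig", "run_all", "load_config"]


@dataclass
class PipelineConfig:
    """Single structured configuration for the whole pipeline.

    Either ``simulate=True`` (synthetic inputs from ``sim``) or matrix/sheet
    paths per group.  ``groups`` orders (control, low, high); defaults mirror
    the analysis conventions: 24-h period, adjusted-p 0.05 rhythmicity
    cutoff, FDR 0.1 and 1.5-fold DEG gates.
    """

    outdir: str = "results"
    groups: tuple[str, str, str] = ("CON", "MMI", "T3")
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    matrix_paths: dict = field(default_factory=dict)   # group -> matrix TSV
    sheet_paths: dict = field(default_factory=dict)    # group -> sample CSV
    gmt_path: str | None = None
    period: float = 24.0
    rhythm_alpha: float = 0.05
    jtk_adj_alpha: float = 0.05
    q_threshold: float = 0.1
    fc_threshold: float = deg.FC_THRESHOLD_LOG2
    min_abs_dmesor: float = 0.0
    min_count: int = 5
    small_query_min_count: int = 2
    small_query_limit: int = 100
    seed: int = 0

    def validate(self) -> None:
        if len(self.groups) < 3:
            raise ValueError("need control, low and high group labels")
        if not self.simulate:
            for g in self.groups:
                if g not in self.matrix_paths or g not in self.sheet_paths:
                    raise ValueError(f"missing matrix/sheet path for group {g!r}")
                for p in (self.matrix_paths[g], self.sheet_paths[g]):
                    if not Path(p).exists():
                        raise FileNotFoundError(p)
        for name, val, lo, hi in [
            ("rhythm_alpha", self.rhythm_alpha, 0, 1),
            ("jtk_adj_alpha", self.jtk_adj_alpha, 0, 1),
            ("q_threshold", self.q_threshold, 0, 1),
        ]:
            if not (lo < val < hi):
                raise ValueError(f"{name}={val} outside ({lo}, {hi})")

    def hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir", None)  # analysis identity, not output location
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("sim", {})
    cfg = PipelineConfig(**raw)
    if sim_raw:
        cfg.sim = SimConfig(**sim_raw)
    if "groups" in raw:
        cfg.groups = tuple(raw["groups"])
    return cfg


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate:
        cfg.sim.seed = cfg.seed
        cfg.sim.groups = tuple(cfg.groups)
        sets, truth = simulate_expression(cfg.sim)
        return sets, truth
    sets = {g: read_expression_set(cfg.matrix_paths[g], cfg.sheet_paths[g])
            for g in cfg.groups}
    return sets, None


def run_all(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every stage; write all tables under ``cfg.outdir``; return them."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"circatx seed={cfg.seed} config={cfg.hash()}"
    results: dict[str, pd.DataFrame] = {}

    def emit(name: str, table: pd.DataFrame) -> None:
        results[name] = table
        write_results(table, outdir / f"{name}.tsv", header_comment=header)

    control, low, high = cfg.groups[0], cfg.groups[1], cfg.groups[2]
    sets, truth = _load_inputs(cfg)
    if truth is not None:
        emit("ground_truth", truth)
    log.info("loaded %d features, groups %s", sets[control].n_features, cfg.groups)

    # rhythmicity screen per group
    rhythm = []
    for g in cfg.groups:
        t = jtk.jtk_batch(sets[g], cfg.period, adj_alpha=cfg.jtk_adj_alpha)
        t.insert(1, "group", g)
        rhythm.append(t)
        log.info("JTK %s: %d rhythmic / %d", g, int(t["rhythmic"].sum()), len(t))
    emit("rhythmicity", pd.concat(rhythm, ignore_index=True))

    # cosinor fits per group
    fits = {}
    for g in cfg.groups:
        f = cosinor.batch_fit(sets[g], cfg.period)
        f.insert(1, "group", g)
        fits[g] = f
    emit("cosinor_fits", pd.concat(fits.values(), ignore_index=True))

    # differential rhythm per contrast
    diff = {}
    for name, g in (("low", low), ("high", high)):
        d = cosinor.batch_compare(sets[control], sets[g], cfg.period,
                                  cfg.rhythm_alpha)
        diff[name] = d
        n_mes = int((d["p_mesor"] < cfg.rhythm_alpha).sum())
        n_amp = int((d["p_amplitude"] < cfg.rhythm_alpha).sum())
        n_ph = int((d["p_phase"] < cfg.rhythm_alpha).sum())
        log.info("compare %s vs %s: mesor %d, amplitude %d, phase %d",
                 control, g, n_mes, n_amp, n_ph)
        emit(f"diff_rhythm_{name}", d)

    # DEG analysis per contrast
    per_zt = {}
    for name, g in (("low", low), ("high", high)):
        gl = deg.global_deg(sets[control], sets[g], cfg.q_threshold,
                            cfg.fc_threshold)
        pz = deg.per_zt_deg(sets[control], sets[g], cfg.q_threshold,
                            cfg.fc_threshold)
        per_zt[name] = pz
        emit(f"deg_global_{name}", gl)
        emit(f"deg_per_zt_{name}", pz)
        emit(f"deg_summary_{name}", deg.deg_summary(gl, pz))
        log.info("DEG %s: global %d, robust %d", name,
                 int(gl["significant"].sum()), len(deg.robust_degs(pz)))

    # tuning panel
    sel = panel.select_tuning_genes(diff["low"], diff["high"],
                                    cfg.rhythm_alpha, cfg.min_abs_dmesor)
    log.info("tuning panel: %d genes", len(sel))
    emit("panel", sel)
    monly = panel.mesor_only_subset(sel, diff["low"], diff["high"], cfg.rhythm_alpha)
    emit("panel_mesor_only", monly)
    if len(sel):
        emit("panel_ranked", panel.rank_panel(sel))
    else:
        emit("panel_ranked", sel)

    # enrichment of the panel against optional gene sets
    if cfg.gmt_path:
        sets_gmt = enrich.read_gmt(cfg.gmt_path)
        universe = sets[control].features
        if len(sel):
            emit("enrichment", enrich.ora(sel["feature"], sets_gmt, universe,
                                          cfg.min_count, cfg.small_query_min_count,
                                          cfg.small_query_limit))
    return results
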