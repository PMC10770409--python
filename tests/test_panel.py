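import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circatx.cosinor import batch_compare, batch_fit
from circatx.panel import (mesor_only_subset, normalize_to_control_mesor,
                           overlap_score, rank_panel, select_tuning_genes)
from circatx.simulate import SimConfig, simulate_expression


def diff_table(rows):
    """Minimal batch_compare-like table from (feature, dmesor, p_mesor,
    p_amp, p_phase, comparable) tuples."""
    return pd.DataFrame([{
        "feature": f, "dmesor": dm, "p_mesor": pm, "damplitude": 0.0,
        "p_amplitude": pa, "dphase": 0.0, "p_phase": pp,
        "phase_comparable": comp,
    } for f, dm, pm, pa, pp, comp in rows])


class TestSelectTuningGenes:
    def test_opposite_direction_required(self):
        low = diff_table([("g1", -0.8, 0.001, 0.5, 0.5, True),
                          ("g2", 0.8, 0.001, 0.5, 0.5, True)])
        high = diff_table([("g1", 0.8, 0.001, 0.5, 0.5, True),
                          ("g2", 0.8, 0.001, 0.5, 0.5, True)])
        sel = select_tuning_genes(low, high)
        assert list(sel["feature"]) == ["g1"]
        assert sel.loc[0, "dir_low"] == "down" and sel.loc[0, "dir_high"] == "up"

    def test_significance_needed_in_both_contrasts(self):
        low = diff_table([("g1", -0.8, 0.2, 0.5, 0.5, True)])
        high = diff_table([("g1", 0.8, 0.001, 0.5, 0.5, True)])
        assert select_tuning_genes(low, high).empty

    def test_contrast_swap_antisymmetry(self):
        low = diff_table([("g1", -0.8, 0.001, 0.5, 0.5, True),
                          ("g2", 0.5, 0.01, 0.5, 0.5, True)])
        high = diff_table([("g1", 0.8, 0.001, 0.5, 0.5, True),
                           ("g2", -0.5, 0.01, 0.5, 0.5, True)])
        a = select_tuning_genes(low, high)
        b = select_tuning_genes(high, low)
        assert set(a["feature"]) == set(b["feature"])
        ga = a.set_index("feature")
        gb = b.set_index("feature")
        assert (ga["dir_low"] == gb["dir_high"]).all()

    def test_min_abs_dmesor_gate(self):
        low = diff_table([("g1", -0.2, 0.001, 0.5, 0.5, True)])
        high = diff_table([("g1", 0.9, 0.001, 0.5, 0.5, True)])
        assert select_tuning_genes(low, high, min_abs_dmesor=0.3).empty
        assert len(select_tuning_genes(low, high, min_abs_dmesor=0.0)) == 1


class TestMesorOnlySubset:
    def test_amplitude_or_phase_change_removed(self):
        low = diff_table([("g1", -0.8, 0.001, 0.5, 0.5, True),
                          ("g2", -0.8, 0.001, 0.5, 0.5, True)])
        high = diff_table([("g1", 0.8, 0.001, 0.5, 0.01, True),  # phase hit
                           ("g2", 0.8, 0.001, 0.5, 0.5, True)])
        panel = select_tuning_genes(low, high)
        only = mesor_only_subset(panel, low, high)
        assert list(only["feature"]) == ["g2"]
        assert only["mesor_only"].all()

    def test_non_comparable_phase_counts_as_quiet(self):
        low = diff_table([("g1", -0.8, 0.001, 0.5, np.nan, False)])
        high = diff_table([("g1", 0.8, 0.001, 0.5, np.nan, False)])
        panel = select_tuning_genes(low, high)
        assert len(mesor_only_subset(panel, low, high)) == 1

    def test_empty_panel_passthrough(self):
        low = diff_table([("g1", -0.8, 0.9, 0.5, 0.5, True)])
        high = diff_table([("g1", 0.8, 0.9, 0.5, 0.5, True)])
        panel = select_tuning_genes(low, high)
        assert mesor_only_subset(panel, low, high).empty


class TestRankPanel:
    def _panel(self, pairs):
        return pd.DataFrame([{
            "feature": f, "dir_low": "down", "dir_high": "up",
            "dmesor_low": -lo, "dmesor_high": hi, "mesor_only": False,
        } for f, lo, hi in pairs])

    def test_dominant_gene_ranks_first(self):
        ranked = rank_panel(self._panel([("a", 1.0, 1.0), ("b", 0.5, 0.5)]))
        assert list(ranked["feature"]) == ["a", "b"]
        assert ranked.loc[0, "rank_combined"] == 1.0

    def test_tie_broken_by_high_contrast_rank(self):
        # A: ranks (1, 4); B: ranks (3, 2) -> both mean 2.5, B first
        panel = self._panel([("A", 1.0, 0.2), ("B", 0.6, 0.8),
                             ("C", 0.8, 0.9), ("D", 0.4, 0.3)])
        ranked = rank_panel(panel).set_index("feature")
        assert ranked.loc["A", "rank_combined"] == ranked.loc["B", "rank_combined"] == 2.5
        assert list(rank_panel(panel)["feature"])[1:3] == ["B", "A"]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(3)
        pairs = [(f"g{i}", rng.uniform(0.1, 2), rng.uniform(0.1, 2))
                 for i in range(100)]
        ranked = rank_panel(self._panel(pairs))
        # oracle: explicit sort on (mean rank, high rank, feature)
        lows = sorted((-abs(lo), f) for f, lo, hi in pairs)
        highs = sorted((-abs(hi), f) for f, lo, hi in pairs)
        rl = {f: i + 1 for i, (_, f) in enumerate(lows)}
        rh = {f: i + 1 for i, (_, f) in enumerate(highs)}
        oracle = sorted(pairs, key=lambda t: ((rl[t[0]] + rh[t[0]]) / 2,
                                              rh[t[0]], t[0]))
        assert list(ranked["feature"]) == [f for f, _, _ in oracle]

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            rank_panel(self._panel([]))


class TestNormalizeToControlMesor:
    def test_constant_at_mesor_maps_to_zero(self, small_sim):
        _, sets, _ = small_sim
        es = sets["CON"]
        fits = batch_fit(es)
        feat = es.features[0]
        es2 = es.subset_features([feat])
        mesor = fits.set_index("feature").loc[feat, "mesor"]
        es2.values.loc[feat] = mesor
        prof = normalize_to_control_mesor(es2, fits, {"s": [feat]})
        np.testing.assert_allclose(prof["mean_log2_rel"], 0.0, atol=1e-9)

    def test_coordinated_shift_appears_as_flat_offset(self):
        cfg = SimConfig(n_features=10, n_mesor_up=10, groups=("CON", "MMI"),
                        noise_sd=0.05, mesor_effect=0.5, frac_rhythmic=0.0,
                        amp_range=(0.0, 0.0), seed=13)
        sets, _ = simulate_expression(cfg)
        fits = batch_fit(sets["CON"])
        prof = normalize_to_control_mesor(sets["MMI"], fits,
                                          {"set": sets["MMI"].features})
        assert abs(prof["mean_log2_rel"].mean() - 0.5) < 0.05
        assert prof["mean_log2_rel"].std() < 0.1


class TestOverlapScore:
    def test_published_style_arithmetic(self):
        query = [f"q{i}" for i in range(224)]
        ref = query[:161] + [f"r{i}" for i in range(500)]
        res = overlap_score(query, ref)
        assert res.n_intersect == 161
        assert round(res.percent, 1) == 71.9

    def test_disjoint_and_subset(self):
        assert overlap_score(["a"], ["b"]).percent == 0.0
        assert overlap_score(["a", "b"], ["a", "b", "c"]).percent == 100.0

    def test_case_insensitive_dedup(self):
        res = overlap_score(["Gene1", "gene1", "GENE2"], ["gene1"])
        assert res.n_query == 2 and res.n_intersect == 1

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            overlap_score([], ["a"])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)))
    def test_matches_set_arithmetic(self, q, r):
        if not q:
            return
        res = overlap_score([str(x) for x in q], [str(x) for x in r])
        assert res.n_intersect == len(q & r)
        assert res.percent == pytest.approx(100 * len(q & r) / len(q))
        assert res.n_intersect <= min(res.n_query, res.n_reference)


def test_end_to_end_panel_on_planted_truth(small_sim):
    """Planted opposite-mesor genes are recovered; a planted extra phase
    confound is removed by the mesor-only filter."""
    _, sets, truth = small_sim
    low = batch_compare(sets["CON"], sets["MMI"])
    high = batch_compare(sets["CON"], sets["T3"])
    sel = select_tuning_genes(low, high)
    planted = set(truth.loc[truth["planted_class"] == "tuning_opposite", "feature"])
    assert len(planted & set(sel["feature"])) / len(planted) >= 0.8
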