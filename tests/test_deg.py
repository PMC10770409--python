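import numpy as np
import pandas as pd
import pytest

from circatx.deg import (FC_THRESHOLD_LOG2, deg_summary, global_deg, per_zt_deg,
                         robust_degs)
from circatx.simulate import SimConfig, simulate_expression


@pytest.fixture(scope="module")
def shifted_pair():
    """CON + MMI with 20 planted +/-1.0 log2 mesor shifts among 300 genes."""
    cfg = SimConfig(n_features=300, n_mesor_up=10, n_mesor_down=10,
                    groups=("CON", "MMI"), noise_sd=0.2, frac_rhythmic=0.0,
                    mesor_effect=1.0, seed=21)
    sets, truth = simulate_expression(cfg)
    return sets["CON"], sets["MMI"], truth


class TestGlobalDeg:
    def test_planted_shift_detected_with_direction(self, shifted_pair):
        con, mmi, truth = shifted_pair
        res = global_deg(con, mmi)
        merged = res.merge(truth, on="feature")
        up = merged[merged["planted_class"] == "mesor_up"]
        down = merged[merged["planted_class"] == "mesor_down"]
        assert up["significant"].all() and (up["direction"] == "up").all()
        assert down["significant"].all() and (down["direction"] == "down").all()

    def test_null_features_controlled(self, shifted_pair):
        con, mmi, truth = shifted_pair
        res = global_deg(con, mmi).merge(truth, on="feature")
        nulls = res[res["planted_class"] == "null_flat"]
        assert nulls["significant"].mean() <= 0.02

    def test_fold_change_gate_blocks_small_effects(self, times_4rep):
        """q tiny but |log2FC| < 0.58 must not be called significant."""
        rng = np.random.default_rng(1)
        n = 200
        vals0 = pd.DataFrame(rng.normal(5, 0.02, (3, n)),
                             index=["a", "b", "c"],
                             columns=[f"c{i}" for i in range(n)])
        vals1 = vals0.copy()
        vals1.columns = [f"t{i}" for i in range(n)]
        vals1.loc["a"] += 0.30  # precise but sub-threshold shift
        meta0 = pd.DataFrame({"sample_id": vals0.columns, "group": "CON",
                              "zt": 2.0, "replicate": range(1, n + 1)})
        meta1 = pd.DataFrame({"sample_id": vals1.columns, "group": "T",
                              "zt": 2.0, "replicate": range(1, n + 1)})
        from circatx.datamodel import ExpressionSet
        res = global_deg(ExpressionSet(vals0, meta0), ExpressionSet(vals1, meta1))
        row = res.set_index("feature").loc["a"]
        assert row["q"] < 1e-6
        assert 0.25 < abs(row["log2fc"]) < FC_THRESHOLD_LOG2
        assert not row["significant"]

    def test_label_swap_negates_log2fc(self, shifted_pair):
        con, mmi, _ = shifted_pair
        a = global_deg(con, mmi)
        b = global_deg(mmi, con)
        np.testing.assert_allclose(a["log2fc"], -b["log2fc"], atol=1e-12)
        np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)

    def test_pure_null_respects_fdr(self):
        cfg = SimConfig(n_features=1000, groups=("CON", "MMI"), noise_sd=0.2,
                        frac_rhythmic=0.0, seed=9)
        sets, _ = simulate_expression(cfg)
        res = global_deg(sets["CON"], sets["MMI"])
        assert res["significant"].mean() <= 0.1


class TestPerZtDeg:
    def test_effect_at_single_zt_localized(self):
        cfg = SimConfig(n_features=50, groups=("CON", "MMI"), noise_sd=0.1,
                        frac_rhythmic=0.0, seed=31)
        sets, _ = simulate_expression(cfg)
        con, mmi = sets["CON"], sets["MMI"]
        target = mmi.values.index[0]
        mask = (mmi.samples["zt"] == 14.0).to_numpy()
        mmi.values.loc[target, mask] += 2.0
        res = per_zt_deg(con, mmi)
        hit = res[(res["feature"] == target) & res["significant"]]
        assert list(hit["scope"]) == ["14"]

    def test_always_different_gene_significant_in_all_strata(self):
        cfg = SimConfig(n_features=100, n_mesor_up=5, groups=("CON", "MMI"),
                        noise_sd=0.1, frac_rhythmic=0.0, mesor_effect=2.0,
                        seed=41)
        sets, truth = simulate_expression(cfg)
        res = per_zt_deg(sets["CON"], sets["MMI"])
        planted = truth.loc[truth["planted_class"] == "mesor_up", "feature"]
        sub = res[res["feature"].isin(planted)]
        assert sub.groupby("feature")["significant"].all().all()
        # union of per-ZT calls covers all 6 strata for each planted gene
        assert sub.groupby("feature")["scope"].nunique().eq(6).all()

    def test_single_sample_stratum_untestable(self):
        cfg = SimConfig(n_features=10, groups=("CON", "MMI"),
                        rep_overrides={("MMI", 6.0): 1}, seed=2)
        sets, _ = simulate_expression(cfg)
        res = per_zt_deg(sets["CON"], sets["MMI"])
        z6 = res[res["scope"] == "6"]
        assert (~z6["testable"]).all()
        assert not z6["significant"].any()


class TestRobustDegs:
    def _table(self, spec):
        # spec: feature -> list of (scope, significant, direction)
        rows = []
        for feat, entries in spec.items():
            for scope, sig, d in entries:
                rows.append({"feature": feat, "scope": scope,
                             "significant": sig, "direction": d})
        return pd.DataFrame(rows)

    def test_all_strata_consistent_included(self):
        t = self._table({"g1": [(str(z), True, "up") for z in range(6)]})
        assert robust_degs(t) == ["g1"]

    def test_five_of_six_excluded(self):
        entries = [(str(z), True, "up") for z in range(5)] + [("5", False, "up")]
        t = self._table({"g1": entries})
        assert robust_degs(t) == []

    def test_direction_flip_excluded(self):
        entries = [(str(z), True, "up") for z in range(3)] \
            + [(str(z), True, "down") for z in range(3, 6)]
        t = self._table({"g1": entries})
        assert robust_degs(t) == []

    def test_matches_brute_force_intersection(self, shifted_pair):
        con, mmi, _ = shifted_pair
        per_zt = per_zt_deg(con, mmi)
        # oracle: set intersection over strata of consistently-directed calls
        strata = sorted(per_zt["scope"].unique())
        per_stratum = []
        for z in strata:
            sub = per_zt[(per_zt["scope"] == z) & per_zt["significant"]]
            per_stratum.append({(f, d) for f, d in zip(sub["feature"], sub["direction"])})
        oracle = set.intersection(*per_stratum)
        assert set(robust_degs(per_zt)) == {f for f, _ in oracle}
        # robust set is contained in the union of stratum calls
        union = set.union(*per_stratum)
        assert {(f,) for f, _ in oracle} <= {(f,) for f, _ in union}


def test_summary_counts_are_set_arithmetic(shifted_pair):
    con, mmi, _ = shifted_pair
    gl = global_deg(con, mmi)
    pz = per_zt_deg(con, mmi)
    summ = deg_summary(gl, pz).set_index("scope")
    assert summ.loc["global", "n_significant"] == gl["significant"].sum()
    temporal = pz.loc[pz["significant"], "feature"].nunique()
    assert summ.loc["temporal", "n_significant"] == temporal
    assert summ.loc["robust", "n_significant"] == len(robust_degs(pz))
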