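import numpy as np
import pandas as pd
import pytest
from scipy import stats

import synfact as sf
from synfact.de import contrast_de, overlap_summary

from conftest import expression_from_arm_means


def welch_oracle(x, y):
    """Hand-coded Welch t-test (two-sided) for one gene."""
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return 2 * stats.t.sf(abs(t), df)


class TestContrastDe:
    def test_identical_groups_give_zero_fc_no_deg(self):
        em, design = expression_from_arm_means([[5.0, 5.0, 7.0, 7.0]])
        res = contrast_de(em, design, "uvssr")
        assert res.loc["g0", "log2fc"] == 0.0
        assert not res.loc["g0", "is_deg"]

    def test_planted_strong_effect_called(self):
        # a small planted fraction keeps CPM library-composition shifts tiny
        cfg = sf.SimulationConfig(
            n_genes=500,
            dispersion=1e-6,
            effect_size_log2=3.0,
            component_fractions={"null": 0.98, "coop_up_concordant": 0.02},
            seed=2,
        )
        cm, design, truth = sf.simulate_counts(cfg)
        em = sf.log_cpm(cm)
        res = contrast_de(em, design, "uvssr")
        planted = truth.index[truth["component"] == "coop_up_concordant"]
        assert res.loc[planted, "is_deg"].all()

    def test_pvalues_match_welch_oracle(self):
        rng = np.random.default_rng(0)
        arm_means = rng.normal(5, 1, size=(2, 4))
        em, design = expression_from_arm_means(arm_means, noise_sd=0.5, seed=1)
        res = contrast_de(em, design, "ozone")
        x = em.values[:, design.arm_mask(0, 1)]
        y = em.values[:, design.arm_mask(0, 0)]
        for g in range(2):
            assert res["p_value"].iloc[g] == pytest.approx(
                welch_oracle(x[g], y[g]), abs=1e-12
            )

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(4)
        em, design = expression_from_arm_means(
            rng.normal(5, 1, size=(5, 4)), noise_sd=0.3, seed=2
        )
        res = contrast_de(em, design, "co")
        flipped = em.values.copy()
        co, ctrl = design.arm_mask(1, 1), design.arm_mask(0, 0)
        flipped[:, co], flipped[:, ctrl] = em.values[:, ctrl], em.values[:, co]
        em2 = sf.ExpressionMatrix(em.gene_ids, em.sample_ids, flipped)
        res2 = contrast_de(em2, design, "co")
        np.testing.assert_allclose(res2["log2fc"], -res["log2fc"], atol=1e-12)
        np.testing.assert_allclose(res2["p_value"], res["p_value"], atol=1e-12)

    def test_deg_flag_is_pure_function_of_cutoffs(self):
        rng = np.random.default_rng(5)
        em, design = expression_from_arm_means(
            rng.normal(5, 2, size=(50, 4)), noise_sd=0.5, seed=3
        )
        res = contrast_de(em, design, "uvssr", p_cut=0.1, fc_cut=1.5)
        expected = (res["p_value"] < 0.1) & (res["log2fc"].abs() > np.log2(1.5))
        assert (res["is_deg"] == expected).all()

    def test_null_not_anticonservative(self):
        """Welch at n=3 is conservative; type-I error must not exceed nominal."""
        cfg = sf.SimulationConfig(
            n_genes=4000, component_fractions={"null": 1.0}, seed=13
        )
        cm, design, _ = sf.simulate_counts(cfg)
        em = sf.log_cpm(sf.filter_low_expression(cm))
        res = contrast_de(em, design, "uvssr")
        type1 = (res["p_value"] < 0.05).mean()
        assert 0.02 < type1 < 0.06

    def test_unknown_arm_rejected(self):
        em, design = expression_from_arm_means([[1.0, 2, 3, 4]])
        with pytest.raises(ValueError, match="arm"):
            contrast_de(em, design, "control")


class TestOverlapSummary:
    @staticmethod
    def _fake(genes, degs):
        return pd.DataFrame(
            {"log2fc": 0.0, "p_value": 1.0, "is_deg": [g in degs for g in genes]},
            index=pd.Index(genes, name="gene_id"),
        )

    def test_no_degs_all_zero(self):
        genes = [f"g{i}" for i in range(5)]
        res = {a: self._fake(genes, set()) for a in ("uvssr", "ozone", "co")}
        assert (overlap_summary(res) == 0).all()

    def test_identical_sets_only_triple(self):
        genes = [f"g{i}" for i in range(6)]
        degs = {"g1", "g3"}
        res = {a: self._fake(genes, degs) for a in ("uvssr", "ozone", "co")}
        out = overlap_summary(res)
        assert out["uvssr&ozone&co"] == 2
        assert out["union"] == 2
        assert out.drop(["uvssr&ozone&co", "union"]).eq(0).all()

    def test_matches_bruteforce_set_arithmetic(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(40)]
        sets = {
            a: {g for g in genes if rng.random() < 0.3}
            for a in ("uvssr", "ozone", "co")
        }
        res = {a: self._fake(genes, s) for a, s in sets.items()}
        out = overlap_summary(res)
        u, o, c = sets["uvssr"], sets["ozone"], sets["co"]
        assert out["uvssr"] == len(u - o - c)
        assert out["uvssr&ozone"] == len((u & o) - c)
        assert out["uvssr&ozone&co"] == len(u & o & c)
        assert out["union"] == len(u | o | c)
        regions = out.drop("union")
        assert regions.sum() == out["union"]

    def test_mismatched_universe_rejected(self):
        res = {
            "uvssr": self._fake(["g1", "g2"], set()),
            "ozone": self._fake(["g1", "g3"], set()),
            "co": self._fake(["g1", "g2"], set()),
        }
        with pytest.raises(ValueError, match="universe"):
            overlap_summary(res)
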