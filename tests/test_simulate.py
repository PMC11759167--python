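import numpy as np
import pandas as pd
import pytest

import synfact as sf
from synfact.components import COMPONENTS, classify_gene
from synfact.simulate import (
    ComponentRealizabilityError,
    SimulationConfig,
    _assign_components,
    default_component_fractions,
    simulate_counts,
    simulate_phenotype,
)


class TestConfigValidation:
    def test_bad_fraction_sum_rejected(self):
        cfg = SimulationConfig(component_fractions={"null": 0.5})
        with pytest.raises(ValueError, match="sum"):
            cfg.validate()

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            SimulationConfig(replicates_per_arm=1).validate()

    def test_unrealizable_component_named_in_error(self):
        cfg = SimulationConfig(
            component_fractions={"null": 0.5, "coop_up_discordant": 0.5},
            interaction_size_log2=0.0,
        )
        with pytest.raises(ComponentRealizabilityError, match="coop_up_discordant"):
            cfg.validate()


class TestComponentAssignment:
    def test_exact_proportions(self):
        counts = _assign_components(default_component_fractions(0.2), 2000)
        assert counts["null"] == 1600
        assert all(counts[c] == 50 for c in COMPONENTS)

    def test_largest_remainder_fills_shortfall(self):
        counts = _assign_components({"null": 1 / 3, "coop_up_concordant": 2 / 3}, 10)
        assert sum(counts.values()) == 10
        assert counts == {"coop_up_concordant": 7, "null": 3}


class TestSimulateCounts:
    def test_pure_null_truth_all_zero_and_equal_arm_means(self):
        cfg = SimulationConfig(
            n_genes=50, component_fractions={"null": 1.0}, dispersion=1e-6, seed=3
        )
        cm, design, truth = simulate_counts(cfg)
        assert (truth[["a", "b", "c"]] == 0).all().all()
        arm_means = {
            (u, o): cm.counts[:, design.arm_mask(u, o)].mean(axis=1)
            for u, o in [(0, 0), (1, 0), (0, 1), (1, 1)]
        }
        base = arm_means[(0, 0)]
        for key, m in arm_means.items():
            np.testing.assert_allclose(m, base, rtol=0.05)

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(n_genes=100, seed=9)
        a = simulate_counts(cfg)
        b = simulate_counts(cfg)
        np.testing.assert_array_equal(a[0].counts, b[0].counts)
        pd.testing.assert_frame_equal(a[1].table, b[1].table)
        pd.testing.assert_frame_equal(a[2], b[2])

    @pytest.mark.parametrize("seed", [1, 2])
    def test_low_dispersion_recovers_planted_effects(self, seed):
        """Empirical arm-mean log2 ratios approach (a, b, a+b+c) as noise -> 0."""
        cfg = SimulationConfig(n_genes=200, dispersion=1e-6, seed=seed)
        cm, design, truth = simulate_counts(cfg)
        counts = cm.counts.astype(float)
        means = {
            arm: counts[:, design.arm_mask(u, o)].mean(axis=1)
            for arm, (u, o) in [("ctrl", (0, 0)), ("uv", (1, 0)), ("o3", (0, 1)), ("co", (1, 1))]
        }
        nonnull = truth["component"] != "null"
        for arm, planted in [
            ("uv", truth["a"]),
            ("o3", truth["b"]),
            ("co", truth["a"] + truth["b"] + truth["c"]),
        ]:
            ratio = np.log2(means[arm] / means["ctrl"])
            np.testing.assert_allclose(
                ratio[nonnull], planted[nonnull], atol=0.1
            )

    def test_true_effects_classify_to_assigned_component(self):
        cfg = SimulationConfig(n_genes=400, seed=5)
        _, _, truth = simulate_counts(cfg)
        nonnull = truth[truth["component"] != "null"]
        assert len(nonnull) == 80
        for _, row in nonnull.iterrows():
            lab = classify_gene(row["a"], row["b"], row["a"] + row["b"] + row["c"])
            assert lab.component == row["component"]

    def test_library_jitter_changes_depths(self):
        cfg = SimulationConfig(n_genes=100, library_jitter_sd=0.5, seed=4)
        cm, _, _ = simulate_counts(cfg)
        depths = cm.counts.sum(axis=0)
        assert depths.std() / depths.mean() > 0.1


class TestSimulatePhenotype:
    def test_degenerate_noise_pins_values_to_means(self):
        ph = simulate_phenotype((60, 55, 55, 50), sd=1e-12, replicates=5, seed=0)
        for arm, mean in zip(("control", "uvssr", "ozone", "co"), (60, 55, 55, 50)):
            np.testing.assert_allclose(ph.arm_values(arm), mean, atol=1e-6)
        assert all(len(ph.arm_values(a)) == 5 for a in ("control", "uvssr", "ozone", "co"))

    def test_determinism(self):
        a = simulate_phenotype((60, 55, 55, 50), sd=0.5, replicates=5, seed=8)
        b = simulate_phenotype((60, 55, 55, 50), sd=0.5, replicates=5, seed=8)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_separated_arms_flagged_downstream(self):
        """Large separation vs noise makes co vs single arms significant."""
        hits = 0
        for seed in range(5):
            ph = simulate_phenotype((60, 55, 55, 48), sd=0.5, replicates=5, seed=seed)
            res = sf.anova_tukey(ph)
            pairs = res.tukey.set_index(["arm_1", "arm_2"])
            co_pairs = pairs[
                (pairs.index.get_level_values(0) == "co")
                | (pairs.index.get_level_values(1) == "co")
            ]
            hits += int(co_pairs["significant"].all())
        assert hits == 5

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_phenotype((1, 2, 3, 4), sd=0.0)
        with pytest.raises(ValueError):
            simulate_phenotype((1, 2, 3, 4), sd=1.0, replicates=1)
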