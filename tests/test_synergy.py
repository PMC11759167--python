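import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synfact.components import classify_all
from synfact.factorial import add_gate, fit_factorial
from synfact.synergy import (
    format_synergy_table,
    select_synergy_genes,
    synergy_score,
)

from conftest import expression_from_arm_means

nonzero_fc = st.floats(-8, 8, allow_nan=False).filter(lambda x: abs(x) > 1e-6)


class TestSynergyScore:
    def test_perfect_additivity_scores_zero(self):
        score, raw = synergy_score(1.5, -0.5, 1.0)
        assert raw == pytest.approx(1.0)
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula_evaluation(self):
        score, raw = synergy_score(1.0, 1.0, 4.0)
        assert (score, raw) == (1.0, 2.0)

    def test_table_row_rendering(self):
        records = pd.DataFrame(
            {
                "component": ["Ozone-dominant"],
                "score": [3.5111],
                "raw_ratio": [2.0**3.5111],
                "is_synergy": [True],
                "main_effect_fc": [2.0],
                "main_effect_p": [0.01],
            },
            index=pd.Index(["APAF1"], name="gene_id"),
        )
        assert "APAF1\tOzone-dominant\t3.51" in format_synergy_table(records)

    def test_cancelling_singles_flagged_infinite(self):
        with pytest.warns(RuntimeWarning, match="infinite"):
            score, raw = synergy_score(1.0, -1.0, 2.0)
        assert score == math.inf and raw == math.inf

    def test_zero_co_effect_gives_minus_inf(self):
        score, raw = synergy_score(1.0, 1.0, 0.0)
        assert score == -math.inf and raw == 0.0

    @given(nonzero_fc, nonzero_fc, nonzero_fc, st.floats(0.1, 10))
    @settings(max_examples=300, derandomize=True)
    def test_scale_invariance_and_symmetry(self, u, o, c, k):
        if abs(u + o) < 1e-6:
            return
        s1, r1 = synergy_score(u, o, c)
        s2, r2 = synergy_score(k * u, k * o, k * c)
        assert r2 == pytest.approx(r1, rel=1e-9)
        assert s2 == pytest.approx(s1, rel=1e-9, abs=1e-9)
        s3, _ = synergy_score(o, u, c)
        assert s3 == pytest.approx(s1, rel=1e-12, abs=1e-12)

    @given(nonzero_fc, nonzero_fc, nonzero_fc)
    @settings(max_examples=300, derandomize=True)
    def test_variant_consistency(self, u, o, c):
        if abs(u + o) < 1e-6:
            return
        log_score, _ = synergy_score(u, o, c, variant="log2_ratio")
        abs_score, _ = synergy_score(u, o, c, variant="abs_ratio")
        assert (log_score > 0) == (abs_score > 1)


def _run_selection(**kwargs):
    """Fixture pipeline: one strong super-additive ozone-dominant gene plus
    an additive gene and a sub-additive gene."""
    arm_means = np.array(
        [
            [5.0, 6.0, 4.0, 8.0],  # uv +1, o3 -1, co +3: competitive, super-additive
            [5.0, 6.0, 5.5, 6.5],  # additive: co = a + b
            [5.0, 7.0, 7.0, 7.5],  # cooperative, strongly sub-additive
        ]
    )
    em, design = expression_from_arm_means(arm_means, noise_sd=0.05, seed=9)
    fits = add_gate(fit_factorial(em, design), alpha=0.2)
    labels = classify_all(fits, gated_only=True)
    return fits, labels, select_synergy_genes(fits, labels, **kwargs)


class TestSelection:
    def test_planted_superadditive_dominant_gene_selected(self):
        fits, labels, records = _run_selection()
        assert labels.loc["g0", "submode"] == "uvssr_dominant"
        assert records.loc["g0", "is_synergy"]
        assert records.loc["g0", "score"] > 0

    def test_additive_gene_excluded_regardless_of_significance(self):
        _, _, records = _run_selection()
        assert "g1" not in records.index or not records.loc["g1", "is_synergy"]
        if "g1" in records.index:
            assert abs(records.loc["g1", "score"]) < 0.2

    def test_zero_p_cut_selects_nothing(self):
        _, _, records = _run_selection(p_cut=0.0)
        assert not records["is_synergy"].any()

    def test_records_sorted_by_descending_score(self, mixture_run):
        *_, fits = mixture_run
        labels = classify_all(fits, gated_only=True)
        records = select_synergy_genes(fits, labels)
        finite = records["score"][np.isfinite(records["score"])]
        assert (finite.diff().dropna() <= 1e-12).all()

    def test_selection_monotone_in_thresholds(self, mixture_run):
        *_, fits = mixture_run
        labels = classify_all(fits, gated_only=True)
        base = select_synergy_genes(fits, labels, p_cut=0.05, fc_cut=1.2)
        stricter_fc = select_synergy_genes(fits, labels, p_cut=0.05, fc_cut=2.0)
        stricter_p = select_synergy_genes(fits, labels, p_cut=0.01, fc_cut=1.2)
        base_set = set(base.index[base["is_synergy"]])
        assert set(stricter_fc.index[stricter_fc["is_synergy"]]) <= base_set
        assert set(stricter_p.index[stricter_p["is_synergy"]]) <= base_set

    def test_co_effect_rule_variant(self, mixture_run):
        *_, fits = mixture_run
        labels = classify_all(fits, gated_only=True)
        records = select_synergy_genes(fits, labels, main_rule="co_effect")
        sel = records[records["is_synergy"]]
        for gene in sel.index:
            assert fits.loc[gene, "p_c"] < 0.05
            assert abs(fits.loc[gene, "co_effect"]) > math.log2(1.2)
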