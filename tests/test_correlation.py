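import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import tfotf
from tfotf.correlation import (
    REASON_INSUFFICIENT,
    REASON_ZERO_VARIANCE,
    UndefinedCorrelation,
)
from tfotf.io import ExpressionMatrix, LookupError_


def make_expr(rows: dict, groups: dict) -> ExpressionMatrix:
    frame = pd.DataFrame(rows).T
    frame.columns = list(groups)
    return ExpressionMatrix(frame, groups)


class TestPearsonR:
    def test_identity_and_anticorrelation(self):
        assert tfotf.pearson_r([1, 2, 3], [1, 2, 3]) == 1.0
        assert tfotf.pearson_r([1, 2, 3], [6, 4, 2]) == -1.0

    def test_closed_form_value(self):
        # sum(dx*dy)/sqrt(sum(dx^2)*sum(dy^2)) = 3/5
        assert tfotf.pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6, abs=1e-12)

    def test_undefined_signals(self):
        with pytest.raises(UndefinedCorrelation) as e:
            tfotf.pearson_r([1, 2], [3, 4])
        assert e.value.reason == REASON_INSUFFICIENT
        with pytest.raises(UndefinedCorrelation) as e:
            tfotf.pearson_r([1, 1, 1], [1, 2, 3])
        assert e.value.reason == REASON_ZERO_VARIANCE

    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 50))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        expected = stats.pearsonr(x, y).statistic
        assert tfotf.pearson_r(x, y) == pytest.approx(expected, abs=1e-12)
        assert -1.0 <= tfotf.pearson_r(x, y) <= 1.0

    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.1, 10.0),
        st.floats(-5.0, 5.0),
    )
    def test_invariance_under_positive_affine_transform(self, seed, slope, shift):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r0 = tfotf.pearson_r(x, y)
        r1 = tfotf.pearson_r(x, slope * y + shift)
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestGroupCorrelations:
    def test_perfect_correlation_in_every_group(self):
        groups = {"s1": "A", "s2": "A", "s3": "A", "s4": "B", "s5": "B", "s6": "B"}
        expr = make_expr(
            {"TF": [1, 2, 3, 1, 3, 5], "g": [1, 2, 3, 1, 3, 5]}, groups
        )
        defined, missing = tfotf.group_correlations(expr, "TF", "g")
        assert defined == {"A": 1.0, "B": 1.0}
        assert missing == {}

    def test_small_group_missing_with_reason(self):
        groups = {"s1": "A", "s2": "A", "s3": "A", "s4": "B", "s5": "B"}
        expr = make_expr(
            {"TF": [1, 2, 3, 1, 2], "g": [1, 3, 2, 2, 1]}, groups
        )
        defined, missing = tfotf.group_correlations(expr, "TF", "g")
        assert "A" in defined
        assert missing == {"B": REASON_INSUFFICIENT}

    def test_constant_tf_missing_with_reason(self):
        groups = {"s1": "A", "s2": "A", "s3": "A"}
        expr = make_expr({"TF": [2, 2, 2], "g": [1, 2, 3]}, groups)
        _, missing = tfotf.group_correlations(expr, "TF", "g")
        assert missing == {"A": REASON_ZERO_VARIANCE}

    def test_unknown_gene_raises(self):
        expr = make_expr({"TF": [1, 2, 3]}, {"s1": "A", "s2": "A", "s3": "A"})
        with pytest.raises(LookupError_):
            tfotf.group_correlations(expr, "TF", "nope")


class TestRScore:
    def expr_three_groups(self):
        # hand-built correlations: group A r≈0.983, group B r=−1 exactly,
        # group C r=0.6 (the closed-form example vectors)
        groups = {f"s{i}": g for i, g in enumerate("AAAABBBBCCCC")}
        tf = [1, 2, 3, 4] * 3
        g = [1, 2, 3, 5, 4, 3, 2, 1, 2, 1, 4, 3]
        return make_expr(
            {"TF": np.array(tf, float), "g": np.array(g, float)}, groups
        )

    def test_signed_maximum_default(self):
        expr = self.expr_three_groups()
        rec = tfotf.r_score(expr, "TF", "g")
        assert rec.r_score == max(rec.per_group_r.values())
        assert rec.per_group_r[rec.best_group] == rec.r_score
        assert rec.n_groups_evaluated == 3

    def test_absolute_mode_reports_magnitude_keeps_signed_per_group(self):
        expr = self.expr_three_groups()
        signed = tfotf.r_score(expr, "TF", "g")
        absolute = tfotf.r_score(expr, "TF", "g", absolute=True)
        best_abs = max(abs(v) for v in signed.per_group_r.values())
        assert absolute.r_score == pytest.approx(best_abs) == 1.0
        assert absolute.best_group == "B"
        assert absolute.per_group_r["B"] == -1.0  # sign kept in per-group map
        assert absolute.r_score >= signed.r_score

    def test_single_defined_group(self):
        groups = {"s1": "A", "s2": "A", "s3": "A"}
        expr = make_expr({"TF": [1.0, 2.0, 3.0], "g": [1.0, 2.0, 2.5]}, groups)
        rec = tfotf.r_score(expr, "TF", "g")
        assert rec.best_group == "A"
        assert rec.r_score == tfotf.pearson_r([1, 2, 3], [1, 2, 2.5])

    def test_no_defined_group_signals(self):
        groups = {"s1": "A", "s2": "A"}
        expr = make_expr({"TF": [1.0, 2.0], "g": [2.0, 1.0]}, groups)
        with pytest.raises(UndefinedCorrelation):
            tfotf.r_score(expr, "TF", "g")

    def test_adding_a_group_never_decreases_r_score(self):
        expr = self.expr_three_groups()
        full = tfotf.r_score(expr, "TF", "g")
        # drop group C
        keep = [s for s, g in expr.group_of_sample.items() if g != "C"]
        sub = ExpressionMatrix(
            expr.values[keep], {s: expr.group_of_sample[s] for s in keep}
        )
        partial = tfotf.r_score(sub, "TF", "g")
        assert full.r_score >= partial.r_score


class TestRScoresAll:
    def test_tf_excluded_and_sorted_descending(self, small_fixture):
        expr = small_fixture["expr"]
        records, skipped = tfotf.r_scores_all(expr, "TF1")
        ids = [r.gene_id for r in records]
        assert "TF1" not in ids
        assert len(ids) == len(set(ids))
        scores = [r.r_score for r in records]
        assert scores == sorted(scores, reverse=True)
        assert skipped == []

    def test_matches_per_gene_r_score(self, small_fixture):
        expr = small_fixture["expr"]
        records, _ = tfotf.r_scores_all(expr, "TF1")
        for rec in records[:10]:
            single = tfotf.r_score(expr, "TF1", rec.gene_id)
            assert rec.r_score == pytest.approx(single.r_score, abs=1e-12)
            assert rec.best_group == single.best_group

    def test_planted_targets_outscore_nulls(self, small_fixture):
        records, _ = tfotf.r_scores_all(small_fixture["expr"], "TF1")
        truth = small_fixture["truth"]
        truth_scores = [r.r_score for r in records if r.gene_id in truth]
        null_scores = [r.r_score for r in records if r.gene_id not in truth]
        # ρ=0.8 at 3×30 samples: planted far above typical nulls
        assert min(truth_scores) > np.percentile(null_scores, 95)

    def test_zero_variance_candidate_recorded_missing(self):
        groups = {"s1": "A", "s2": "A", "s3": "A"}
        expr = make_expr(
            {"TF": [1.0, 2.0, 3.0], "g1": [5.0, 5.0, 5.0], "g2": [1.0, 2.0, 3.5]},
            groups,
        )
        records, skipped = tfotf.r_scores_all(expr, "TF")
        assert ("g1", "no_defined_group") in skipped
        assert [r.gene_id for r in records] == ["g2"]

    def test_fisher_z_recovery_of_planted_effect(self):
        # ρ=0.9, one group of 500 samples: sample r inside the 99% band
        cfg = tfotf.SimulationConfig(
            seed=3, n_genes=20, n_true_targets=5, n_groups=1,
            samples_per_group=500, effect_size=0.9,
            genes_per_chrom=20, promoter_length=50, motif_length=5,
        )
        truth = sorted(
            tfotf.simulate_genome_and_annotation(cfg)[2]
        )
        expr = tfotf.simulate_expression(cfg, set(truth))
        records, _ = tfotf.r_scores_all(expr, cfg.tf_gene_id)
        z = np.arctanh(0.9)
        sd = 1 / np.sqrt(500 - 3)
        lo, hi = np.tanh(z - 2.81 * sd), np.tanh(z + 2.81 * sd)
        for rec in records:
            if rec.gene_id in truth:
                assert lo <= rec.r_score <= hi
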