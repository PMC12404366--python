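"""Pairwise-comparison weighting: eigenvector extraction and consistency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fruitqual as fq
from fruitqual.ahp import RANDOM_INDEX, JudgmentMatrix, eigen_weights, geometric_mean_weights

SAATY_VALUES = [1/9, 1/8, 1/7, 1/6, 1/5, 1/4, 1/3, 1/2, 1, 2, 3, 4, 5, 6, 7, 8, 9]


def random_reciprocal(k, rng):
    a = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            a[i, j] = rng.choice(SAATY_VALUES)
            a[j, i] = 1 / a[i, j]
    return JudgmentMatrix(tuple(f"c{i}" for i in range(k)), a)


class TestJudgmentMatrix:
    def test_fraction_literals_parse_exactly(self):
        m = JudgmentMatrix.from_rows(["a", "b"], [[1, "1/7"], [7, 1]])
        assert m.entries[0, 1] == 1 / 7  # Fraction(1,7) -> float, not a parse of "0.142857"

    def test_upper_triangle_input_fills_reciprocals(self):
        m = JudgmentMatrix.from_upper(["a", "b", "c"], [[3, 5], [2]])
        full = JudgmentMatrix.from_rows(
            ["a", "b", "c"], [[1, 3, 5], ["1/3", 1, 2], ["1/5", "1/2", 1]])
        np.testing.assert_allclose(m.entries, full.entries)

    def test_non_reciprocal_rejected(self):
        with pytest.raises(fq.ValidationError, match="reciprocal"):
            JudgmentMatrix(("a", "b"), np.array([[1.0, 2.0], [1.0, 1.0]]))

    def test_bad_diagonal_rejected(self):
        with pytest.raises(fq.ValidationError, match="diagonal"):
            JudgmentMatrix(("a", "b"), np.array([[2.0, 2.0], [0.5, 0.5]]))

    def test_out_of_scale_rejected(self):
        with pytest.raises(fq.ValidationError, match="scale"):
            JudgmentMatrix(("a", "b"), np.array([[1.0, 12.0], [1 / 12.0, 1.0]]))


class TestEigenWeights:
    def test_all_ones_matrix_gives_equal_weights(self):
        for k in (2, 3, 4, 5):
            m = JudgmentMatrix(tuple(f"c{i}" for i in range(k)), np.ones((k, k)))
            w, rep = eigen_weights(m)
            np.testing.assert_allclose(w, np.full(k, 1 / k), atol=1e-12)
            assert rep.lambda_max == pytest.approx(k, abs=1e-9)
            assert rep.cr == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("v", [(1, 2, 3), (0.5, 3, 1, 2), (4, 4, 1, 0.5, 2)])
    def test_ratio_matrix_recovers_generating_vector(self, v):
        """a_ij = v_i/v_j is perfectly consistent: weights = v/sum(v), CR = 0."""
        v = np.array(v, dtype=float)
        a = v[:, None] / v[None, :]
        m = JudgmentMatrix(tuple(f"c{i}" for i in range(len(v))), a)
        w, rep = eigen_weights(m)
        np.testing.assert_allclose(w, v / v.sum(), atol=1e-10)
        assert rep.cr == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_power_iteration_matches_dense_eig_on_3x3(self, seed):
        """Independent oracle: numpy's full eigen solve on random 3x3 matrices."""
        m = random_reciprocal(3, np.random.default_rng(seed))
        w, rep = eigen_weights(m)
        vals, vecs = np.linalg.eig(m.entries)
        i = np.argmax(vals.real)
        oracle = np.abs(vecs[:, i].real)
        oracle /= oracle.sum()
        np.testing.assert_allclose(w, oracle, atol=1e-9)
        assert rep.lambda_max == pytest.approx(float(vals.real.max()), abs=1e-9)

    def test_geometric_mean_agrees_with_eigen_on_3x3(self):
        m = random_reciprocal(3, np.random.default_rng(42))
        w_e, _ = eigen_weights(m)
        w_g, _ = geometric_mean_weights(m)
        np.testing.assert_allclose(w_e, w_g, atol=1e-9)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 10**6), st.integers(3, 5))
    def test_permuting_criteria_permutes_weights(self, seed, k):
        m = random_reciprocal(k, np.random.default_rng(seed))
        w = dict(zip(m.labels, eigen_weights(m)[0]))
        order = list(m.labels)[::-1]
        w_perm = dict(zip(order, eigen_weights(m.permuted(order))[0]))
        for lab in m.labels:
            assert w[lab] == pytest.approx(w_perm[lab], abs=1e-10)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 10**6))
    def test_increasing_dominance_never_hurts_the_dominant(self, seed):
        rng = np.random.default_rng(seed)
        m = random_reciprocal(4, rng)
        a = m.entries.copy()
        if a[0, 1] >= 9:
            a[0, 1] = 1.0
            a[1, 0] = 1.0
        before = eigen_weights(JudgmentMatrix(m.labels, a))[0]
        a2 = a.copy()
        a2[0, 1] = min(a[0, 1] * 2, 9.0)
        a2[1, 0] = 1 / a2[0, 1]
        after = eigen_weights(JudgmentMatrix(m.labels, a2))[0]
        assert after[0] / after[1] >= before[0] / before[1] - 1e-12

    def test_consistency_report_identities(self):
        m = random_reciprocal(4, np.random.default_rng(1))
        _, rep = eigen_weights(m)
        assert rep.lambda_max >= 4 - 1e-9
        assert rep.ci == pytest.approx((rep.lambda_max - 4) / 3)
        assert rep.ri == RANDOM_INDEX[4]
        assert rep.cr == pytest.approx(rep.ci / rep.ri)

    def test_two_by_two_has_zero_cr(self):
        m = JudgmentMatrix.from_rows(["a", "b"], [[1, 3], ["1/3", 1]])
        _, rep = eigen_weights(m)
        assert rep.cr == 0.0 and rep.passed


class TestAggregateSubjective:
    def test_global_weights_are_products_and_sum_to_one(self, study):
        hierarchy, first, groups, _ = study
        sw = fq.aggregate_subjective(hierarchy, first, groups)
        assert sum(sw.group_weights.values()) == pytest.approx(1.0, abs=1e-9)
        for g in hierarchy.first_level:
            members = hierarchy.group_members(g)
            assert sum(sw.within_group[i] for i in members) == pytest.approx(1.0, abs=1e-9)
            for i in members:
                assert sw.global_weights[i] == pytest.approx(
                    sw.group_weights[g] * sw.within_group[i], abs=1e-9)
        assert sum(sw.global_weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_two_by_two_group_splits_evenly(self, toy_hierarchy):
        first = fq.JudgmentMatrix(("g",), np.ones((1, 1)))
        group = fq.JudgmentMatrix.from_rows(["a", "b"], [[1, 1], [1, 1]])
        sw = fq.aggregate_subjective(toy_hierarchy, first, {"g": group})
        assert sw.global_weights == pytest.approx({"a": 0.5, "b": 0.5})

    def test_missing_group_matrix_rejected(self, study):
        hierarchy, first, groups, _ = study
        incomplete = {g: m for g, m in groups.items() if g != "eating"}
        with pytest.raises(fq.ValidationError, match="eating"):
            fq.aggregate_subjective(hierarchy, first, incomplete)

    def test_inconsistent_matrix_strict_vs_lenient(self, toy_hierarchy):
        # a cyclic 3x3 judgment (a>b, b>c, c>a strongly) is badly inconsistent
        h = fq.Hierarchy(
            first_level=("g",),
            indicators=tuple(
                fq.IndicatorSpec(id=i, label=i, group="g", orientation="benefit")
                for i in "abc"),
        )
        first = fq.JudgmentMatrix(("g",), np.ones((1, 1)))
        cyclic = fq.JudgmentMatrix.from_rows(
            ["a", "b", "c"], [[1, 9, "1/9"], ["1/9", 1, 9], [9, "1/9", 1]])
        with pytest.raises(fq.ConsistencyError):
            fq.aggregate_subjective(h, first, {"g": cyclic})
        sw = fq.aggregate_subjective(h, first, {"g": cyclic}, strict=False)
        assert not sw.reports["g"].passed
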