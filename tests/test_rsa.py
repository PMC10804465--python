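import itertools

import numpy as np
import pandas as pd
import pytest

import sonorsa as s

from _oracles import (
    oracle_edi,
    oracle_edi_permutation,
    oracle_rdm_comparison,
    oracle_sdrdm,
)
from conftest import make_state_set


def _states_from_vectors(vectors_by_movement):
    states, labels = [], []
    for m, vecs in vectors_by_movement.items():
        for i, v in enumerate(vecs):
            states.append(s.MuscleState(values=np.asarray(v, float), source="end",
                                        movement=m, trial_index=i + 1))
            labels.append(m)
    return s.LabeledStateSet(states=states, labels=labels)


class TestSplitTrials:
    @pytest.mark.parametrize("n, sizes", [(10, (5, 5)), (5, (3, 2)), (2, (1, 1))])
    def test_contiguous_split_sizes(self, n, sizes):
        a, b = s.split_trials(list(range(n)), policy="contiguous")
        assert (len(a), len(b)) == sizes
        assert a == list(range(sizes[0]))  # acquisition order preserved

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            s.split_trials([1])

    def test_random_split_is_seeded_and_balanced(self):
        a1, b1 = s.split_trials(list(range(7)), policy="random", seed=5)
        a2, b2 = s.split_trials(list(range(7)), policy="random", seed=5)
        assert (a1, b1) == (a2, b2)
        assert len(a1) == 4 and len(b1) == 3
        assert sorted(a1 + b1) == list(range(7))


class TestSdrdm:
    def test_orthogonal_identical_halves(self):
        # per movement both halves share one mean; across movements the means
        # are mutually uncorrelated -> diagonal 0, off-diagonal 1
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(20, 6))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        vectors = {m: [q[:, i], q[:, i]] for i, m in enumerate(s.MOVEMENTS)}
        rdm = s.sdrdm(_states_from_vectors(vectors))
        assert np.allclose(np.diag(rdm.matrix), 0.0, atol=1e-9)
        off = rdm.matrix[~np.eye(6, dtype=bool)]
        assert np.allclose(off, 1.0, atol=1e-9)

    def test_shared_mean_state_gives_all_zeros(self):
        shared = np.array([1.0, 4.0, 2.0, 8.0])
        vectors = {m: [shared, shared] for m in s.MOVEMENTS}
        rdm = s.sdrdm(_states_from_vectors(vectors))
        assert np.allclose(rdm.matrix, 0.0, atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        lss = make_state_set(rng, n_per_class=5, n_features=20)
        rdm = s.sdrdm(lss, policy="contiguous")
        expected = oracle_sdrdm(lss.matrix(), lss.labels, lss.classes)
        assert np.allclose(rdm.matrix, expected)

    def test_generally_asymmetric_with_nonzero_diagonal(self, affected_states):
        end, _ = affected_states
        rdm = s.sdrdm(end)
        assert not np.allclose(rdm.matrix, rdm.matrix.T)
        assert np.all(np.diag(rdm.matrix) > 0)


class TestEdi:
    def test_unit_contrast(self):
        m = np.ones((6, 6)) - np.eye(6)
        assert s.edi(m) == pytest.approx(1.0)

    def test_constant_matrix_is_zero(self):
        assert s.edi(np.full((6, 6), 0.7)) == pytest.approx(0.0)

    def test_three_by_three_hand_arithmetic(self):
        m = np.array([[0.1, 0.5, 0.6], [0.4, 0.2, 0.7], [0.5, 0.6, 0.3]])
        assert s.edi(m) == pytest.approx(0.35)
        assert oracle_edi(m) == pytest.approx(0.35)

    def test_invariant_under_simultaneous_permutation(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(0, 2, size=(6, 6))
        for _ in range(10):
            p = rng.permutation(6)
            assert s.edi(m[np.ix_(p, p)]) == pytest.approx(s.edi(m))


class TestEdiPermutationTest:
    def test_enumerates_all_720_label_permutations(self):
        rng = np.random.default_rng(3)
        res = s.edi_permutation_test(rng.uniform(0, 2, size=(6, 6)))
        assert res.n_permutations == 720
        assert len(res.null_values) == 720

    def test_constant_matrix_gives_p_one(self):
        res = s.edi_permutation_test(np.full((6, 6), 0.5))
        assert res.p_value == 1.0

    def test_uniquely_best_diagonal_gives_minimal_p(self):
        # off-diagonal entries all strictly exceed the diagonal ones, so every
        # non-identity permutation raises the diagonal sum and lowers the EDI
        m = 0.5 + 0.01 * np.add.outer(np.arange(6), np.arange(6.0))
        np.fill_diagonal(m, 0.1)
        res = s.edi_permutation_test(m)
        assert res.p_value == pytest.approx(1 / 720)
        obs, null, p = oracle_edi_permutation(m)
        assert p == pytest.approx(1 / 720)

    def test_matches_explicit_row_permutation_oracle(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(0, 2, size=(6, 6))
        res = s.edi_permutation_test(m)
        obs, null, p = oracle_edi_permutation(m)
        assert res.observed == pytest.approx(obs)
        assert np.allclose(np.sort(res.null_values), np.sort(null))
        assert res.p_value == pytest.approx(p)

    def test_identity_always_in_null_so_p_is_positive(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            res = s.edi_permutation_test(rng.uniform(0, 2, size=(6, 6)))
            assert res.p_value >= 1 / 720


class TestMovementRdm:
    def test_symmetric_with_zero_diagonal(self, affected_states):
        end, _ = affected_states
        rdm = s.movement_rdm(end)
        assert np.array_equal(rdm.matrix, rdm.matrix.T)
        assert np.all(np.diag(rdm.matrix) == 0)

    def test_matches_brute_force_oracle(self):
        from _oracles import oracle_dissimilarity

        rng = np.random.default_rng(6)
        lss = make_state_set(rng, n_per_class=4, n_features=15)
        rdm = s.movement_rdm(lss)
        means = {m: np.mean([st.values for st in lss.states_for(m)], axis=0)
                 for m in lss.classes}
        for i, mi in enumerate(lss.classes):
            for j, mj in enumerate(lss.classes):
                expected = 0.0 if i == j else oracle_dissimilarity(means[mi], means[mj])
                assert rdm.matrix[i, j] == pytest.approx(expected)


class TestRdmCorrelation:
    def _random_rdm(self, rng, n=6):
        tri = rng.uniform(0.1, 1.9, size=n * (n - 1) // 2)
        m = np.zeros((n, n))
        m[np.triu_indices(n, 1)] = tri
        return m + m.T

    def test_self_correlation_is_one(self):
        m = self._random_rdm(np.random.default_rng(7))
        assert s.rdm_correlation(m, m) == pytest.approx(1.0)

    def test_positive_affine_image_correlates_perfectly(self):
        m = self._random_rdm(np.random.default_rng(8))
        m2 = np.where(np.eye(6, dtype=bool), 0.0, 0.5 * m + 0.1)
        assert s.rdm_correlation(m, m2) == pytest.approx(1.0)

    def test_hand_constructed_linear_triangles(self):
        def from_tri(vals):
            m = np.zeros((3, 3))
            m[np.triu_indices(3, 1)] = vals
            return m + m.T

        a = from_tri([0.2, 0.4, 0.6])
        b = from_tri([0.25, 0.45, 0.65])
        assert s.rdm_correlation(a, b) == pytest.approx(1.0)

    def test_constant_triangle_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            s.rdm_correlation(np.ones((6, 6)) - np.eye(6),
                              self._random_rdm(np.random.default_rng(9)))


class TestRdmComparisonTest:
    def test_enumerates_all_720_permutations(self):
        rng = np.random.default_rng(10)
        a = TestRdmCorrelation()._random_rdm(rng)
        b = TestRdmCorrelation()._random_rdm(rng)
        res = s.rdm_comparison_test(a, b)
        assert res.n_permutations == 720

    def test_identical_distinct_rdms_give_minimal_p(self):
        a = TestRdmCorrelation()._random_rdm(np.random.default_rng(11))
        res = s.rdm_comparison_test(a, a)
        assert res.observed == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 720)

    def test_matches_explicit_permutation_oracle(self):
        rng = np.random.default_rng(12)
        a = TestRdmCorrelation()._random_rdm(rng)
        b = TestRdmCorrelation()._random_rdm(rng)
        res = s.rdm_comparison_test(a, b)
        obs, null, p = oracle_rdm_comparison(a, b)
        assert res.observed == pytest.approx(obs)
        assert np.allclose(np.sort(res.null_values), np.sort(null))
        assert res.p_value == pytest.approx(p)

    def test_p_superuniform_under_exchangeable_structure(self):
        # b's movements are exchangeable (equal off-diagonals + tiny noise),
        # so the test should reject at most at its nominal level
        rng = np.random.default_rng(13)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = TestRdmCorrelation()._random_rdm(rng)
            tri = 1.0 + rng.normal(0, 0.01, size=15)
            b = np.zeros((6, 6))
            b[np.triu_indices(6, 1)] = tri
            b = b + b.T
            rejections += s.rdm_comparison_test(a, b).p_value <= 0.05
        ci = 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert rejections / n_rep <= ci


class TestCompareLimbEdi:
    def _result(self, p):
        null = np.linspace(-0.2, 0.5, 720)
        obs = float(np.quantile(null, 1 - p))
        return s.PermutationTestResult(observed=obs, null_values=null,
                                       p_value=p, n_permutations=720,
                                       statistic_name="edi")

    def test_flags_significance_at_alpha(self):
        table = s.compare_limb_edi(self._result(1 / 720), self._result(1 / 720),
                                   alpha=0.05, subject_id="A")
        assert list(table["significant"]) == [True, True]
        assert list(table["limb"]) == ["affected", "unaffected"]

    def test_large_p_not_significant(self):
        table = s.compare_limb_edi(self._result(0.5), self._result(1 / 720))
        assert list(table["significant"]) == [False, True]

    def test_two_rows_per_subject(self):
        tables = [
            s.compare_limb_edi(self._result(0.01), self._result(0.01), subject_id=sub)
            for sub in "ABC"
        ]
        combined = pd.concat(tables)
        assert len(combined) == 3 * 2
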