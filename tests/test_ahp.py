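"""AHP weighting, consistency screening and group aggregation.

The dense eigendecomposition (numpy.linalg.eig) serves as the independent
oracle for the power-iteration weights and for lambda_max throughout.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import prioritycompass as pc
from prioritycompass.ahp import AhpError, PairwiseMatrix, SAATY_RANDOM_INDEX


def eig_oracle(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Principal eigenpair via full dense eigendecomposition."""
    vals, vecs = np.linalg.eig(matrix)
    k = int(np.argmax(vals.real))
    vec = np.abs(vecs[:, k].real)
    return vec / vec.sum(), float(vals[k].real)


def random_reciprocal(n: int, rng: np.random.Generator) -> PairwiseMatrix:
    a = np.ones((n, n))
    iu = np.triu_indices(n, k=1)
    a[iu] = np.exp(rng.normal(0.0, 0.8, size=len(iu[0])))
    a[(iu[1], iu[0])] = 1.0 / a[iu]
    return PairwiseMatrix(a)


positive_weights = st.lists(
    st.floats(min_value=0.01, max_value=100.0,
              allow_nan=False, allow_infinity=False),
    min_size=2, max_size=8,
)


class TestPairwiseMatrix:
    def test_non_reciprocal_rejected(self):
        with pytest.raises(AhpError, match="reciprocal"):
            PairwiseMatrix(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_non_positive_rejected(self):
        with pytest.raises(AhpError, match="positive"):
            PairwiseMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]))

    def test_non_unit_diagonal_rejected(self):
        with pytest.raises(AhpError, match="diagonal"):
            PairwiseMatrix(np.array([[2.0, 1.0], [1.0, 2.0]]))


class TestBuildConsistentMatrix:
    def test_entries_are_weight_ratios(self):
        m = pc.build_consistent_matrix((0.5, 0.3, 0.2))
        assert m.values[0, 2] == pytest.approx(2.5)
        assert m.values[2, 0] == pytest.approx(0.4)

    def test_uniform_weights_give_all_ones(self):
        m = pc.build_consistent_matrix((0.25, 0.25, 0.25, 0.25))
        assert np.array_equal(m.values, np.ones((4, 4)))

    def test_printed_weight_ratio(self, printed_weights):
        m = pc.build_consistent_matrix(printed_weights)
        assert m.values[2, 4] == pytest.approx(0.337 / 0.077)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(AhpError):
            pc.build_consistent_matrix((0.5, 0.0, 0.5))

    @given(positive_weights, st.floats(min_value=0.1, max_value=10.0))
    def test_scale_invariance(self, weights, c):
        w = np.asarray(weights)
        a = pc.build_consistent_matrix(w)
        b = pc.build_consistent_matrix(c * w)
        assert np.allclose(a.values, b.values, rtol=1e-12)


class TestDeriveWeights:
    def test_two_by_two_closed_form(self):
        m = PairwiseMatrix(np.array([[1.0, 3.0], [1 / 3, 1.0]]))
        w, lam = pc.derive_weights(m)
        assert w == pytest.approx([0.75, 0.25], abs=1e-12)
        assert lam == pytest.approx(2.0, abs=1e-12)

    def test_recovers_printed_weights_exactly(self, printed_weights):
        m = pc.build_consistent_matrix(printed_weights)
        w, lam = pc.derive_weights(m)
        assert np.max(np.abs(w - printed_weights / printed_weights.sum())) < 1e-9
        assert lam == pytest.approx(5.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_eigensolver_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        m = random_reciprocal(5, rng)
        w, lam = pc.derive_weights(m)
        w_ref, lam_ref = eig_oracle(m.values)
        assert np.max(np.abs(w - w_ref)) < 1e-8
        assert lam == pytest.approx(lam_ref, abs=1e-8)

    def test_methods_agree_on_consistent_matrices(self, printed_weights):
        m = pc.build_consistent_matrix(printed_weights)
        w_eig, _ = pc.derive_weights(m, method="eigenvector")
        w_gm, _ = pc.derive_weights(m, method="geometric_mean")
        assert np.max(np.abs(w_eig - w_gm)) < 1e-9

    def test_unknown_method_rejected(self, printed_weights):
        m = pc.build_consistent_matrix(printed_weights)
        with pytest.raises(AhpError, match="method"):
            pc.derive_weights(m, method="ideal")

    @pytest.mark.parametrize("seed", range(10))
    def test_lambda_max_at_least_n(self, seed):
        """For any positive reciprocal matrix the principal eigenvalue is
        bounded below by the order n."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        m = random_reciprocal(n, rng)
        _, lam = pc.derive_weights(m)
        assert lam >= n - 1e-9


class TestConsistencyRatio:
    def test_consistent_matrix_passes_with_zero_cr(self, printed_weights):
        report = pc.consistency_ratio(pc.build_consistent_matrix(printed_weights))
        assert report.cr == pytest.approx(0.0, abs=1e-9)
        assert report.passed

    def test_two_by_two_cr_is_zero_by_definition(self):
        report = pc.consistency_ratio(
            PairwiseMatrix(np.array([[1.0, 7.0], [1 / 7, 1.0]]))
        )
        assert report.cr == 0.0 and report.ci == 0.0

    def test_perturbed_matrix_matches_brute_force(self, printed_weights):
        """CR of a noisy matrix equals (lambda_max - n)/(n-1)/RI recomputed
        from the dense eigensolver."""
        rng = np.random.default_rng(42)
        base = pc.build_consistent_matrix(printed_weights).values
        n = 5
        iu = np.triu_indices(n, k=1)
        noisy = np.ones((n, n))
        noisy[iu] = base[iu] * np.exp(rng.normal(0.0, 0.3, size=len(iu[0])))
        noisy[(iu[1], iu[0])] = 1.0 / noisy[iu]
        report = pc.consistency_ratio(PairwiseMatrix(noisy))
        _, lam_ref = eig_oracle(noisy)
        expected = ((lam_ref - n) / (n - 1)) / SAATY_RANDOM_INDEX[n]
        assert report.cr > 0
        assert report.cr == pytest.approx(expected, abs=1e-8)

    def test_large_matrix_needs_user_ri(self):
        w = np.arange(1.0, 13.0)
        m = pc.build_consistent_matrix(w)
        with pytest.raises(AhpError, match="ri"):
            pc.consistency_ratio(m)
        report = pc.consistency_ratio(m, ri=1.54)
        assert report.cr == pytest.approx(0.0, abs=1e-9)


class TestAggregation:
    def test_single_matrix_is_identity(self, printed_weights):
        m = pc.build_consistent_matrix(printed_weights)
        agg = pc.aggregate_expert_matrices([m])
        assert np.allclose(agg.values, m.values, rtol=1e-12)

    def test_reciprocal_pair_cancels_to_ones(self):
        rng = np.random.default_rng(0)
        m = pc.build_consistent_matrix(rng.uniform(0.1, 1.0, size=4))
        inv = PairwiseMatrix(1.0 / m.values, m.labels)
        agg = pc.aggregate_expert_matrices([m, inv])
        assert np.allclose(agg.values, 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_reciprocity_preserved_exactly(self, seed):
        rng = np.random.default_rng(seed)
        mats = [random_reciprocal(5, rng) for _ in range(6)]
        agg = pc.aggregate_expert_matrices(mats)
        iu = np.triu_indices(5, k=1)
        lower = agg.values[(iu[1], iu[0])]
        assert np.array_equal(lower, 1.0 / agg.values[iu])
        assert np.allclose(agg.values * agg.values.T, 1.0, rtol=1e-12)

    def test_dimension_mismatch_rejected(self):
        a = pc.build_consistent_matrix((1.0, 2.0))
        b = pc.build_consistent_matrix((1.0, 2.0, 3.0))
        with pytest.raises(AhpError, match="mismatch"):
            pc.aggregate_expert_matrices([a, b])

    def test_empty_collection_rejected(self):
        with pytest.raises(AhpError):
            pc.aggregate_expert_matrices([])


class TestParameterRecovery:
    def test_error_shrinks_as_noise_vanishes(self, printed_weights):
        """Group weights converge to the latent weights as expert noise
        goes to zero (monotone over the 0.4/0.2/0.1/0.05 noise grid)."""
        latent = printed_weights / printed_weights.sum()
        errors = []
        for sd in (0.4, 0.2, 0.1, 0.05):
            per_seed = []
            for seed in range(10):
                cfg = pc.SynthConfig(seed=seed, expert_noise_sd=sd)
                agg = pc.aggregate_expert_matrices(pc.gen_expert_matrices(cfg))
                w, _ = pc.derive_weights(agg)
                per_seed.append(np.max(np.abs(w - latent)))
            errors.append(np.mean(per_seed))
        assert errors == sorted(errors, reverse=True)
        assert errors[-1] < 0.02
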