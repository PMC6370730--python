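"""Cross-diffusion iteration, kernel combination, and mutual-kNN masking."""

import numpy as np
import pytest

from skfuse.fusion import (
    FusionParams,
    apply_weight,
    combine_kernels,
    default_neighborhood_size,
    mutual_weight_matrix,
    skf,
    skf_iterate,
)
from skfuse.io import Cohort, ExpressionView
from skfuse.kernels import NeighborSets, SimilarityKernel, knn_sets, normalize_P

from conftest import ids, make_kernel, make_view, random_similarity


def _P(matrix):
    return make_kernel(np.asarray(matrix, dtype=float), kind="normalized_P")


def _S(matrix):
    return make_kernel(np.asarray(matrix, dtype=float), kind="sparse_S")


def _random_P(rng, n):
    return normalize_P(random_similarity(rng, n))


def _random_S(rng, n, k=2):
    kern = random_similarity(rng, n)
    from skfuse.kernels import sparsify_S

    return sparsify_S(kern, knn_sets(kern, k))


class TestIterate:
    def test_alpha0_fixed_point_in_one_step(self, rng):
        P = [_random_P(rng, 6) for _ in range(3)]
        S = [_random_S(rng, 6) for _ in range(3)]
        finals, iters, converged, history = skf_iterate(P, S, FusionParams(alpha=0.0))
        assert converged and iters == 2
        assert history[1] == pytest.approx(0.0, abs=1e-14)
        # state after one step is the cross-view anchor: mean of the OTHER
        # initial kernels (already column-stochastic, renormalization no-op)
        expected0 = (P[1].matrix + P[2].matrix) / 2
        np.testing.assert_allclose(finals[0].matrix, expected0, atol=1e-12)

    def test_alpha1_identity_S_swaps_views(self):
        A = _P([[0.7, 0.2], [0.3, 0.8]])
        B = _P([[0.5, 0.4], [0.5, 0.6]])
        I = _S(np.eye(2))
        params = FusionParams(alpha=1.0, max_iters=1, tol=1e-15)
        finals, *_ = skf_iterate([A, B], [I, I], params)
        np.testing.assert_allclose(finals[0].matrix, B.matrix, atol=1e-12)
        np.testing.assert_allclose(finals[1].matrix, A.matrix, atol=1e-12)
        # one more sweep swaps back: period 2 for distinct A, B
        params2 = FusionParams(alpha=1.0, max_iters=2, tol=1e-15)
        finals2, *_ = skf_iterate([A, B], [I, I], params2)
        np.testing.assert_allclose(finals2[0].matrix, A.matrix, atol=1e-12)

    def test_identical_views_alpha0_stay_put(self, rng):
        P = _random_P(rng, 5)
        S = _random_S(rng, 5)
        finals, *_ = skf_iterate([P, P, P], [S, S, S], FusionParams(alpha=0.0))
        for f in finals:
            np.testing.assert_allclose(f.matrix, P.matrix, atol=1e-12)

    def test_identical_views_stay_identical_across_iterations(self, rng):
        # diffusion cannot create asymmetry BETWEEN views: identical inputs
        # yield identical per-view states at every alpha
        P = _random_P(rng, 6)
        S = _random_S(rng, 6)
        for alpha in (0.0, 0.5, 1.0):
            finals, *_ = skf_iterate([P, P, P], [S, S, S], FusionParams(alpha=alpha))
            np.testing.assert_allclose(finals[0].matrix, finals[1].matrix, atol=1e-12)
            np.testing.assert_allclose(finals[0].matrix, finals[2].matrix, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        P = [_random_P(rng, 4), _random_P(rng, 5)]
        S = [_random_S(rng, 4), _random_S(rng, 5)]
        with pytest.raises(ValueError):
            skf_iterate(P, S, FusionParams())

    def test_outputs_remain_column_stochastic(self, rng):
        P = [_random_P(rng, 7) for _ in range(3)]
        S = [_random_S(rng, 7) for _ in range(3)]
        finals, *_ = skf_iterate(P, S, FusionParams(alpha=0.7))
        for f in finals:
            np.testing.assert_allclose(f.matrix.sum(axis=0), 1.0, atol=1e-8)
            assert f.matrix.min() >= 0


class TestCombineAndMask:
    def test_combine_mean(self):
        a = _P(np.eye(2))
        b = _P([[0, 1], [1, 0]])
        np.testing.assert_allclose(combine_kernels([a, b]).matrix, 0.5)
        np.testing.assert_allclose(combine_kernels([a, a]).matrix, a.matrix)

    def test_combine_linear_in_scale(self, rng):
        kernels = [_random_P(rng, 4) for _ in range(3)]
        scaled = [
            SimilarityKernel(2.5 * k.matrix, k.patient_ids, kind="combined")
            for k in kernels
        ]
        np.testing.assert_allclose(
            combine_kernels(scaled).matrix, 2.5 * combine_kernels(kernels).matrix
        )

    def test_mutual_weight_cases(self):
        # N_1={1,2}, N_2={2,3}, N_3={3,2} in 1-based terms
        nb = NeighborSets(np.array([[0, 1], [1, 2], [1, 2]]), k=1)
        w = mutual_weight_matrix(nb)
        assert w[0, 1] == 0.5 and w[1, 0] == 0.5  # one-way
        assert w[1, 2] == 1.0 and w[2, 1] == 1.0  # mutual
        assert w[0, 2] == 0.0 and w[2, 0] == 0.0  # neither
        np.testing.assert_array_equal(np.diag(w), 1.0)

    def test_mutual_weight_saturation(self, rng):
        k = random_similarity(rng, 5)
        w = mutual_weight_matrix(knn_sets(k, 4))
        np.testing.assert_array_equal(w, 1.0)

    def test_apply_weight_hand_example(self):
        k_com = make_kernel([[1.0, 0.8], [0.6, 1.0]], kind="combined")
        w = np.array([[1.0, 0.5], [0.5, 1.0]])
        fused = apply_weight(k_com, w)
        np.testing.assert_allclose(fused.matrix, [[1.0, 0.35], [0.35, 1.0]])

    def test_apply_weight_identity_and_annihilation(self, rng):
        k = random_similarity(rng, 4)
        sym = (k.matrix + k.matrix.T) / 2
        np.testing.assert_allclose(apply_weight(k, np.ones((4, 4))).matrix, sym)
        only_diag = apply_weight(k, np.eye(4)).matrix
        np.testing.assert_array_equal(only_diag, np.diag(np.diag(k.matrix)))


class TestEndToEnd:
    def test_identical_views_alpha0_equals_masked_P(self, rng):
        view = make_view(rng.normal(size=(10, 6)))
        cohort = Cohort([view, view, view])
        res = skf(cohort, FusionParams(alpha=0.0, k=3))
        # all views identical => fused kernel is the masked, symmetrized P
        from skfuse.io import zscore_normalize
        from skfuse.kernels import distance_to_similarity, pairwise_distance_kernel

        v = zscore_normalize(view)
        D = pairwise_distance_kernel(v)
        K = distance_to_similarity(D, knn_sets(D, 3, largest=False))
        P = normalize_P(K)
        w = mutual_weight_matrix(knn_sets(combine_kernels([P, P, P]), 3))
        expected = apply_weight(combine_kernels([P, P, P]), w)
        np.testing.assert_allclose(res.fused.matrix, expected.matrix, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        view_values = [rng.normal(size=(9, 5)) for _ in range(3)]
        base_ids = ids(9)
        perm = rng.permutation(9)

        def build(order):
            views = [
                ExpressionView(
                    vals[order], [base_ids[i] for i in order],
                    [f"f{j}" for j in range(vals.shape[1])], f"view{v}",
                )
                for v, vals in enumerate(view_values)
            ]
            return Cohort(views)

        res_a = skf(build(np.arange(9)), FusionParams(k=3))
        res_b = skf(build(perm), FusionParams(k=3))
        np.testing.assert_allclose(
            res_b.fused.matrix, res_a.fused.matrix[np.ix_(perm, perm)], atol=1e-10
        )

    def test_fused_kernel_well_formed(self, small_cohort):
        cohort, _ = small_cohort
        res = skf(cohort, FusionParams(k=4))
        m = res.fused.matrix
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        assert np.isfinite(m).all() and m.min() >= 0

    def test_mask_semantics_on_fused(self, small_cohort):
        cohort, _ = small_cohort
        params = FusionParams(k=4)
        res = skf(cohort, params)
        k_com = combine_kernels(res.per_view_final)
        w = mutual_weight_matrix(knn_sets(k_com, 4))
        sym_com = (k_com.matrix + k_com.matrix.T) / 2
        # w is symmetric, so w=0 entries are exactly annihilated and w=1
        # entries carry the symmetrized combined kernel unchanged
        assert np.all(res.fused.matrix[w == 0] == 0)
        np.testing.assert_allclose(res.fused.matrix[w == 1.0], sym_com[w == 1.0])

    def test_within_between_separation(self, small_cohort):
        cohort, labels = small_cohort
        res = skf(cohort)
        m = res.fused.matrix.copy()
        np.fill_diagonal(m, np.nan)
        same = labels[:, None] == labels[None, :]
        within = np.nanmean(m[same])
        between = np.nanmean(m[~same])
        assert within > between


def test_default_neighborhood_size():
    assert default_neighborhood_size(30) == 5
    assert default_neighborhood_size(400) == 40
    assert default_neighborhood_size(4) == 3


def test_params_validation():
    with pytest.raises(ValueError):
        FusionParams(alpha=1.5)
    with pytest.raises(ValueError):
        FusionParams(tol=0)
    with pytest.raises(ValueError):
        FusionParams(max_iters=0)
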