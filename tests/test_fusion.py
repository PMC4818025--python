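import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_expr
from wsnf.fusion import (
    AffinityMatrix,
    DistanceMatrix,
    FusedNetwork,
    FusionParams,
    affinity_matrix,
    estimate_num_clusters,
    snf_fuse,
    spectral_cluster,
    weighted_distance_matrix,
)
from wsnf.preprocess import ExpressionMatrix


def dist_from_matrix(d, view="v"):
    return DistanceMatrix(matrix=np.asarray(d, float), samples=[f"S{i}" for i in range(len(d))], view=view)


# ---------------------------------------------------------------- distances


class TestWeightedDistance:
    def test_identical_samples_have_zero_distance(self):
        m = make_expr(np.tile([[1.0], [2.0]], (1, 3)))
        w = pd.Series(0.5, index=m.features)
        d = weighted_distance_matrix(m, w, standardize=False)
        assert np.allclose(d.matrix, 0.0)

    def test_uniform_weights_reduce_to_scaled_euclidean(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(12, 6))
        m = make_expr(x)
        p = x.shape[0]
        w = pd.Series(1.0 / p, index=m.features)
        d = weighted_distance_matrix(m, w, standardize=False).matrix
        from scipy.spatial.distance import pdist, squareform

        euclid = squareform(pdist(x.T))
        assert np.max(np.abs(d - euclid / math.sqrt(p))) <= 1e-12

    def test_hand_computed_two_feature_case(self):
        m = make_expr(np.array([[0.0, 2.0], [0.0, 2.0]]))
        w = pd.Series([0.5, 0.5], index=m.features)
        d = weighted_distance_matrix(m, w, standardize=False)
        assert d.matrix[0, 1] == pytest.approx(2.0)

    def test_metric_properties_on_random_data(self):
        rng = np.random.default_rng(15)
        m = make_expr(rng.normal(size=(20, 15)))
        w = pd.Series(rng.random(20), index=m.features)
        d = weighted_distance_matrix(m, w, standardize=True).matrix
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        for _ in range(50):
            i, j, k = rng.choice(15, 3, replace=False)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_missing_weight_rejected(self):
        m = make_expr(np.ones((3, 4)))
        with pytest.raises(KeyError):
            from wsnf.weighting import WeightVector

            wv = WeightVector(table=pd.DataFrame({"W": [0.5]}, index=["g0"]), beta=0.5)
            weighted_distance_matrix(m, wv)


# ---------------------------------------------------------------- affinity


def affinity_oracle(d, K, mu):
    """Scalar re-evaluation of the kernel formulas, coded independently."""
    n = len(d)
    knn_mean = []
    for i in range(n):
        others = sorted(d[i, j] for j in range(n) if j != i)
        knn_mean.append(sum(others[:K]) / K)
    kernel = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            eps = (knn_mean[i] + knn_mean[j] + d[i, j]) / 3.0
            kernel[i, j] = math.exp(-d[i, j] ** 2 / (mu * eps))
    return np.array(knn_mean), kernel


class TestAffinity:
    coords = np.array([0.0, 1.0, 3.0, 7.0])

    def _dist(self):
        return dist_from_matrix(np.abs(self.coords[:, None] - self.coords[None, :]))

    def test_kernel_matches_scalar_hand_evaluation(self):
        params = FusionParams(K=2, mu=0.5)
        aff = affinity_matrix(self._dist(), params)
        _, expected = affinity_oracle(self._dist().matrix, K=2, mu=0.5)
        assert np.max(np.abs(aff.kernel - expected)) <= 1e-12

    def test_zero_distance_gives_unit_kernel(self):
        d = dist_from_matrix([[0, 0, 5], [0, 0, 5], [5, 5, 0]])
        aff = affinity_matrix(d, FusionParams(K=1, mu=0.5))
        assert aff.kernel[0, 1] == pytest.approx(1.0)

    def test_p_rows_sum_to_one_with_half_diagonal(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 30))
        from scipy.spatial.distance import pdist, squareform

        aff = affinity_matrix(dist_from_matrix(squareform(pdist(x.T))), FusionParams(K=5, mu=0.5))
        assert np.allclose(aff.p.sum(axis=1), 1.0)
        assert np.allclose(np.diag(aff.p), 0.5)

    def test_s_supported_on_k_neighbors_rows_sum_one(self):
        aff = affinity_matrix(self._dist(), FusionParams(K=2, mu=0.5))
        assert np.allclose(aff.s.sum(axis=1), 1.0)
        assert np.all((aff.s > 0).sum(axis=1) == 2)
        assert np.allclose(np.diag(aff.s), 0.0)

    def test_k_must_be_below_n(self):
        with pytest.raises(ValueError):
            affinity_matrix(self._dist(), FusionParams(K=4, mu=0.5))


# ---------------------------------------------------------------- fusion


def full_normalize_oracle(w):
    n = len(w)
    p = np.zeros_like(w)
    for i in range(n):
        row = sum(w[i, j] for j in range(n) if j != i)
        for j in range(n):
            p[i, j] = 0.5 if i == j else w[i, j] / (2 * row)
    return p


def snf_oracle(affinities, T):
    """Dense-loop re-implementation of the cross-network diffusion."""
    ps = [a.p.copy() for a in affinities]
    ss = [a.s for a in affinities]
    m = len(ps)
    for _ in range(T):
        updated = []
        for v in range(m):
            mean_others = sum(ps[k] for k in range(m) if k != v) / (m - 1)
            raw = ss[v] @ mean_others @ ss[v].T
            assert np.all(raw >= -1e-12), "diffusion produced negative mass"
            updated.append(full_normalize_oracle(raw))
        ps = updated
    fused = sum(ps) / m
    return (fused + fused.T) / 2


def two_block_views(n_per=10, sep=6.0, seed=0, n_feat=12):
    rng = np.random.default_rng(seed)
    shift = np.zeros((n_feat, 2 * n_per))
    shift[:, n_per:] = sep
    views = []
    for _ in range(2):
        x = rng.normal(size=(n_feat, 2 * n_per)) + shift
        m = make_expr(x)
        w = pd.Series(1.0 / n_feat, index=m.features)
        d = weighted_distance_matrix(m, w, standardize=False)
        views.append(affinity_matrix(d, FusionParams(K=4, mu=0.5)))
    return views


class TestSnfFuse:
    def test_single_view_returns_symmetrized_full_kernel(self):
        aff = two_block_views()[0]
        fused = snf_fuse([aff], FusionParams(K=4, mu=0.5))
        assert np.allclose(fused.matrix, (aff.p + aff.p.T) / 2)
        assert fused.iterations == 0

    def test_two_identical_views_match_dense_loop_oracle(self):
        aff = two_block_views(seed=3)[0]
        pair = [aff, AffinityMatrix(kernel=aff.kernel, p=aff.p.copy(), s=aff.s, samples=aff.samples)]
        params = FusionParams(K=4, mu=0.5, T=10)
        fused = snf_fuse(pair, params)
        expected = snf_oracle(pair, T=10)
        assert np.max(np.abs(fused.matrix - expected)) <= 1e-6
        assert np.allclose(fused.matrix, fused.matrix.T)
        assert np.all(fused.matrix >= 0)

    def test_block_structure_survives_fusion(self):
        views = two_block_views(seed=5)
        fused = snf_fuse(views, FusionParams(K=4, mu=0.5, T=20)).matrix
        n = 10
        for i in range(2 * n):
            own = slice(0, n) if i < n else slice(n, 2 * n)
            other = slice(n, 2 * n) if i < n else slice(0, n)
            assert fused[i, own].sum() > fused[i, other].sum()

    def test_sample_mismatch_rejected(self):
        a, b = two_block_views()
        b.samples = list(reversed(b.samples))
        with pytest.raises(ValueError, match="sample"):
            snf_fuse([a, b], FusionParams(K=4, mu=0.5))
        with pytest.raises(ValueError):
            snf_fuse([], FusionParams())


# ---------------------------------------------------------------- clustering


def block_similarity(sizes, within=1.0, between=0.0, noise=0.0, seed=0):
    n = sum(sizes)
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    s = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if noise:
        sym = rng.random((n, n)) * noise
        s += (sym + sym.T) / 2
    np.fill_diagonal(s, within)
    return FusedNetwork(matrix=s, samples=[f"S{i}" for i in range(n)], iterations=0), labels


class TestClusterNumber:
    def test_exact_three_blocks_found(self):
        fused, _ = block_similarity([5, 6, 7])
        candidates, n_components = estimate_num_clusters(fused, 2, 6)
        assert candidates[0] == 3
        assert n_components == 3

    def test_uniform_similarity_still_returns_ranking(self):
        fused = FusedNetwork(matrix=np.ones((8, 8)), samples=[f"S{i}" for i in range(8)], iterations=0)
        candidates, _ = estimate_num_clusters(fused, 2, 5)
        assert sorted(candidates) == [2, 3, 4, 5]

    def test_planted_five_blocks_with_noise(self):
        fused, _ = block_similarity([12, 12, 12, 12, 12], within=1.0, between=0.0, noise=0.05, seed=4)
        candidates, _ = estimate_num_clusters(fused, 2, 8)
        assert candidates[0] == 5


class TestSpectralCluster:
    def test_exact_two_blocks_recovered(self):
        fused, labels = block_similarity([6, 6])
        assignment = spectral_cluster(fused, k=2, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, assignment.labels.to_numpy()) == 1.0
        assert sorted(assignment.labels.unique()) == [1, 2]

    def test_deterministic_under_seed(self):
        fused, _ = block_similarity([5, 5, 5], noise=0.2, seed=9)
        a = spectral_cluster(fused, k=3, seed=7).labels
        b = spectral_cluster(fused, k=3, seed=7).labels
        assert a.equals(b)

    def test_k_bounds_enforced(self):
        fused, _ = block_similarity([3, 3])
        with pytest.raises(ValueError):
            spectral_cluster(fused, k=6, seed=0)
        with pytest.raises(ValueError):
            spectral_cluster(fused, k=1, seed=0)
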