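"""Weighted patient distances, similarity-network fusion, and clustering.

Per data view, patient distances are weighted Euclidean::

    Distance(S_i, S_j) = sqrt( sum_m W(f_m) * (f_m^{S_i} - f_m^{S_j})^2 )

so with uniform weights ``W = 1/p`` this is the plain Euclidean distance
divided by ``sqrt(p)``.  Each view's distance matrix becomes a scaled
exponential affinity kernel; the per-view kernels are fused by the
cross-network diffusion of similarity network fusion (SNF): each view's
full kernel is repeatedly propagated through the other views' sparse
(K-nearest-neighbor) kernels until the views agree, and the fused
patient similarity is their average.  Subtypes are then read off by
normalized spectral clustering, with the cluster number either supplied
or estimated from the eigengap of the normalized graph Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .network import RegulatoryNetwork
from .preprocess import ExpressionMatrix
from .ranking import RankingParams, rank_features
from .weighting import WeightingParams, WeightVector, compute_weights, mad

_EPS = 1e-20


@dataclass(frozen=True)
class FusionParams:
    """SNF hyperparameters.

    K
        neighborhood size for the local kernels (must be < n_samples).
    mu
        bandwidth multiplier of the scaled exponential kernel
        (customary range 0.3-0.8).
    T
        number of diffusion iterations.
    standardize
        z-score each feature across samples before computing distances.
    """

    K: int = 20
    mu: float = 0.5
    T: int = 20
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass
class DistanceMatrix:
    matrix: np.ndarray  # n x n, symmetric, zero diagonal
    samples: list[str]
    view: str = ""


@dataclass
class AffinityMatrix:
    """Full kernel W, row-stochastic full kernel P, KNN-masked kernel S."""

    kernel: np.ndarray
    p: np.ndarray  # P(i,i) = 1/2, off-diagonal rows sum to 1/2
    s: np.ndarray  # support only on each row's K nearest neighbors
    samples: list[str]
    view: str = ""


@dataclass
class FusedNetwork:
    matrix: np.ndarray  # symmetric nonnegative similarity
    samples: list[str]
    iterations: int
    view_status: list[np.ndarray] = field(default_factory=list)


@dataclass
class SubtypeAssignment:
    """Sample -> cluster label in {1..k}, with provenance."""

    labels: pd.Series
    k: int
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        present = sorted(set(self.labels))
        if present != list(range(1, self.k + 1)):
            raise ValueError(f"labels must be contiguous 1..{self.k}, got {present}")


def weighted_distance_matrix(
    view: ExpressionMatrix,
    weights: WeightVector | pd.Series,
    standardize: bool = True,
) -> DistanceMatrix:
    """Weighted Euclidean distances between samples of one view.

    Equivalent to Euclidean distance after rescaling each feature by
    ``sqrt(W)`` — hence a true metric.  Optional per-feature z-scoring
    (population SD; zero-variance features are left centered at 0) is
    applied first.
    """
    if len(view.samples) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    w = weights.for_features(view.features) if isinstance(weights, WeightVector) else weights.loc[view.features]
    w = w.to_numpy(dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    x = view.values.to_numpy(dtype=float)  # features x samples
    if np.isnan(x).any():
        raise ValueError("expression contains missing values; impute first")
    if standardize:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    scaled = (x * np.sqrt(w)[:, None]).T  # samples x features
    d = squareform(pdist(scaled, metric="euclidean"))
    return DistanceMatrix(matrix=d, samples=view.samples, view=view.view)


def affinity_matrix(dist: DistanceMatrix, params: FusionParams) -> AffinityMatrix:
    """Scaled exponential kernel plus its two SNF normalizations.

    kernel(i,j) = exp(-d(i,j)^2 / (mu * eps_ij)) with
    eps_ij = (mean d to i's K nearest + mean d to j's K nearest + d(i,j)) / 3.
    P is the row-stochastic full kernel (diagonal 1/2, off-diagonal rows
    summing to 1/2); S is the kernel row-normalized over each row's K
    nearest neighbors (self excluded) and zero elsewhere.
    """
    d = dist.matrix
    n = d.shape[0]
    if params.K >= n:
        raise ValueError(f"K={params.K} must be < n_samples={n}")
    # mean distance to the K nearest neighbors, self excluded
    d_sorted = np.sort(d, axis=1)  # column 0 is the zero self-distance
    knn_mean = d_sorted[:, 1 : params.K + 1].mean(axis=1)
    eps = (knn_mean[:, None] + knn_mean[None, :] + d) / 3.0
    eps = np.maximum(eps, _EPS)  # duplicate-point guard
    kernel = np.exp(-(d**2) / (params.mu * eps))
    p = _full_kernel_normalize(kernel)
    # local kernel: keep each row's K nearest neighbors (self excluded)
    order = np.argsort(d, axis=1)
    s = np.zeros_like(kernel)
    for i in range(n):
        neighbors = [j for j in order[i] if j != i][: params.K]
        s[i, neighbors] = kernel[i, neighbors]
    s /= s.sum(axis=1, keepdims=True)
    return AffinityMatrix(kernel=kernel, p=p, s=s, samples=dist.samples, view=dist.view)


def _full_kernel_normalize(w: np.ndarray) -> np.ndarray:
    """P(i,i) = 1/2; P(i,j) = w(i,j) / (2 * sum_{k != i} w(i,k))."""
    off = w.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1, keepdims=True)
    row[row == 0] = _EPS
    p = off / (2.0 * row)
    np.fill_diagonal(p, 0.5)
    return p


def snf_fuse(views: Sequence[AffinityMatrix], params: FusionParams) -> FusedNetwork:
    """Fuse per-view kernels by cross-network diffusion.

    For m >= 2 views, iterate T times with synchronous updates::

        P(v) <- S(v) @ mean_{k != v} P(k) @ S(v).T

    re-normalizing each updated P to the (1/2, 1/2) row-stochastic form.
    The fused similarity is the symmetrized mean of the final P's.  A
    single view is returned as its symmetrized full kernel (no
    diffusion).
    """
    if len(views) == 0:
        raise ValueError("need at least one view")
    samples = views[0].samples
    for v in views[1:]:
        if v.samples != samples:
            raise ValueError("views must share the same sample set and order")
    if len(views) == 1:
        p = views[0].p
        return FusedNetwork(matrix=(p + p.T) / 2.0, samples=samples, iterations=0, view_status=[p])
    ps = [v.p.copy() for v in views]
    ss = [v.s for v in views]
    m = len(views)
    for _ in range(params.T):
        new_ps = []
        for v in range(m):
            others = sum(ps[k] for k in range(m) if k != v) / (m - 1)
            updated = ss[v] @ others @ ss[v].T
            new_ps.append(_full_kernel_normalize(updated))
        ps = new_ps
    fused = sum(ps) / m
    fused = (fused + fused.T) / 2.0
    return FusedNetwork(matrix=fused, samples=samples, iterations=params.T, view_status=ps)


def _normalized_laplacian(w: np.ndarray) -> np.ndarray:
    deg = w.sum(axis=1)
    deg[deg == 0] = _EPS
    inv_sqrt = 1.0 / np.sqrt(deg)
    return np.eye(len(w)) - (inv_sqrt[:, None] * w) * inv_sqrt[None, :]


def estimate_num_clusters(fused: FusedNetwork, k_min: int = 2, k_max: int = 8):
    """Rank candidate cluster numbers by the eigengap of the normalized Laplacian.

    Returns ``(candidates, n_components)``: candidate k's sorted by
    decreasing gap between consecutive Laplacian eigenvalues, and the
    number of connected components of the similarity graph (equals the
    best k exactly for block-diagonal similarity).
    """
    n = len(fused.samples)
    if not 2 <= k_min <= k_max < n:
        raise ValueError(f"need 2 <= k_min <= k_max < n; got {k_min}, {k_max}, n={n}")
    lap = _normalized_laplacian(fused.matrix)
    evals = eigh(lap, eigvals_only=True)
    gaps = {k: evals[k] - evals[k - 1] for k in range(k_min, k_max + 1)}
    candidates = sorted(gaps, key=lambda k: (-gaps[k], k))
    n_components = connected_components(fused.matrix > 0, directed=False)[0]
    return candidates, n_components


def spectral_cluster(fused: FusedNetwork, k: int, seed: int = 0) -> SubtypeAssignment:
    """Normalized spectral clustering of the fused similarity.

    Takes the eigenvectors of the normalized Laplacian for the k
    smallest eigenvalues, row-normalizes them to unit length, and runs
    seeded k-means with 50 restarts.  Deterministic given the seed.
    Labels are relabeled to 1..k in order of first appearance.
    """
    n = len(fused.samples)
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n_samples; got k={k}, n={n}")
    lap = _normalized_laplacian(fused.matrix)
    _, vecs = eigh(lap, subset_by_index=(0, k - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    embedding = vecs / norms
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    raw = km.fit_predict(embedding)
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    labels = pd.Series([relabel[l] for l in raw], index=fused.samples, name="subtype")
    return SubtypeAssignment(labels=labels, k=k, seed=seed, params={"method": "spectral+kmeans", "n_init": 50})


@dataclass
class WSNFResult:
    """End-to-end pipeline output with all intermediates."""

    assignment: SubtypeAssignment
    fused: FusedNetwork
    weights: WeightVector
    ranks: pd.Series
    distances: dict[str, DistanceMatrix]
    affinities: dict[str, AffinityMatrix]
    k_candidates: list[int] | None = None


def run_wsnf(
    gene_view: ExpressionMatrix,
    mirna_view: ExpressionMatrix,
    net: RegulatoryNetwork,
    wparams: WeightingParams | None = None,
    rparams: RankingParams | None = None,
    fparams: FusionParams | None = None,
    k: int | str = "auto",
    seed: int = 0,
) -> WSNFResult:
    """Rank -> weight -> weighted distances -> fusion -> spectral clustering.

    The two views must share an identical, identically ordered sample
    set; network nodes must be covered by the views' features (so every
    ranked feature has an expression variation).
    """
    wparams = wparams or WeightingParams()
    rparams = rparams or RankingParams()
    fparams = fparams or FusionParams()
    if gene_view.samples != mirna_view.samples:
        extra = set(gene_view.samples) ^ set(mirna_view.samples)
        raise ValueError(f"views disagree on samples (offending ids: {sorted(extra)[:10] or 'ordering'})")

    rank = rank_features(net, rparams)
    mads = pd.concat(
        [
            gene_view.values.apply(lambda row: mad(row.to_numpy()), axis=1),
            mirna_view.values.apply(lambda row: mad(row.to_numpy()), axis=1),
        ]
    )
    weights = compute_weights(rank, mads, net.classes, wparams)

    distances, affinities = {}, {}
    for view in (gene_view, mirna_view):
        d = weighted_distance_matrix(view, weights, standardize=fparams.standardize)
        distances[view.view] = d
        affinities[view.view] = affinity_matrix(d, fparams)
    fused = snf_fuse([affinities[gene_view.view], affinities[mirna_view.view]], fparams)

    k_candidates = None
    if k == "auto":
        k_candidates, _ = estimate_num_clusters(fused)
        k_use = k_candidates[0]
    else:
        k_use = int(k)
    assignment = spectral_cluster(fused, k_use, seed=seed)
    return WSNFResult(
        assignment=assignment,
        fused=fused,
        weights=weights,
        ranks=rank.ranks,
        distances=distances,
        affinities=affinities,
        k_candidates=k_candidates,
    )
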