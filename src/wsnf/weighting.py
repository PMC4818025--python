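"""Feature weights: combining regulatory rank with expression variation.

The per-feature weight is a convex combination of two simplex-normalized
signals: the network-derived rank ``RN`` and the median absolute
deviation of expression across samples ``MADN``::

    W(f) = beta * RN(f) + (1 - beta) * MADN(f)

with ``beta`` in [0, 1] (default 0.8, emphasising the network).  Since
both inputs sum to one, so does W for any beta.

The module also ships a GeneRank-style weight (the teleport term of the
rank recursion replaced by the normalized MAD) together with a
correlation diagnostic: GeneRank-style weights are dominated by the
graph structure and correlate strongly with the rank-only weights,
which is precisely why the convex combination above is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve
from scipy.stats import pearsonr

from .network import RegulatoryNetwork
from .ranking import RankVector, _rank_operator


@dataclass(frozen=True)
class WeightingParams:
    beta: float = 0.8
    per_view: bool = False  # normalize RN/MADN within each view instead of jointly

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")


@dataclass
class WeightVector:
    """Per-feature rank, variation, their normalizations and final W."""

    table: pd.DataFrame  # columns: klass, rank, RN, MAD, MADN, W
    beta: float

    @property
    def w(self) -> pd.Series:
        return self.table["W"]

    def for_features(self, features) -> pd.Series:
        missing = [f for f in features if f not in self.table.index]
        if missing:
            raise KeyError(f"features without a weight: {missing[:10]}")
        return self.table.loc[list(features), "W"]


def mad(values) -> float:
    """Median absolute deviation: median(|X - median(X)|).

    No consistency scaling constant is applied; even-length medians use
    the midpoint of the two central order statistics.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad of an empty vector is undefined")
    if not np.all(np.isfinite(x)):
        raise ValueError("mad requires finite values; impute missing data first")
    return float(np.median(np.abs(x - np.median(x))))


def normalize_simplex(v) -> np.ndarray:
    """Scale a nonnegative vector to sum to one."""
    x = np.asarray(v, dtype=float)
    if np.any(x < 0):
        raise ValueError("simplex normalization requires nonnegative entries")
    total = x.sum()
    if total == 0:
        raise ValueError("cannot normalize an all-zero vector")
    return x / total


def combine_weights(rn, madn, beta: float) -> np.ndarray:
    """W = beta * RN + (1 - beta) * MADN on aligned simplex vectors."""
    rn = np.asarray(rn, dtype=float)
    madn = np.asarray(madn, dtype=float)
    if rn.shape != madn.shape:
        raise ValueError(f"length mismatch: RN has {rn.shape}, MADN has {madn.shape}")
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    return beta * rn + (1.0 - beta) * madn


def compute_weights(
    rank: RankVector,
    mads: pd.Series,
    classes: dict[str, str],
    params: WeightingParams | None = None,
) -> WeightVector:
    """Assemble the full weight table for all network features.

    ``mads`` must cover every ranked feature.  By default RN and MADN
    are normalized jointly over all N features — the literal reading of
    the normalization sums — even though gene and miRNA expression live
    on different scales; ``per_view=True`` normalizes within each view
    (miRNA vs genes) separately so each view's weights sum to one.
    """
    params = params or WeightingParams()
    features = list(rank.ranks.index)
    missing = [f for f in features if f not in mads.index]
    if missing:
        raise KeyError(f"no expression variation for ranked features: {missing[:10]}")
    r = rank.ranks.to_numpy()
    m = mads.loc[features].to_numpy(dtype=float)
    klass = pd.Series({f: classes[f] for f in features})

    if params.per_view:
        is_mirna = (klass == "miRNA").to_numpy()
        rn = np.empty_like(r)
        madn = np.empty_like(m)
        for mask in (is_mirna, ~is_mirna):
            if mask.any():
                rn[mask] = normalize_simplex(r[mask])
                madn[mask] = normalize_simplex(m[mask])
    else:
        rn = normalize_simplex(r)
        madn = normalize_simplex(m)

    w = combine_weights(rn, madn, params.beta)
    table = pd.DataFrame(
        {"klass": klass.values, "rank": r, "RN": rn, "MAD": m, "MADN": madn, "W": w},
        index=pd.Index(features, name="feature"),
    )
    return WeightVector(table=table, beta=params.beta)


def generank_weights(net: RegulatoryNetwork, mads: pd.Series, d: float = 0.85) -> pd.Series:
    """GeneRank/NCIS-style weights: MAD replaces the uniform teleport term.

    Solves ``W = (1 - d) * MADN + d * M W`` exactly, where M is the same
    target-averaging operator as the rank recursion.  Provided for the
    correlation diagnostic only.
    """
    features = net.features
    madn = normalize_simplex(mads.loc[features].to_numpy(dtype=float))
    m = _rank_operator(net)
    n = net.n_features
    a = sp.eye(n, format="csc") - d * m.tocsc()
    w = np.atleast_1d(spsolve(a, (1.0 - d) * madn))
    return pd.Series(w, index=features, name="generank_weight")


def rank_weight_correlation(rank: RankVector, w_generank, w_linear) -> tuple[float, float]:
    """Pearson correlations of two candidate weightings with rank-only weights.

    Returns ``(r_generank, r_linear)``: each candidate vector correlated
    against the simplex-normalized rank.  A candidate that merely
    shadows the rank (high correlation) adds no expression information.
    """
    rn = normalize_simplex(rank.ranks.to_numpy())
    out = []
    for w in (np.asarray(w_generank, float), np.asarray(w_linear, float)):
        if w.shape != rn.shape:
            raise ValueError("weight vector length does not match rank vector")
        if w.size < 3:
            raise ValueError("correlation needs at least 3 features")
        if np.std(w) == 0 or np.std(rn) == 0:
            raise ValueError("correlation undefined for zero-variance input")
        out.append(float(pearsonr(rn, w).statistic))
    return out[0], out[1]
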