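"""Expression-matrix preparation.

Mirrors the preparation applied to TCGA-style inputs: log2 transform of
count-like values, K-nearest-feature imputation of missing microarray
observations, removal of a low-mean quantile of features, and removal
of features below a standard-deviation threshold.  All filters remove
features only — the sample set is never touched — and the pipeline is
order-dependent: the RNA-seq path is log2 -> low-mean -> low-SD, the
microarray path is impute -> low-SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer


@dataclass
class ExpressionMatrix:
    """One view's features x samples expression grid.

    ``values`` is indexed by feature id with sample ids as columns;
    ``classes`` maps each feature to miRNA/TF/mRNA; ``view`` tags the
    data type ("genes" or "miRNA").  ``steps`` records the
    preprocessing operations applied, in order.
    """

    values: pd.DataFrame
    classes: dict[str, str] | None = None
    view: str = "genes"
    steps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:10]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def _with(self, values: pd.DataFrame, step: str) -> "ExpressionMatrix":
        return replace(self, values=values, steps=[*self.steps, step])


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise value -> log2(value + pseudocount)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    vals = m.values.to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        raise ValueError("log2 transform requires nonnegative expression values")
    out = pd.DataFrame(np.log2(vals + pseudocount), index=m.values.index, columns=m.values.columns)
    return m._with(out, f"log2(+{pseudocount:g})")


def impute_missing(m: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Fill missing cells from the k nearest features.

    Feature-to-feature distances are Euclidean over co-observed samples;
    a missing cell takes the mean of the neighbors' observed values in
    that sample (the behavior of the classic microarray KNN imputer).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = m.values.to_numpy(dtype=float)
    fully_missing = np.isnan(vals).all(axis=1)
    if fully_missing.any():
        names = m.values.index[fully_missing].tolist()
        raise ValueError(f"features with no observed values cannot be imputed: {names[:10]}")
    if not np.isnan(vals).any():
        return m._with(m.values.copy(), "impute(noop)")
    # rows are features, so neighbors are features, as required
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    out = pd.DataFrame(imputer.fit_transform(vals), index=m.values.index, columns=m.values.columns)
    return m._with(out, f"impute(k={k})")


def filter_low_mean(m: ExpressionMatrix, drop_fraction: float) -> ExpressionMatrix:
    """Drop the ``floor(drop_fraction * n)`` features with lowest mean.

    Ties at the cutoff keep the earlier row (later rows drop first).
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError(f"drop_fraction must be in [0, 1), got {drop_fraction}")
    if m.values.empty:
        raise ValueError("cannot filter an empty matrix")
    n = len(m.values)
    n_drop = int(np.floor(drop_fraction * n))
    if n_drop == 0:
        return m._with(m.values.copy(), f"low_mean({drop_fraction:g})")
    means = m.values.mean(axis=1).to_numpy()
    # primary key mean ascending; among ties, later input rows sort first
    order = np.lexsort((-np.arange(n), means))
    keep = np.ones(n, dtype=bool)
    keep[order[:n_drop]] = False
    return m._with(m.values.iloc[keep], f"low_mean({drop_fraction:g})")


def filter_low_sd(m: ExpressionMatrix, threshold: float) -> ExpressionMatrix:
    """Drop features with sample SD (n-1 denominator) strictly below threshold."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if m.values.shape[1] < 2:
        raise ValueError("standard deviation undefined with fewer than 2 samples")
    sds = m.values.std(axis=1, ddof=1)
    return m._with(m.values.loc[sds >= threshold], f"low_sd({threshold:g})")


def preprocess_rnaseq(
    m: ExpressionMatrix,
    pseudocount: float = 1.0,
    drop_fraction: float = 0.25,
    sd_threshold: float = 0.5,
) -> ExpressionMatrix:
    """RNA-seq path: log2 -> low-mean quantile filter -> SD filter."""
    return filter_low_sd(filter_low_mean(log2_transform(m, pseudocount), drop_fraction), sd_threshold)


def preprocess_microarray(m: ExpressionMatrix, k: int = 10, sd_threshold: float = 0.6) -> ExpressionMatrix:
    """Microarray path: KNN imputation -> SD filter."""
    return filter_low_sd(impute_missing(m, k), sd_threshold)
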