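"""Subtype validation: silhouette width, core samples, survival separation.

Cluster quality on the fused similarity matrix is assessed with the
silhouette width after converting similarity to dissimilarity
(``1 - min-max-scaled similarity`` over the off-diagonal entries, a
configurable convention).  "Core" samples are those with nonnegative
silhouette width.  Clinical relevance is assessed with the k-group
log-rank test on overall survival; synthetic-recovery experiments use
the adjusted Rand index against known labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import adjusted_rand_score

from .fusion import FusedNetwork, SubtypeAssignment


@dataclass
class SurvivalRecord:
    sample: str
    time: float  # days
    event: int  # 1 = death observed, 0 = censored

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.sample}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass
class SilhouetteResult:
    widths: pd.Series  # per-sample s_i in [-1, 1]
    cluster_sizes: dict[int, int]
    average: float


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def similarity_to_dissimilarity(similarity: np.ndarray) -> np.ndarray:
    """1 - similarity min-max scaled to [0, 1] over off-diagonal entries."""
    s = np.asarray(similarity, dtype=float)
    off = ~np.eye(len(s), dtype=bool)
    lo, hi = s[off].min(), s[off].max()
    scale = hi - lo if hi > lo else 1.0
    d = 1.0 - (s - lo) / scale
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def silhouette_from_similarity(fused: FusedNetwork, assignment: SubtypeAssignment) -> SilhouetteResult:
    """Silhouette widths of a clustering of the fused similarity matrix.

    s_i = (b_i - a_i) / max(a_i, b_i) with a_i the mean within-cluster
    dissimilarity (self excluded) and b_i the smallest mean
    dissimilarity to another cluster.  Samples in singleton clusters get
    s_i = 0 by convention.
    """
    labels = assignment.labels.loc[fused.samples].to_numpy()
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    d = similarity_to_dissimilarity(fused.matrix)
    n = len(labels)
    widths = np.zeros(n)
    for i in range(n):
        own = labels[i]
        mask_own = labels == own
        if mask_own.sum() == 1:
            widths[i] = 0.0  # singleton convention
            continue
        a = d[i, mask_own].sum() / (mask_own.sum() - 1)
        b = min(d[i, labels == other].mean() for other in uniq if other != own)
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    series = pd.Series(widths, index=fused.samples, name="silhouette")
    sizes = {int(c): int((labels == c).sum()) for c in uniq}
    return SilhouetteResult(widths=series, cluster_sizes=sizes, average=float(series.mean()))


def core_samples(sil: SilhouetteResult, assignment: SubtypeAssignment) -> tuple[list[str], dict[int, int]]:
    """Samples with nonnegative silhouette width, plus per-subtype counts.

    Only strictly negative widths are removed (s_i = 0 is retained).
    """
    keep = sil.widths.index[sil.widths >= 0].tolist()
    counts = assignment.labels.loc[keep].value_counts().sort_index()
    return keep, {int(k): int(v) for k, v in counts.items()}


def logrank_test(survival: pd.DataFrame | list[SurvivalRecord], assignment: SubtypeAssignment) -> LogrankResult:
    """k-group log-rank test of survival separation between subtypes.

    At each distinct event time the observed event count per group is
    compared with its hypergeometric expectation; the chi-square
    statistic has k - 1 degrees of freedom.  Requires >= 2 groups and at
    least one observed event.
    """
    if isinstance(survival, list):
        survival = pd.DataFrame(
            {"sample": [r.sample for r in survival], "time": [r.time for r in survival], "event": [r.event for r in survival]}
        )
    surv = survival.set_index("sample") if "sample" in survival.columns else survival
    missing = [s for s in surv.index if s not in assignment.labels.index]
    if missing:
        raise ValueError(f"survival records without a subtype label: {missing[:10]}")
    groups = assignment.labels.loc[surv.index]
    if groups.nunique() < 2:
        raise ValueError("log-rank test requires at least 2 groups")
    if (surv["event"] == 0).all():
        raise ValueError("log-rank test undefined with no observed events")
    res = multivariate_logrank_test(surv["time"], groups, surv["event"])
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=int(groups.nunique() - 1),
        p_value=float(res.p_value),
    )


def adjusted_rand_index(a: SubtypeAssignment | pd.Series, b: SubtypeAssignment | pd.Series) -> float:
    """Chance-corrected partition agreement; 1 iff identical up to relabeling."""
    sa = a.labels if isinstance(a, SubtypeAssignment) else a
    sb = b.labels if isinstance(b, SubtypeAssignment) else b
    if set(sa.index) != set(sb.index):
        raise ValueError("partitions cover different sample sets")
    sb = sb.loc[sa.index]
    return float(adjusted_rand_score(sa.to_numpy(), sb.to_numpy()))
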