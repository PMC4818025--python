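"""Readers and writers for the plain-text exchange formats.

Expression TSV: first column ``feature``, remaining columns sample ids,
missing values encoded ``NA``.  Edge lists, feature classes, weights,
subtype labels and fused similarity matrices are TSV; survival tables
are CSV with header ``sample,time,event``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fusion import FusedNetwork, SubtypeAssignment
from .preprocess import ExpressionMatrix
from .weighting import WeightVector


def read_expression(path, classes: dict[str, str] | None = None, view: str = "genes") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature", na_values=["NA"])
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df, classes=classes, view=view)


def write_expression(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="feature", na_rep="NA")


def write_edges(edges, path) -> None:
    pd.DataFrame(sorted(edges), columns=["regulator", "target"]).to_csv(path, sep="\t", index=False)


def write_classes(classes: dict[str, str], path) -> None:
    pd.DataFrame(sorted(classes.items()), columns=["feature", "class"]).to_csv(path, sep="\t", index=False)


def write_weights(w: WeightVector, path) -> None:
    w.table.to_csv(path, sep="\t", index_label="feature")


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"sample", "time", "event"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns sample,time,event")
    return df


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("subtype").to_csv(path, sep="\t", index_label="sample")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    return df.iloc[:, 0]


def write_fused(fused: FusedNetwork, path) -> None:
    pd.DataFrame(fused.matrix, index=fused.samples, columns=fused.samples).to_csv(path, sep="\t", index_label="sample")


def read_fused(path) -> FusedNetwork:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    return FusedNetwork(matrix=df.to_numpy(dtype=float), samples=list(df.columns), iterations=-1)


def assignment_from_labels(labels: pd.Series, seed: int = 0) -> SubtypeAssignment:
    """Wrap raw labels (any hashable values) as a contiguous-1..k assignment."""
    uniq = {v: i + 1 for i, v in enumerate(sorted(pd.unique(labels)))}
    mapped = labels.map(uniq).astype(int)
    return SubtypeAssignment(labels=mapped, k=len(uniq), seed=seed)
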