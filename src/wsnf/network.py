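"""miRNA-TF-mRNA regulatory network construction.

A regulatory network is a directed graph whose nodes are molecular
features (miRNAs, transcription factors, mRNAs) and whose edges point
from a regulator to its target.  Edge lists come from upstream database
exports (Tarbase, miRTarBase, starBase, ENCODE, TRED, TransmiR,
Reactome, STRING, ...) already reduced to ``regulator<TAB>target``
tables; this module merges them, restricts them to the features that
actually appear in the expression data, and exposes the two quantities
the ranking recursion needs: the target set ``T(f)`` of each feature and
the regulator count (in-degree) ``L(f)`` of each feature.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

KLASSES = ("miRNA", "TF", "mRNA")

#: Interaction classes a regulatory edge may belong to, keyed by the
#: (regulator klass, target klass) pair.
INTERACTION_CLASSES = {
    ("miRNA", "mRNA"): "miRNA->mRNA",
    ("miRNA", "TF"): "miRNA->TF",
    ("TF", "miRNA"): "TF->miRNA",
    ("TF", "mRNA"): "TF->mRNA",
    ("TF", "TF"): "TF->TF",
    ("mRNA", "mRNA"): "mRNA->mRNA",
}


class NetworkFormatError(ValueError):
    """Malformed edge-list or class file."""


class EmptyTableError(ValueError):
    """Edge-list file contains a header but no data rows."""


class ClassConflictError(ValueError):
    """The same feature id was assigned two different classes."""


@dataclass(frozen=True)
class FeatureId:
    """A typed feature: gene symbol or miRNA name plus its class."""

    id: str
    klass: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("feature id must be non-empty")
        if self.klass not in KLASSES:
            raise ValueError(f"unknown feature class {self.klass!r}; expected one of {KLASSES}")


@dataclass
class InteractionTable:
    """Parsed rows of one edge-list file (order preserved)."""

    rows: pd.DataFrame  # columns: regulator, target, source
    expected_class: str = "any"

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class RegulatoryNetwork:
    """Directed typed graph restricted to an expression-feature universe.

    ``classes`` maps every node id to its class; isolated features (no
    interactions) are retained as degree-0 nodes so that every feature
    receives a baseline rank from the teleport term of the ranking
    recursion.
    """

    classes: dict[str, str]
    edges: set[tuple[str, str]]
    dropped_outside_universe: int = 0
    dropped_self_loops: int = 0
    duplicate_edges: int = 0
    _features: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("network must contain at least one node")
        for reg, tgt in self.edges:
            if reg not in self.classes or tgt not in self.classes:
                raise ValueError(f"edge endpoint not in node set: ({reg!r}, {tgt!r})")
        if not self._features:
            self._features = sorted(self.classes)

    @property
    def features(self) -> list[str]:
        """Node ids in a deterministic (sorted) order."""
        return self._features

    @property
    def n_features(self) -> int:
        return len(self._features)

    def targets(self) -> dict[str, set[str]]:
        """T(f): the set of targets each feature regulates."""
        t: dict[str, set[str]] = {f: set() for f in self._features}
        for reg, tgt in self.edges:
            t[reg].add(tgt)
        return t

    def in_degree(self) -> dict[str, int]:
        """L(f): the number of regulators of each feature."""
        l = dict.fromkeys(self._features, 0)
        for _, tgt in self.edges:
            l[tgt] += 1
        return l

    def out_degree(self) -> dict[str, int]:
        d = dict.fromkeys(self._features, 0)
        for reg, _ in self.edges:
            d[reg] += 1
        return d


def make_universe(features: Iterable[FeatureId] | Mapping[str, str]) -> dict[str, str]:
    """Resolve feature ids to classes, refusing conflicting assignments.

    An id may carry exactly one class per run (a symbol cannot be both
    TF and mRNA); conflicts are surfaced, never silently resolved.
    """
    if isinstance(features, Mapping):
        items = list(features.items())
    else:
        items = [(f.id, f.klass) for f in features]
    universe: dict[str, str] = {}
    conflicts: dict[str, set[str]] = {}
    for fid, klass in items:
        if klass not in KLASSES:
            raise NetworkFormatError(f"unknown class {klass!r} for feature {fid!r}")
        if fid in universe and universe[fid] != klass:
            conflicts.setdefault(fid, {universe[fid]}).add(klass)
        universe[fid] = universe.get(fid, klass)
    if conflicts:
        detail = "; ".join(f"{fid}: {sorted(ks)}" for fid, ks in sorted(conflicts.items()))
        raise ClassConflictError(f"features with conflicting class assignments: {detail}")
    return universe


def load_feature_classes(path) -> dict[str, str]:
    """Read a ``feature<TAB>class`` TSV into an id -> class mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"feature", "class"}.issubset(df.columns):
        raise NetworkFormatError(f"{path}: expected columns 'feature' and 'class', got {list(df.columns)}")
    return make_universe(dict(zip(df["feature"].str.strip(), df["class"].str.strip())))


def load_interactions(path, expected_class: str = "any") -> InteractionTable:
    """Parse an edge-list TSV (``regulator<TAB>target[<TAB>source]``).

    Ids are whitespace-trimmed and row order is preserved.  Raises
    :class:`NetworkFormatError` on missing columns or blank ids (the
    error names the offending line) and :class:`EmptyTableError` for a
    header-only file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"regulator", "target"}
    if not required.issubset(df.columns):
        raise NetworkFormatError(
            f"{path}: expected header columns 'regulator' and 'target', got {list(df.columns)}"
        )
    if len(df) == 0:
        raise EmptyTableError(f"{path}: no interaction rows")
    if "source" not in df.columns:
        df["source"] = ""
    df = df[["regulator", "target", "source"]].copy()
    df["regulator"] = df["regulator"].str.strip()
    df["target"] = df["target"].str.strip()
    blank = (df["regulator"] == "") | (df["target"] == "")
    if blank.any():
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in df.index[blank]]
        raise NetworkFormatError(f"{path}: blank regulator/target id on line(s) {lines}")
    return InteractionTable(rows=df.reset_index(drop=True), expected_class=expected_class)


def build_network(
    tables: Iterable[InteractionTable],
    universe: Mapping[str, str] | Iterable[FeatureId],
) -> RegulatoryNetwork:
    """Merge edge lists into one deduplicated network over ``universe``.

    Edges are pooled across tables and collapsed to unweighted
    (regulator, target) pairs regardless of source.  Edges with either
    endpoint absent from the universe, and self-loops, are dropped and
    counted.  Every universe feature becomes a node even if isolated.
    """
    classes = universe if isinstance(universe, dict) else make_universe(universe)
    classes = make_universe(classes)  # re-validate
    edges: set[tuple[str, str]] = set()
    n_rows = 0
    dropped_outside = 0
    dropped_self = 0
    for table in tables:
        for reg, tgt in zip(table.rows["regulator"], table.rows["target"]):
            n_rows += 1
            if reg not in classes or tgt not in classes:
                dropped_outside += 1
                continue
            if reg == tgt:
                dropped_self += 1
                continue
            edges.add((reg, tgt))
    return RegulatoryNetwork(
        classes=dict(classes),
        edges=edges,
        dropped_outside_universe=dropped_outside,
        dropped_self_loops=dropped_self,
        duplicate_edges=n_rows - dropped_outside - dropped_self - len(edges),
    )


def network_summary(net: RegulatoryNetwork) -> dict:
    """Node counts per class, edge counts per interaction class, drops."""
    node_counts = Counter(net.classes.values())
    edge_counts: Counter[str] = Counter()
    for reg, tgt in net.edges:
        pair = (net.classes[reg], net.classes[tgt])
        edge_counts[INTERACTION_CLASSES.get(pair, f"{pair[0]}->{pair[1]}")] += 1
    return {
        "n_nodes": net.n_features,
        "nodes_per_class": {k: node_counts.get(k, 0) for k in KLASSES},
        "n_edges": len(net.edges),
        "edges_per_class": dict(edge_counts),
        "dropped_outside_universe": net.dropped_outside_universe,
        "dropped_self_loops": net.dropped_self_loops,
        "duplicate_edges": net.duplicate_edges,
    }
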