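"""PPI edge-list I/O and the gene graph substrate.

Confidence-scored protein–protein interaction networks arrive as two- or
three-column delimited text (STRING-, CPDB-, BioGRID-style exports).  This
module reads them, applies the high-confidence filter, and canonicalizes the
result into an undirected simple :class:`GeneGraph` whose node order is fixed
(lexicographic) so that seeded downstream runs are reproducible across
platforms.  It also aligns a graph with a feature matrix and a label set into
the single :class:`AlignedDataset` consumed by the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "WeightedEdgeList",
    "GeneGraph",
    "AlignedDataset",
    "read_edge_list",
    "filter_by_confidence",
    "build_graph",
    "align_dataset",
    "degree_histogram",
]


@dataclass(frozen=True)
class EdgeRecord:
    gene_a: str
    gene_b: str
    confidence: float | None = None


class WeightedEdgeList:
    """Ordered list of (gene_a, gene_b, confidence-or-None) records."""

    def __init__(self, records: Iterable[tuple] = ()):  # accepts tuples or EdgeRecords
        self.records: list[EdgeRecord] = []
        for r in records:
            if isinstance(r, EdgeRecord):
                rec = r
            else:
                a, b = r[0], r[1]
                c = r[2] if len(r) > 2 else None
                rec = EdgeRecord(str(a), str(b), None if c is None else float(c))
            if not rec.gene_a or not rec.gene_b:
                raise ValueError("gene symbols must be nonempty")
            if rec.confidence is not None and not np.isfinite(rec.confidence):
                raise ValueError(f"non-finite confidence for edge {rec.gene_a}-{rec.gene_b}")
            self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_edge_list(path, dialect: str = "three-column", delimiter: str = "\t") -> WeightedEdgeList:
    """Parse a delimited edge-list file into a :class:`WeightedEdgeList`.

    A header line is auto-detected: in three-column dialect, a first row whose
    score field is non-numeric is treated as a header; in two-column dialect a
    first row is kept (two gene symbols are indistinguishable from a header).
    STRING detailed-links combined scores on the 0–1000 scale are rescaled to
    [0, 1] when any score exceeds 1.
    """
    if dialect not in ("two-column", "three-column"):
        raise ValueError(f"unknown dialect {dialect!r}")
    want_score = dialect == "three-column"
    records: list[EdgeRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected at least 2 fields, got {len(fields)}")
            if want_score:
                if len(fields) < 3:
                    raise ValueError(f"line {lineno}: three-column dialect needs a score field")
                if lineno == 1 and not _looks_numeric(fields[2]):
                    continue  # header
                if not _looks_numeric(fields[2]):
                    raise ValueError(f"line {lineno}: unparsable score {fields[2]!r}")
                records.append(EdgeRecord(fields[0], fields[1], float(fields[2])))
            else:
                records.append(EdgeRecord(fields[0], fields[1], None))
    scores = [r.confidence for r in records if r.confidence is not None]
    if scores and max(scores) > 1.0:
        records = [EdgeRecord(r.gene_a, r.gene_b, r.confidence / 1000.0) for r in records]
    return WeightedEdgeList(records)


def filter_by_confidence(
    edges: WeightedEdgeList, threshold: float, comparator: str = "strict"
) -> WeightedEdgeList:
    """Keep records whose confidence passes ``threshold``.

    ``comparator='strict'`` keeps scores > threshold (the CPDB "higher than
    0.5" reading); ``'inclusive'`` keeps scores >= threshold (the STRING
    "threshold of 0.85" reading).  Input order is preserved.
    """
    if comparator not in ("strict", "inclusive"):
        raise ValueError(f"unknown comparator {comparator!r}")
    kept = []
    for r in edges:
        if r.confidence is None:
            raise ValueError(f"edge {r.gene_a}-{r.gene_b} carries no confidence score")
        if (r.confidence > threshold) if comparator == "strict" else (r.confidence >= threshold):
            kept.append(r)
    return WeightedEdgeList(kept)


class GeneGraph:
    """Undirected simple graph over gene symbols with optional edge confidences.

    Nodes are ordered lexicographically at construction; adjacency is stored in
    CSR form (``indptr``/``indices``) for fast seeded neighbor sampling.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str]],
        confidence: Mapping[tuple[str, str], float] | None = None,
    ):
        self.nodes: tuple[str, ...] = tuple(sorted(set(map(str, nodes))))
        self.node_index: dict[str, int] = {g: i for i, g in enumerate(self.nodes)}
        edge_set: set[tuple[str, str]] = set()
        for a, b in edges:
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if key[0] not in self.node_index or key[1] not in self.node_index:
                raise ValueError(f"edge endpoint not in node set: {key}")
            edge_set.add(key)
        self.edges: frozenset[tuple[str, str]] = frozenset(edge_set)
        self.confidence: dict[tuple[str, str], float] = {}
        if confidence:
            for (a, b), c in confidence.items():
                key = (a, b) if a <= b else (b, a)
                if key in self.edges:
                    self.confidence[key] = float(c)
        self._build_csr()

    def _build_csr(self) -> None:
        n = len(self.nodes)
        if self.edges:
            pairs = np.array(
                [(self.node_index[a], self.node_index[b]) for a, b in self.edges], dtype=np.int64
            )
            src = np.concatenate([pairs[:, 0], pairs[:, 1]])
            dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
            order = np.lexsort((dst, src))
            src, dst = src[order], dst[order]
        else:
            src = dst = np.zeros(0, dtype=np.int64)
        self.indptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(self.indptr, src + 1, 1)
        self.indptr = np.cumsum(self.indptr)
        self.indices = dst

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, gene: str) -> int:
        i = self.node_index[gene]
        return int(self.indptr[i + 1] - self.indptr[i])

    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    def neighbors(self, gene: str) -> tuple[str, ...]:
        i = self.node_index[gene]
        return tuple(self.nodes[j] for j in self.indices[self.indptr[i] : self.indptr[i + 1]])

    def has_edge(self, a: str, b: str) -> bool:
        return ((a, b) if a <= b else (b, a)) in self.edges

    def subgraph(self, keep: Iterable[str]) -> "GeneGraph":
        """Induced subgraph on ``keep`` (unknown symbols ignored)."""
        keep_set = {g for g in keep if g in self.node_index}
        edges = [(a, b) for a, b in self.edges if a in keep_set and b in keep_set]
        conf = {e: self.confidence[e] for e in self.confidence if e[0] in keep_set and e[1] in keep_set}
        return GeneGraph(keep_set, edges, conf)

    def edge_dump(self) -> WeightedEdgeList:
        """Sorted edge list round-trippable through :func:`build_graph`."""
        recs = []
        for a, b in sorted(self.edges):
            recs.append((a, b, self.confidence.get((a, b))))
        return WeightedEdgeList(recs)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b in self.edges:
            g.add_edge(a, b, **({"confidence": self.confidence[(a, b)]} if (a, b) in self.confidence else {}))
        return g

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeneGraph)
            and self.nodes == other.nodes
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return f"GeneGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def build_graph(edges: WeightedEdgeList) -> GeneGraph:
    """Canonicalize an edge list: drop self-loops, collapse duplicate and
    reversed pairs (confidence = max over duplicates), node set = union of
    endpoints."""
    nodes: set[str] = set()
    conf: dict[tuple[str, str], float] = {}
    pairs: set[tuple[str, str]] = set()
    for r in edges:
        nodes.add(r.gene_a)
        nodes.add(r.gene_b)
        if r.gene_a == r.gene_b:
            continue
        key = (r.gene_a, r.gene_b) if r.gene_a <= r.gene_b else (r.gene_b, r.gene_a)
        pairs.add(key)
        if r.confidence is not None:
            conf[key] = max(conf.get(key, -np.inf), r.confidence)
    return GeneGraph(nodes, pairs, conf)


def degree_histogram(graph: GeneGraph) -> dict[int, int]:
    degs = graph.degrees()
    vals, counts = np.unique(degs, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts)}


@dataclass
class AlignedDataset:
    """Graph, node features, and labels over one shared gene universe."""

    graph: GeneGraph
    features: "FeatureMatrix"  # noqa: F821 - forward ref to features module
    labels: "LabelSet"  # noqa: F821
    expression: object | None = None  # optional raw ExpressionMatrix for refit scenarios
    report: list[str] = field(default_factory=list)


def align_dataset(graph: GeneGraph, features, labels, expression=None) -> AlignedDataset:
    """Restrict graph, features, and labels to their common gene universe.

    The graph is induced on nodes that have feature rows; labels are restricted
    to surviving nodes and genes without a label become unlabeled.  Returns the
    dataset plus a plain-text report of what was dropped.
    """
    from .labeling import LabelSet

    feature_genes = set(features.genes)
    keep = [g for g in graph.nodes if g in feature_genes]
    if not keep:
        raise ValueError("no overlap between graph nodes and feature genes")
    report = []
    n_dropped = graph.n_nodes - len(keep)
    if n_dropped:
        report.append(f"dropped {n_dropped} genes lacking features")
    sub = graph.subgraph(keep)
    feats = features.restrict(keep)
    keep_set = set(keep)
    essential = labels.essential & keep_set
    nonessential = labels.nonessential & keep_set
    labeled = essential | nonessential | (labels.unlabeled & keep_set)
    unlabeled = (keep_set - essential - nonessential) | (labels.unlabeled & keep_set)
    n_newly_unlabeled = len(keep_set - (labels.essential | labels.nonessential | labels.unlabeled))
    if n_newly_unlabeled:
        report.append(f"marked {n_newly_unlabeled} in-network genes without labels as unlabeled")
    del labeled
    lab = LabelSet(essential=essential, nonessential=nonessential, unlabeled=unlabeled)
    return AlignedDataset(graph=sub, features=feats, labels=lab, expression=expression, report=report)
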