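"""Synthetic networks, labels, expression, and gene-effect screens.

Every generator emulates the statistical structure the classifier assumes in
real data — scale-free PPI topology (preferential attachment), essential
genes enriched among hubs, expression with a planted class signal smoothed
over the network, and bimodal knockout-screen gene effects — so the whole
pipeline is exercisable with no downloads.  Outputs use the same text
dialects the I/O readers consume, and every generator is a pure function of
its configuration and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import ExpressionMatrix, apply_feature_transform, fit_feature_transform
from .graph import AlignedDataset, GeneGraph, align_dataset
from .labeling import GeneEffectMatrix, LabelSet

__all__ = [
    "SyntheticConfig",
    "REFERENCE_CONFIG",
    "generate_graph",
    "plant_labels",
    "generate_expression",
    "generate_gene_effects",
    "generate_scaling_suite",
    "make_reference_dataset",
    "gene_names",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic reference experiment."""

    n_nodes: int = 2_000
    n_edges: int = 10_000
    essential_fraction: float = 0.10
    hub_bias: float = 1.0
    n_samples: int = 100
    feature_effect_size: float = 1.5   # class mean shift, in noise-sd units
    neighbor_correlation: float = 0.3  # weight of one neighbor-smoothing pass
    n_lines: int = 100
    effect_separation: float = 1.0     # gene-effect class separation
    n_components: int = 50
    seed: int = 0


REFERENCE_CONFIG = SyntheticConfig()


def gene_names(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def generate_graph(n_nodes: int, n_edges: int, seed: int = 0) -> GeneGraph:
    """Scale-free graph with exactly ``n_nodes`` nodes and ``n_edges`` edges.

    Preferential-attachment growth with attachment count
    m = floor(n_edges / n_nodes) per new node, then the remaining edges are
    added one by one with degree-proportional endpoint sampling (rejecting
    self-loops and duplicates), so realized sizes match the request exactly.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_nodes < 2 or n_edges < n_nodes - 1 or n_edges > max_edges:
        raise ValueError(
            f"infeasible sizes: {n_nodes} nodes cannot host {n_edges} simple edges "
            "while staying connected"
        )
    rng = np.random.default_rng(seed)
    m = max(1, n_edges // n_nodes)
    names = gene_names(n_nodes)
    # seed component: path over the first m+1 nodes
    edges: set[tuple[int, int]] = {(i, i + 1) for i in range(m)}
    repeated: list[int] = []  # node id repeated once per incident edge
    for a, b in edges:
        repeated.extend((a, b))
    for v in range(m + 1, n_nodes):
        targets: set[int] = set()
        while len(targets) < m:
            t = repeated[rng.integers(len(repeated))]
            if t != v:
                targets.add(int(t))
        for t in targets:
            edges.add((t, v) if t < v else (v, t))
            repeated.extend((v, t))
    attempts = 0
    while len(edges) < n_edges:
        a = repeated[rng.integers(len(repeated))]
        b = repeated[rng.integers(len(repeated))]
        key = (a, b) if a < b else (b, a)
        if a == b or key in edges:
            attempts += 1
            if attempts > 100 * n_edges:
                raise RuntimeError("edge top-up stalled; graph too dense for PA sampling")
            continue
        edges.add(key)
        repeated.extend((a, b))
    return GeneGraph(names, [(names[a], names[b]) for a, b in edges])


def plant_labels(
    graph: GeneGraph, essential_fraction: float, hub_bias: float = 0.0, seed: int = 0,
    unlabeled_fraction: float = 0.0,
) -> LabelSet:
    """Plant an essential set of exactly round(fraction·n) genes, drawn with
    probability proportional to degree**hub_bias (uniform at hub_bias 0)."""
    if not 0.0 < essential_fraction < 1.0:
        raise ValueError("essential_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    nodes = np.array(graph.nodes)
    degs = graph.degrees().astype(float)
    w = np.ones_like(degs) if hub_bias == 0 else np.power(np.maximum(degs, 1e-12), hub_bias)
    p = w / w.sum()
    n_ess = int(round(essential_fraction * len(nodes)))
    essential = set(rng.choice(nodes, size=n_ess, replace=False, p=p))
    rest = [g for g in nodes if g not in essential]
    n_unl = int(round(unlabeled_fraction * len(nodes)))
    unlabeled = set(rng.choice(rest, size=min(n_unl, len(rest)), replace=False)) if n_unl else set()
    nonessential = set(rest) - unlabeled
    return LabelSet(essential=essential, nonessential=nonessential, unlabeled=unlabeled)


def generate_expression(
    graph: GeneGraph,
    labels: LabelSet,
    n_samples: int = 100,
    feature_effect_size: float = 1.5,
    neighbor_correlation: float = 0.3,
    seed: int = 0,
) -> ExpressionMatrix:
    """FPKM-like expression with a planted class signal.

    Per gene and sample, a latent log2 signal = class mean shift (essential
    genes shifted by ``feature_effect_size`` noise-sd units) + N(0, 1) noise.
    One neighbor-averaging pass blends each gene's signal with the mean of its
    neighbors' (weight ``neighbor_correlation``), coupling features to
    topology; 2**signal then yields nonnegative expression values.
    """
    if not 0.0 <= neighbor_correlation < 1.0:
        raise ValueError("neighbor_correlation must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    nodes = list(graph.nodes)
    shift = np.array([feature_effect_size if g in labels.essential else 0.0 for g in nodes])
    latent = shift[:, None] + rng.standard_normal((len(nodes), n_samples))
    if neighbor_correlation > 0 and graph.n_edges:
        counts = graph.degrees()
        rows = np.repeat(np.arange(graph.n_nodes), counts)
        nbr_sum = np.zeros_like(latent)
        np.add.at(nbr_sum, rows, latent[graph.indices])
        nbr_mean = np.where(counts[:, None] > 0, nbr_sum / np.maximum(counts, 1)[:, None], latent)
        latent = (1 - neighbor_correlation) * latent + neighbor_correlation * nbr_mean
    values = np.exp2(latent)
    samples = [f"S{j:04d}" for j in range(1, n_samples + 1)]
    return ExpressionMatrix(pd.DataFrame(values, index=nodes, columns=samples))


def generate_gene_effects(
    labels: LabelSet, n_lines: int = 100, effect_separation: float = 1.0, seed: int = 0,
) -> GeneEffectMatrix:
    """Bimodal knockout-screen matrix: essential genes' viability effects are
    drawn from N(−effect_separation, 0.2²), others from N(0, 0.2²),
    independently per cell line."""
    if effect_separation <= 0:
        raise ValueError("effect_separation must be positive")
    rng = np.random.default_rng(seed)
    genes = sorted(labels.universe)
    mu = np.array([-effect_separation if g in labels.essential else 0.0 for g in genes])
    vals = mu[:, None] + 0.2 * rng.standard_normal((len(genes), n_lines))
    lines = [f"ACH-{j:06d}" for j in range(1, n_lines + 1)]
    return GeneEffectMatrix(pd.DataFrame(vals, index=genes, columns=lines))


def generate_scaling_suite(
    node_counts=(10_000, 15_000, 20_000, 25_000, 30_000),
    edge_counts=tuple(range(200_000, 1_800_001, 200_000)),
    seed: int = 0,
    out_dir=None,
) -> pd.DataFrame:
    """The node-count × edge-count grid of simulated networks (45 by default)
    used for scalability experiments.  Returns a manifest of requested vs
    realized sizes; graphs are written as two-column edge-list TSVs when
    ``out_dir`` is given, in the same dialect the readers consume."""
    root = np.random.SeedSequence(seed)
    rows = []
    for n in node_counts:
        for e in edge_counts:
            child = root.spawn(1)[0]
            if e < n - 1 or e > n * (n - 1) // 2:
                warnings.warn(f"skipping infeasible grid point ({n} nodes, {e} edges)")
                continue
            g = generate_graph(n, e, seed=int(np.random.default_rng(child).integers(2**31)))
            path = None
            if out_dir is not None:
                path = Path(out_dir) / f"net_n{n}_e{e}.tsv"
                with open(path, "w") as fh:
                    for a, b in sorted(g.edges):
                        fh.write(f"{a}\t{b}\n")
            rows.append(
                {
                    "requested_nodes": n,
                    "requested_edges": e,
                    "realized_nodes": g.n_nodes,
                    "realized_edges": g.n_edges,
                    "path": str(path) if path else "",
                }
            )
    return pd.DataFrame(rows)


def make_reference_dataset(seed: int = 0, config: SyntheticConfig | None = None) -> AlignedDataset:
    """The standard synthetic experiment: scale-free graph, hub-biased
    essential set, planted expression signal, PCA node features, all aligned
    into one dataset (with the raw expression attached for refit scenarios)."""
    cfg = config or REFERENCE_CONFIG
    root = np.random.SeedSequence(seed)
    s_graph, s_labels, s_expr = (int(np.random.default_rng(s).integers(2**31)) for s in root.spawn(3))
    graph = generate_graph(cfg.n_nodes, cfg.n_edges, seed=s_graph)
    labels = plant_labels(graph, cfg.essential_fraction, cfg.hub_bias, seed=s_labels)
    expr = generate_expression(
        graph, labels, cfg.n_samples, cfg.feature_effect_size, cfg.neighbor_correlation,
        seed=s_expr,
    )
    transform = fit_feature_transform(expr, n_components=cfg.n_components)
    feats = apply_feature_transform(transform, expr)
    return align_dataset(graph, feats, labels, expression=expr)
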