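"""Controlled corruption of network structure and node features.

These perturbations probe how much of the classifier's performance rests on
network topology versus expression-derived features: a chosen fraction of
edges is replaced by uniformly random ones (destroying local topology while
conserving node and edge counts), and a chosen fraction of nodes has feature
vectors swapped pairwise (destroying the gene↔feature association while
conserving the feature-row multiset).  A scan harness reruns cross-validation
across perturbation levels and modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .graph import AlignedDataset, GeneGraph

__all__ = [
    "PerturbationSpec",
    "perturb_edges",
    "perturb_features",
    "perturb_both",
    "perturbation_scan",
]


@dataclass
class PerturbationSpec:
    edge_fraction: float = 0.0
    feature_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for f in (self.edge_fraction, self.feature_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("perturbation fractions must lie in [0, 1]")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def perturb_edges(
    graph: GeneGraph, fraction: float, rng: np.random.Generator,
    mode: str = "replace", max_attempts: int = 10_000,
) -> GeneGraph:
    """Replace round(fraction·|edges|) uniformly chosen edges with random ones.

    ``mode='replace'`` redraws both endpoints uniformly from the node set;
    ``mode='rewire-one'`` keeps one (randomly chosen) endpoint and redraws the
    other.  Self-loops, duplicates, and re-creations of original edges are
    rejected, so node and edge counts are preserved exactly and precisely
    round(fraction·|edges|) edges differ from the original edge set.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if mode not in ("replace", "rewire-one"):
        raise ValueError(f"unknown mode {mode!r}")
    n_swap = _round_half_away(fraction * graph.n_edges)
    if n_swap == 0:
        return GeneGraph(graph.nodes, graph.edges, graph.confidence)
    edges = sorted(graph.edges)
    chosen = rng.choice(len(edges), size=n_swap, replace=False)
    chosen_set = set(int(i) for i in chosen)
    current = set(edges)
    nodes = graph.nodes
    for i in sorted(chosen_set):
        old = edges[i]
        current.discard(old)
        placed = False
        for _ in range(max_attempts):
            if mode == "replace":
                a, b = nodes[rng.integers(len(nodes))], nodes[rng.integers(len(nodes))]
            else:
                keep = old[rng.integers(2)]
                a, b = keep, nodes[rng.integers(len(nodes))]
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if key in current or key in graph.edges:
                continue
            current.add(key)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "could not place a replacement edge without duplicates "
                f"after {max_attempts} attempts (graph too dense)"
            )
    return GeneGraph(nodes, current)


def perturb_features(
    features: FeatureMatrix, fraction: float, rng: np.random.Generator
) -> FeatureMatrix:
    """Swap feature vectors within random pairs covering round(fraction·n)
    nodes (rounded down to an even count).  The row multiset is conserved."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    genes = list(features.genes)
    n_pick = _round_half_away(fraction * len(genes))
    n_pick -= n_pick % 2
    mat = features.frame.to_numpy().copy()
    if n_pick >= 2:
        picked = rng.choice(len(genes), size=n_pick, replace=False)
        picked = rng.permutation(picked)
        for a, b in picked.reshape(-1, 2):
            mat[[a, b]] = mat[[b, a]]
    return FeatureMatrix(pd.DataFrame(mat, index=genes, columns=features.frame.columns))


def perturb_both(dataset: AlignedDataset, spec: PerturbationSpec) -> AlignedDataset:
    """Apply edge and feature perturbation with independent seed substreams."""
    ss_edges, ss_feats = np.random.SeedSequence(spec.seed).spawn(2)
    graph = perturb_edges(dataset.graph, spec.edge_fraction, np.random.default_rng(ss_edges))
    feats = perturb_features(dataset.features, spec.feature_fraction, np.random.default_rng(ss_feats))
    return AlignedDataset(
        graph=graph, features=feats, labels=dataset.labels, expression=dataset.expression
    )


def perturbation_scan(
    dataset: AlignedDataset,
    config=None,
    fractions=(0.0, 0.25, 0.5, 0.75, 1.0),
    modes=("edges", "features", "both"),
    repeats: int = 10,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format AUPRC/AUROC table over mode × fraction × repeat × fold.

    A fresh perturbation is drawn per repeat (before cross-validation), then a
    single round of k-fold CV is run on the perturbed dataset.
    """
    from .evaluation import run_cross_validation

    rows = []
    root = np.random.SeedSequence(seed)
    for mode in modes:
        if mode not in ("edges", "features", "both"):
            raise ValueError(f"unknown mode {mode!r}")
        for fraction in fractions:
            for rep in range(repeats):
                ss_perturb, ss_cv = root.spawn(1)[0].spawn(2)
                spec = PerturbationSpec(
                    edge_fraction=fraction if mode in ("edges", "both") else 0.0,
                    feature_fraction=fraction if mode in ("features", "both") else 0.0,
                    seed=int(np.random.default_rng(ss_perturb).integers(2**31)),
                )
                perturbed = perturb_both(dataset, spec)
                res = run_cross_validation(
                    perturbed, config, k=k, repeats=1,
                    seed=int(np.random.default_rng(ss_cv).integers(2**31)),
                )
                for f in res.folds:
                    rows.append(
                        {
                            "mode": mode,
                            "fraction": fraction,
                            "repeat": rep,
                            "fold": f.fold,
                            "auprc": f.auprc,
                            "auroc": f.auroc,
                            "seed": spec.seed,
                        }
                    )
    return pd.DataFrame(rows)
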