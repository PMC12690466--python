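"""Layered neighbor sampling: the per-target computation graph.

For a batch of target nodes the sampler draws, hop by hop, a fixed-size
uniform sample (without replacement) of each frontier node's neighbors.  Hop 1
(a target's direct neighbors) uses ``sizes[0]``, hop 2 uses ``sizes[1]``, and
so on.  Nodes with degree below the hop size keep all their neighbors;
isolated nodes get an empty set.  The resulting :class:`ComputationGraph`
records exactly which nodes can influence each target's prediction — nothing
outside it is ever touched by a forward pass, which is what makes the model
inductive and memory-bounded regardless of total network size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .graph import GeneGraph

__all__ = ["ComputationGraph", "sample_neighborhood"]


@dataclass
class _HopSample:
    """Samples drawn for one hop: CSR layout over the hop's frontier."""

    frontier: np.ndarray       # node ids (sorted unique)
    indptr: np.ndarray         # len(frontier) + 1
    indices: np.ndarray        # sampled neighbor node ids
    support: np.ndarray        # union of frontier and sampled ids (sorted)
    self_pos: np.ndarray       # position of frontier[i] within support
    sample_pos: np.ndarray     # positions of indices within support

    def mean_operator(self) -> sparse.csr_matrix:
        """Sparse matrix M with M @ H = per-frontier-node mean of sampled
        neighbors' rows of H (zero row where the sample is empty)."""
        counts = np.diff(self.indptr)
        rows = np.repeat(np.arange(len(self.frontier)), counts)
        data = np.repeat(np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0), counts)
        return sparse.csr_matrix(
            (data, (rows, self.sample_pos)), shape=(len(self.frontier), len(self.support))
        )


@dataclass
class ComputationGraph:
    """K hops of sampled neighbor sets for a batch of targets."""

    targets: np.ndarray                  # node ids, in request order
    sizes: tuple[int, ...]
    hops: list[_HopSample] = field(default_factory=list)
    node_names: tuple[str, ...] = ()

    @property
    def depth(self) -> int:
        return len(self.hops)

    @property
    def involved_ids(self) -> np.ndarray:
        """Every node id that participates in any target's computation."""
        return self.hops[-1].support if self.hops else np.unique(self.targets)

    @property
    def involved_nodes(self) -> set[str]:
        return {self.node_names[i] for i in self.involved_ids}

    def sampled_neighbors(self, gene: str, hop: int) -> tuple[str, ...]:
        """The neighbor sample drawn for ``gene`` at ``hop`` (1-based)."""
        h = self.hops[hop - 1]
        idx = self.node_names.index(gene) if isinstance(gene, str) else gene
        pos = np.searchsorted(h.frontier, idx)
        if pos >= len(h.frontier) or h.frontier[pos] != idx:
            raise KeyError(f"{gene!r} is not on the hop-{hop} frontier")
        sl = h.indices[h.indptr[pos] : h.indptr[pos + 1]]
        return tuple(self.node_names[j] for j in sl)


def _sample_hop(graph: GeneGraph, frontier: np.ndarray, size: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform without-replacement neighbor sample for every frontier node,
    vectorized over the whole frontier.  Returns (indptr, sampled ids)."""
    indptr, indices = graph.indptr, graph.indices
    counts = (indptr[frontier + 1] - indptr[frontier]).astype(np.int64)
    total = int(counts.sum())
    if total == 0:
        return np.zeros(len(frontier) + 1, dtype=np.int64), np.zeros(0, dtype=np.int64)
    starts = indptr[frontier]
    row_flat_start = np.concatenate(([0], np.cumsum(counts)[:-1]))
    within = np.arange(total) - np.repeat(row_flat_start, counts)
    nbrs = indices[np.repeat(starts, counts) + within]
    rows = np.repeat(np.arange(len(frontier)), counts)
    keys = rng.random(total)
    order = np.lexsort((keys, rows))
    keep = within < np.minimum(np.repeat(counts, counts), size)
    sampled = nbrs[order][keep]
    samp_counts = np.minimum(counts, size)
    out_indptr = np.concatenate(([0], np.cumsum(samp_counts)))
    return out_indptr, sampled


def sample_neighborhood(
    graph: GeneGraph,
    targets,
    sizes,
    rng: np.random.Generator,
) -> ComputationGraph:
    """Draw the K-hop computation graph for ``targets``.

    ``sizes[d]`` is the per-node sample size at hop d+1.  Each hop's frontier
    is the union of the previous frontier and its sampled neighbors, so a
    node's own representation is always carried forward alongside its
    neighborhood mean.
    """
    target_ids = np.array(
        [t if isinstance(t, (int, np.integer)) else graph.node_index[t] for t in targets],
        dtype=np.int64,
    )
    if len(target_ids) and (target_ids.min() < 0 or target_ids.max() >= graph.n_nodes):
        raise KeyError("target node absent from graph")
    cg = ComputationGraph(
        targets=target_ids, sizes=tuple(int(s) for s in sizes), node_names=graph.nodes
    )
    frontier = np.unique(target_ids)
    for size in cg.sizes:
        if size <= 0:
            raise ValueError("sample sizes must be positive")
        indptr_h, sampled = _sample_hop(graph, frontier, size, rng)
        support = np.union1d(frontier, sampled)
        cg.hops.append(
            _HopSample(
                frontier=frontier,
                indptr=indptr_h,
                indices=sampled,
                support=support,
                self_pos=np.searchsorted(support, frontier),
                sample_pos=np.searchsorted(support, sampled),
            )
        )
        frontier = support
    return cg
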