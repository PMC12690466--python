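"""Essential / nonessential / unlabeled label construction from knockout screens.

A gene is called *common essential* when it shows a significant growth defect
in most cell lines of a genome-wide viability screen.  Following the
percentile-rank approach used for DepMap-style gene-effect matrices: genes are
ranked by viability effect within each cell line (most negative effect = rank
1), each gene's per-line percentile ranks are summarized by a high quantile
(default 0.90, i.e. "depleted in >90% of lines"), and the resulting summary
distribution — bimodal when common-essential genes exist — is split at the
valley of a Gaussian kernel density estimate (a threshold that lands around
0.3 on real screens).  Calls from independent technologies (CRISPR, RNAi) are
intersected; conditionally essential genes are set aside as unlabeled rather
than being counted as negatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde, rankdata

__all__ = [
    "GeneEffectMatrix",
    "RankSummary",
    "LabelSet",
    "percentile_ranks",
    "rank_summary",
    "kde_valley_threshold",
    "call_common_essential",
    "intersect_screens",
    "assign_labels",
    "label_screen",
]


class GeneEffectMatrix:
    """Gene × cell-line viability effect scores (more negative = stronger
    growth defect).  Missing entries (gene unscreened in a line) are NaN and
    are excluded from that gene's rank vector rather than imputed."""

    def __init__(self, frame: pd.DataFrame):
        if frame.shape[0] < 2 or frame.shape[1] < 1:
            raise ValueError("need at least 2 genes and 1 cell line")
        self.frame = frame.astype(float)

    @classmethod
    def from_csv(cls, path, delimiter: str = ",") -> "GeneEffectMatrix":
        """Load a DepMap-style export; orientation auto-detected so genes end
        up in rows (DepMap ships cell lines in rows with ``ACH-``-style ids)."""
        df = pd.read_csv(path, sep=delimiter, index_col=0)
        index_ach = sum(str(i).startswith("ACH-") for i in df.index)
        col_ach = sum(str(c).startswith("ACH-") for c in df.columns)
        if index_ach > col_ach:
            df = df.T
        return cls(df)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def lines(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()


@dataclass
class RankSummary:
    genes: tuple[str, ...]
    summary: np.ndarray  # per-gene high quantile of percentile ranks, in [0, 1]
    coverage: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.summary, index=list(self.genes))


@dataclass
class LabelSet:
    """Three-way partition of a gene universe."""

    essential: set[str]
    nonessential: set[str]
    unlabeled: set[str]

    def __post_init__(self):
        self.essential = set(self.essential)
        self.nonessential = set(self.nonessential)
        self.unlabeled = set(self.unlabeled)
        if (
            self.essential & self.nonessential
            or self.essential & self.unlabeled
            or self.nonessential & self.unlabeled
        ):
            raise ValueError("label sets must be pairwise disjoint")

    @property
    def universe(self) -> set[str]:
        return self.essential | self.nonessential | self.unlabeled

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(g, "essential") for g in sorted(self.essential)]
            + [(g, "nonessential") for g in sorted(self.nonessential)]
            + [(g, "unlabeled") for g in sorted(self.unlabeled)]
        )
        return pd.DataFrame(rows, columns=["gene", "label"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LabelSet":
        df = pd.read_csv(path, sep="\t")
        by = {k: set(v["gene"]) for k, v in df.groupby("label")}
        return cls(
            essential=by.get("essential", set()),
            nonessential=by.get("nonessential", set()),
            unlabeled=by.get("unlabeled", set()),
        )


def percentile_ranks(effects: GeneEffectMatrix) -> pd.DataFrame:
    """Within-line ascending percentile ranks of gene effect.

    The most depleted gene of a line gets rank 1; ties receive the average
    rank; percentiles are rank / n_scored_genes, so values lie in (0, 1].
    NaN entries stay NaN and do not consume ranks.
    """
    vals = effects.values
    out = np.full(vals.shape, np.nan)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        mask = ~np.isnan(col)
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"cell line {effects.lines[j]!r} has no scored genes")
        out[mask, j] = rankdata(col[mask], method="average") / n
    return pd.DataFrame(out, index=list(effects.genes), columns=list(effects.lines))


def rank_summary(ranks: pd.DataFrame, coverage: float = 0.90) -> RankSummary:
    """Per-gene ``coverage``-quantile (linear interpolation) of its percentile
    ranks across cell lines.  A small summary means the gene ranks among the
    most depleted in at least ``coverage`` of its lines."""
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    vals = ranks.to_numpy()
    summ = np.empty(vals.shape[0])
    for i, row in enumerate(vals):
        row = row[~np.isnan(row)]
        if row.size == 0:
            raise ValueError(f"gene {ranks.index[i]!r} has no scored lines")
        summ[i] = np.quantile(row, coverage, method="linear")
    return RankSummary(genes=tuple(ranks.index), summary=summ, coverage=coverage)


def kde_valley_threshold(
    values, grid_points: int = 512, bandwidth_rule: str | float = "scott",
    min_prominence: float = 0.05,
) -> float:
    """Valley of a Gaussian KDE between the two dominant modes of a bimodal
    sample on [0, 1].

    The density is evaluated on a uniform grid over [0, 1]; local maxima with
    prominence at least ``min_prominence`` of the peak density count as modes
    (this rejects sampling-noise shoulders on unimodal data), the two with
    highest density are taken as the bimodal pair, and the grid location of
    minimum density strictly between them is returned.  If several grid points
    tie at the minimum, the midpoint of the tied run is used.  Raises
    ``ValueError("no valley found")`` on unimodal samples.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 50:
        raise ValueError("need at least 50 values for density estimation")
    kde = gaussian_kde(values, bw_method=bandwidth_rule)
    grid = np.linspace(0.0, 1.0, grid_points)
    density = kde(grid)
    peaks, _ = find_peaks(density, prominence=min_prominence * density.max())
    if peaks.size < 2:
        raise ValueError("no valley found")
    top_two = peaks[np.argsort(density[peaks])[-2:]]
    lo, hi = int(top_two.min()), int(top_two.max())
    between = density[lo + 1 : hi]
    if between.size == 0:
        raise ValueError("no valley found")
    min_val = between.min()
    tied = np.flatnonzero(between == min_val) + lo + 1
    return float(grid[tied].mean())


def call_common_essential(summary: RankSummary, threshold: float) -> set[str]:
    """Genes whose rank summary falls strictly below ``threshold``."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return {g for g, s in zip(summary.genes, summary.summary) if s < threshold}


def intersect_screens(set_a: set[str], set_b: set[str]) -> set[str]:
    """Common-essential calls supported by both screening technologies."""
    return set(set_a) & set(set_b)


def assign_labels(universe: set[str], common: set[str], conditional: set[str]) -> LabelSet:
    """Partition ``universe``: essential = common calls; conditionally
    essential genes (minus common ones) are unlabeled; everything else is
    nonessential.  Essential takes precedence over conditional."""
    universe, common, conditional = set(universe), set(common), set(conditional)
    if not common <= universe:
        raise ValueError(f"common essential genes outside universe: {sorted(common - universe)[:5]}")
    unlabeled = (conditional - common) & universe
    nonessential = universe - common - unlabeled
    return LabelSet(essential=common, nonessential=nonessential, unlabeled=unlabeled)


def label_screen(
    effects: GeneEffectMatrix, coverage: float = 0.90, grid_points: int = 512,
    bandwidth_rule: str | float = "scott",
) -> tuple[set[str], RankSummary, float]:
    """Full single-screen pipeline: percentile ranks → rank summary → KDE
    valley → common-essential call.  Returns (calls, summary, threshold)."""
    ranks = percentile_ranks(effects)
    summ = rank_summary(ranks, coverage=coverage)
    thr = kde_valley_threshold(summ.summary, grid_points=grid_points, bandwidth_rule=bandwidth_rule)
    return call_common_essential(summ, thr), summ, thr
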