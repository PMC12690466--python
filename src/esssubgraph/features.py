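"""Expression-derived node features.

Gene expression (FPKM-like, genes × tumor samples) is turned into fixed-length
node feature vectors by log transform, principal-component projection, and
per-component minimum–maximum scaling.  Genes are the observations and samples
the variables, so any gene with an expression row — including one never seen
when the transform was fitted — can be projected inductively.  Fitted genes
land in [0, 1] per component by construction; unseen genes may fall outside
and are deliberately not clamped (linearity preserved).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "ExpressionMatrix",
    "FeatureTransform",
    "FeatureMatrix",
    "normalize_expression",
    "fit_feature_transform",
    "apply_feature_transform",
]


class ExpressionMatrix:
    """Nonnegative gene × sample expression values."""

    def __init__(self, frame: pd.DataFrame):
        vals = frame.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression values must be finite")
        if (vals < 0).any():
            raise ValueError("expression values must be nonnegative")
        self.frame = frame.astype(float)

    @classmethod
    def from_csv(cls, path, delimiter: str = ",") -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep=delimiter, index_col=0))

    def to_csv(self, path, delimiter: str = ",") -> None:
        self.frame.to_csv(path, sep=delimiter)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)


def normalize_expression(expr: ExpressionMatrix, method: str = "log2") -> ExpressionMatrix:
    """Normalize before PCA.  ``log2`` (default) is elementwise log2(x + 1);
    ``none`` passes values through; ``zscore`` standardizes each gene row."""
    if method == "none":
        return ExpressionMatrix(expr.frame.copy())
    if method == "log2":
        return ExpressionMatrix(np.log2(expr.frame + 1.0))
    if method == "zscore":
        vals = expr.frame.to_numpy()
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (vals - mu) / sd
        # shift to nonnegative so the container invariant holds; an affine
        # per-gene shift does not change the PCA solution's discriminative use
        z = z - z.min()
        return ExpressionMatrix(pd.DataFrame(z, index=expr.frame.index, columns=expr.frame.columns))
    raise ValueError(f"unknown normalization {method!r}")


class FeatureMatrix:
    """Gene × d node feature vectors (rows keyed by gene symbol)."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.astype(float)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def dim(self) -> int:
        return self.frame.shape[1]

    def vector(self, gene: str) -> np.ndarray:
        return self.frame.loc[gene].to_numpy()

    def matrix_for(self, genes: Iterable[str]) -> np.ndarray:
        return self.frame.loc[list(genes)].to_numpy()

    def restrict(self, genes: Iterable[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.frame.loc[[g for g in genes if g in self.frame.index]])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class FeatureTransform:
    """Fitted normalization + PCA + min-max map, reusable on unseen genes."""

    normalization: str
    samples: tuple[str, ...]
    component_means: np.ndarray      # per-sample centering vector (length n_samples)
    component_loadings: np.ndarray   # n_samples × d
    explained_variance_ratio: np.ndarray
    minmax_bounds: np.ndarray        # d × 2 (min, max) over the fit genes' scores
    fitted_on: frozenset[str]

    @property
    def dim(self) -> int:
        return self.component_loadings.shape[1]

    def save(self, path) -> None:
        np.savez(
            path,
            normalization=np.array(self.normalization),
            samples=np.array(self.samples),
            component_means=self.component_means,
            component_loadings=self.component_loadings,
            explained_variance_ratio=self.explained_variance_ratio,
            minmax_bounds=self.minmax_bounds,
            fitted_on=np.array(sorted(self.fitted_on)),
        )

    @classmethod
    def load(cls, path) -> "FeatureTransform":
        z = np.load(path, allow_pickle=False)
        return cls(
            normalization=str(z["normalization"]),
            samples=tuple(z["samples"]),
            component_means=z["component_means"],
            component_loadings=z["component_loadings"],
            explained_variance_ratio=z["explained_variance_ratio"],
            minmax_bounds=z["minmax_bounds"],
            fitted_on=frozenset(z["fitted_on"]),
        )


def fit_feature_transform(
    expr: ExpressionMatrix,
    n_components: int = 50,
    fit_genes: Iterable[str] | None = None,
    normalization: str = "log2",
) -> FeatureTransform:
    """Fit PCA (genes as observations, samples as variables) on ``fit_genes``
    only, then record per-component min–max bounds from those genes' scores.

    The component sign convention is deterministic: each loading vector's
    largest-magnitude entry is made positive, so features are reproducible
    across platforms.
    """
    norm = normalize_expression(expr, method=normalization)
    genes = list(norm.genes) if fit_genes is None else [g for g in norm.genes if g in set(fit_genes)]
    if not genes:
        raise ValueError("no fit genes present in the expression matrix")
    X = norm.frame.loc[genes].to_numpy()
    max_rank = min(len(genes), X.shape[1])
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_fit_genes, n_samples)={max_rank}"
        )
    if np.allclose(X, X[0]):
        raise ValueError("zero-variance expression data")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()  # n_samples × d
    # deterministic sign: largest-|.| entry of each loading vector positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings *= flip
    scores *= flip
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    if np.any(hi <= lo):
        raise ValueError("degenerate (zero-range) principal component")
    return FeatureTransform(
        normalization=normalization,
        samples=tuple(norm.samples),
        component_means=pca.mean_,
        component_loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        minmax_bounds=np.column_stack([lo, hi]),
        fitted_on=frozenset(genes),
    )


def apply_feature_transform(
    t: FeatureTransform, expr: ExpressionMatrix, genes: Iterable[str] | None = None
) -> FeatureMatrix:
    """Project genes through a fitted transform: normalize, center on the fit
    mean, project onto the loadings, and apply the stored min-max affine map.
    Unseen genes may land outside [0, 1]; no clamping is applied."""
    norm = normalize_expression(expr, method=t.normalization)
    if tuple(norm.samples) != tuple(t.samples):
        raise ValueError("sample columns do not match the fitted transform")
    genes = list(norm.genes) if genes is None else list(genes)
    missing = [g for g in genes if g not in norm.frame.index]
    if missing:
        raise ValueError(f"expression rows missing for genes: {missing[:5]}")
    X = norm.frame.loc[genes].to_numpy()
    scores = (X - t.component_means) @ t.component_loadings
    lo = t.minmax_bounds[:, 0]
    hi = t.minmax_bounds[:, 1]
    scaled = (scores - lo) / (hi - lo)
    cols = [f"PC{i + 1}" for i in range(t.dim)]
    return FeatureMatrix(pd.DataFrame(scaled, index=genes, columns=cols))
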