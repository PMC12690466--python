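"""Class-imbalance-aware benchmarking.

Essential genes are heavily outnumbered, so evaluation follows the imbalanced
node-classification protocol: the candidate pool is fixed at a 4:1
nonessential:essential ratio (making the random-classifier AUPRC baseline
0.2), performance is summarized by AUPRC (primary) and AUROC (supporting)
over repeated stratified 5-fold cross-validation, and a decision cutoff is
chosen by maximizing Youden's J = TPR − FPR.  The four unseen-gene scenarios
control exactly which information about test genes — labels, graph edges,
expression distribution — is visible during training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import apply_feature_transform, fit_feature_transform
from .graph import AlignedDataset
from .model import EssSubgraph, ModelConfig
from .sampling import sample_neighborhood

__all__ = [
    "SplitSpec",
    "EvalResult",
    "subsample_negatives",
    "make_cv_splits",
    "auprc",
    "auroc",
    "youden_cutoff",
    "run_cross_validation",
    "run_unseen_scenarios",
    "SCENARIOS",
]

SCENARIOS = (
    "mask-labels-only",
    "drop-test-from-graph",
    "pca-train-only",
    "drop-test-completely",
)


@dataclass
class SplitSpec:
    """One repeat's folds: (train, val, test) node-id sets."""

    folds: list[tuple[list[str], list[str], list[str]]]
    repeat_index: int
    seed: int


@dataclass
class FoldResult:
    repeat: int
    fold: int
    auprc: float
    auroc: float
    scores: dict[str, float] = field(default_factory=dict)
    labels: dict[str, int] = field(default_factory=dict)


@dataclass
class EvalResult:
    folds: list[FoldResult]
    config: ModelConfig
    seed: int
    scenario: str = "mask-labels-only"

    @property
    def auprc_values(self) -> np.ndarray:
        return np.array([f.auprc for f in self.folds])

    @property
    def auroc_values(self) -> np.ndarray:
        return np.array([f.auroc for f in self.folds])

    @property
    def mean_auprc(self) -> float:
        return float(self.auprc_values.mean())

    @property
    def mean_auroc(self) -> float:
        return float(self.auroc_values.mean())

    def pooled_scores(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated per-gene test scores and labels across all folds."""
        s, y = [], []
        for f in self.folds:
            for g in f.scores:
                s.append(f.scores[g])
                y.append(f.labels[g])
        return np.array(s), np.array(y)

    def curve_coordinates(self):
        """PR and ROC coordinate tables (for plotting) from pooled scores."""
        import pandas as pd
        from sklearn.metrics import precision_recall_curve, roc_curve

        s, y = self.pooled_scores()
        prec, rec, _ = precision_recall_curve(y, s)
        fpr, tpr, _ = roc_curve(y, s)
        return (
            pd.DataFrame({"recall": rec, "precision": prec}),
            pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        )

    def summary(self) -> str:
        a, r = self.auprc_values, self.auroc_values
        return (
            f"{self.scenario}: AUPRC {a.mean():.3f} ± {a.std(ddof=1):.3f}, "
            f"AUROC {r.mean():.3f} ± {r.std(ddof=1):.3f} "
            f"({len(self.folds)} folds)"
        )

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "seed": self.seed,
            "mean_auprc": self.mean_auprc,
            "mean_auroc": self.mean_auroc,
            "sd_auprc": float(self.auprc_values.std(ddof=1)) if len(self.folds) > 1 else 0.0,
            "sd_auroc": float(self.auroc_values.std(ddof=1)) if len(self.folds) > 1 else 0.0,
            "folds": [
                {"repeat": f.repeat, "fold": f.fold, "auprc": f.auprc, "auroc": f.auroc}
                for f in self.folds
            ],
        }


def subsample_negatives(labels, ratio: float = 4.0, rng=None) -> list[str]:
    """All essential genes plus round(ratio · n_essential) uniformly sampled
    nonessential genes; takes all negatives (with a warning) if too few."""
    rng = rng or np.random.default_rng()
    pos = sorted(labels.essential)
    neg = sorted(labels.nonessential)
    if not pos:
        raise ValueError("no essential genes to anchor the pool")
    n_neg = int(round(ratio * len(pos)))
    if n_neg > len(neg):
        warnings.warn(
            f"only {len(neg)} nonessential genes available for a {n_neg}-gene sample; taking all"
        )
        sampled = neg
    else:
        sampled = list(rng.choice(neg, size=n_neg, replace=False))
    return pos + sorted(sampled)


def make_cv_splits(
    pool, pool_labels, k: int = 5, val_fraction: float = 0.1, rng=None, repeat_index: int = 0
) -> SplitSpec:
    """Stratified k-fold test partition of ``pool``; within each fold,
    ``val_fraction`` of the remainder (stratified) is held out for validation."""
    rng = rng or np.random.default_rng()
    pool = np.asarray(pool)
    y = np.asarray(pool_labels)
    if len(pool) < k:
        raise ValueError("pool smaller than number of folds")
    for cls in np.unique(y):
        if np.sum(y == cls) < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    seed = int(rng.integers(2**31))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for rest_idx, test_idx in skf.split(pool, y):
        rest, y_rest = pool[rest_idx], y[rest_idx]
        val = []
        for cls in np.unique(y_rest):
            members = rest[y_rest == cls]
            n_val = max(1, int(round(val_fraction * len(members))))
            val.extend(rng.choice(members, size=min(n_val, len(members) - 1), replace=False))
        val_set = set(val)
        train = [g for g in rest if g not in val_set]
        folds.append((train, sorted(val_set), list(pool[test_idx])))
    return SplitSpec(folds=folds, repeat_index=repeat_index, seed=seed)


def _check_two_class(labels) -> np.ndarray:
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def auprc(scores, labels) -> float:
    """Area under the precision–recall curve, step-interpolation convention
    (sum over thresholds of precision × recall increment)."""
    y = _check_two_class(labels)
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def auroc(scores, labels) -> float:
    """Area under the ROC curve; equals the midrank-normalized Mann–Whitney U."""
    y = _check_two_class(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def youden_cutoff(scores, labels) -> tuple[float, float]:
    """Threshold maximizing Youden's J = TPR − FPR.

    Candidates are the distinct score values (rule: score >= threshold is
    called positive); the smallest threshold is returned among ties."""
    y = _check_two_class(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = len(y) - n_pos
    best_thr, best_j = np.inf, -np.inf
    for thr in np.unique(s):
        pred = s >= thr
        tpr = np.sum(pred & (y == 1)) / n_pos
        fpr = np.sum(pred & (y == 0)) / n_neg
        j = tpr - fpr
        if j > best_j or (j == best_j and thr < best_thr):
            best_thr, best_j = thr, j
    return float(best_thr), float(best_j)


def _fold_eval(dataset, config, train, val, test, test_labels01, fold_seed, repeat, fold,
               train_graph=None, instrument=None) -> FoldResult:
    """Train on one fold and score its test set."""
    if train_graph is not None:
        ds = AlignedDataset(
            graph=train_graph, features=dataset.features, labels=dataset.labels,
            expression=dataset.expression,
        )
    else:
        ds = dataset
    res = EssSubgraph(ds, replace(config, seed=fold_seed)).fit(train, val)
    if instrument is not None:
        instrument(ds, res)
    p = res.predict_scores(test, graph=dataset.graph, features=dataset.features, seed=fold_seed)
    return FoldResult(
        repeat=repeat,
        fold=fold,
        auprc=auprc(p, test_labels01),
        auroc=auroc(p, test_labels01),
        scores=dict(zip(test, map(float, p))),
        labels=dict(zip(test, map(int, test_labels01))),
    )


def run_cross_validation(
    dataset: AlignedDataset,
    config: ModelConfig | None = None,
    k: int = 5,
    repeats: int = 10,
    ratio: float = 4.0,
    seed: int = 0,
) -> EvalResult:
    """Repeated stratified k-fold CV at a fixed negative:positive pool ratio.

    Per repeat: draw the 4:1 pool, split into folds, train with test labels
    masked, and score each held-out fold.  Test labels enter nothing but the
    final metric computation.
    """
    config = config or ModelConfig()
    root = np.random.SeedSequence(seed)
    results = []
    for rep, ss in enumerate(root.spawn(repeats)):
        rng = np.random.default_rng(ss)
        pool = subsample_negatives(dataset.labels, ratio=ratio, rng=rng)
        y = np.array([1 if g in dataset.labels.essential else 0 for g in pool])
        spec = make_cv_splits(pool, y, k=k, rng=rng, repeat_index=rep)
        label_of = dict(zip(pool, y))
        for fold_i, (train, val, test) in enumerate(spec.folds):
            fold_seed = int(rng.integers(2**31))
            results.append(
                _fold_eval(
                    dataset, config, train, val, test,
                    np.array([label_of[g] for g in test]),
                    fold_seed, rep, fold_i,
                )
            )
    return EvalResult(folds=results, config=config, seed=seed)


def run_unseen_scenarios(
    dataset: AlignedDataset,
    config: ModelConfig | None = None,
    scenario: str = "mask-labels-only",
    k: int = 5,
    repeats: int = 1,
    ratio: float = 4.0,
    n_components: int | None = None,
    seed: int = 0,
    instrument=None,
) -> EvalResult:
    """Cross-validation under one of four feature-exposure regimes.

    - ``mask-labels-only``: standard CV — full graph, transform fitted on all
      genes, only test labels hidden.
    - ``drop-test-from-graph``: test nodes deleted from the training graph;
      feature transform still fitted on all genes.
    - ``pca-train-only``: full graph, but the feature transform is fitted on
      non-test genes only and test genes are projected through it.
    - ``drop-test-completely``: both restrictions; test nodes re-enter the
      graph and the projection only at scoring time.

    Scenarios that refit the transform require ``dataset.expression``.
    ``instrument`` (optional) is called per fold with the training dataset and
    fitted results, e.g. to audit which nodes entered training.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    config = config or ModelConfig()
    refit_pca = scenario in ("pca-train-only", "drop-test-completely")
    drop_graph = scenario in ("drop-test-from-graph", "drop-test-completely")
    if refit_pca and dataset.expression is None:
        raise ValueError(f"scenario {scenario!r} needs the raw expression matrix on the dataset")
    if n_components is None:
        n_components = dataset.features.dim
    root = np.random.SeedSequence(seed)
    results = []
    for rep, ss in enumerate(root.spawn(repeats)):
        rng = np.random.default_rng(ss)
        pool = subsample_negatives(dataset.labels, ratio=ratio, rng=rng)
        y = np.array([1 if g in dataset.labels.essential else 0 for g in pool])
        spec = make_cv_splits(pool, y, k=k, rng=rng, repeat_index=rep)
        label_of = dict(zip(pool, y))
        for fold_i, (train, val, test) in enumerate(spec.folds):
            fold_seed = int(rng.integers(2**31))
            test_set = set(test)
            ds = dataset
            train_graph = None
            if refit_pca:
                fit_genes = [g for g in dataset.graph.nodes if g not in test_set]
                t = fit_feature_transform(
                    dataset.expression, n_components=n_components, fit_genes=fit_genes,
                )
                feats = apply_feature_transform(t, dataset.expression, list(dataset.graph.nodes))
                feats.transform = t  # expose the fold's fitted transform for auditing
                ds = AlignedDataset(
                    graph=dataset.graph, features=feats, labels=dataset.labels,
                    expression=dataset.expression,
                )
            if drop_graph:
                train_graph = ds.graph.subgraph(
                    [g for g in ds.graph.nodes if g not in test_set]
                )
            results.append(
                _fold_eval(
                    ds, config, train, val, test,
                    np.array([label_of[g] for g in test]),
                    fold_seed, rep, fold_i,
                    train_graph=train_graph, instrument=instrument,
                )
            )
    return EvalResult(folds=results, config=config, seed=seed, scenario=scenario)
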