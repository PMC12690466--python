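"""Negative subsampling, CV splits, metrics, and the unseen-gene scenarios."""

import numpy as np
import pytest

from esssubgraph import (
    LabelSet,
    auprc,
    auroc,
    make_cv_splits,
    run_unseen_scenarios,
    subsample_negatives,
    youden_cutoff,
)
from esssubgraph.evaluation import SCENARIOS


def brute_force_auprc(scores, labels):
    """All-thresholds PR step area computed from first principles."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, len(y) + 1)
    recall = tp / y.sum()
    # merge tied scores: keep only the last point of each tie block
    s_sorted = scores[order]
    keep = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    precision, recall = precision[keep], recall[keep]
    prev_r = 0.0
    area = 0.0
    for p, r in zip(precision, recall):
        area += p * (r - prev_r)
        prev_r = r
    return area


def brute_force_auroc(scores, labels):
    """Pairwise-comparison Mann–Whitney with half-credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    best = (np.inf, -np.inf)
    for thr in sorted(set(scores)):
        pred = scores >= thr
        tpr = np.sum(pred & (labels == 1)) / np.sum(labels == 1)
        fpr = np.sum(pred & (labels == 0)) / np.sum(labels == 0)
        j = tpr - fpr
        if j > best[1] or (j == best[1] and thr < best[0]):
            best = (thr, j)
    return best


def labels_for(pool, essential):
    return np.array([1 if g in essential else 0 for g in pool])


class TestSubsampleNegatives:
    def _labels(self, n_pos, n_neg):
        return LabelSet(
            {f"e{i}" for i in range(n_pos)}, {f"n{i}" for i in range(n_neg)}, set()
        )

    def test_four_to_one_pool(self):
        pool = subsample_negatives(self._labels(100, 10_000), rng=np.random.default_rng(0))
        assert len(pool) == 500
        assert sum(g.startswith("e") for g in pool) == 100

    def test_takes_all_when_insufficient_and_warns(self):
        with pytest.warns(UserWarning, match="taking all"):
            pool = subsample_negatives(self._labels(100, 300), rng=np.random.default_rng(0))
        assert len(pool) == 400

    def test_deterministic_under_seed(self):
        lab = self._labels(50, 1_000)
        p1 = subsample_negatives(lab, rng=np.random.default_rng(7))
        p2 = subsample_negatives(lab, rng=np.random.default_rng(7))
        assert p1 == p2

    def test_no_positives_errors(self):
        with pytest.raises(ValueError):
            subsample_negatives(self._labels(0, 10))


class TestMakeCvSplits:
    def test_test_sets_partition_pool(self):
        pool = [f"g{i}" for i in range(500)]
        y = np.array([1] * 100 + [0] * 400)
        spec = make_cv_splits(pool, y, k=5, rng=np.random.default_rng(1))
        tests = [set(t) for _, _, t in spec.folds]
        assert all(len(t) == 100 for t in tests)
        union = set().union(*tests)
        assert union == set(pool)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not tests[i] & tests[j]

    def test_stratification_within_one_member(self):
        pool = [f"g{i}" for i in range(500)]
        y = np.array([1] * 100 + [0] * 400)
        spec = make_cv_splits(pool, y, k=5, rng=np.random.default_rng(2))
        for _, _, test in spec.folds:
            n_pos = sum(1 for g in test if int(g[1:]) < 100)
            assert abs(n_pos - 20) <= 1

    def test_fold_parts_disjoint(self):
        pool = [f"g{i}" for i in range(100)]
        y = np.array([1] * 20 + [0] * 80)
        spec = make_cv_splits(pool, y, k=5, rng=np.random.default_rng(3))
        for train, val, test in spec.folds:
            assert not set(train) & set(val)
            assert not set(train) & set(test)
            assert not set(val) & set(test)

    def test_small_class_rejected(self):
        pool = list("abcdefgh")
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="fewer than k"):
            make_cv_splits(pool, y, k=5, rng=np.random.default_rng(0))


class TestMetrics:
    def test_perfect_ranking(self):
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_two_point_hand_case(self):
        assert auprc([0.9, 0.1], [1, 0]) == 1.0

    def test_reversed_ranking_auroc_zero(self):
        assert auroc([0.1, 0.9], [1, 0]) == 0.0

    def test_single_class_rejected(self):
        for fn in (auprc, auroc, youden_cutoff):
            with pytest.raises(ValueError):
                fn([0.5, 0.6], [1, 1])

    def test_agree_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(4, 50)
            scores = rng.choice([0.1, 0.25, 0.5, 0.75, 0.9], size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert auprc(scores, labels) == pytest.approx(brute_force_auprc(scores, labels))
            assert auroc(scores, labels) == pytest.approx(brute_force_auroc(scores, labels))
            thr, j = youden_cutoff(scores, labels)
            bthr, bj = brute_force_youden(scores, labels)
            assert (thr, j) == (pytest.approx(bthr), pytest.approx(bj))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        warped = np.exp(3 * scores)
        assert auprc(scores, labels) == pytest.approx(auprc(warped, labels))
        assert auroc(scores, labels) == pytest.approx(auroc(warped, labels))

    def test_null_auprc_approaches_prevalence(self):
        rng = np.random.default_rng(4)
        vals = []
        for _ in range(30):
            y = (rng.random(2_000) < 0.2).astype(int)
            vals.append(auprc(rng.random(2_000), y))
        assert np.mean(vals) == pytest.approx(0.2, abs=0.05)

    def test_null_auroc_half(self):
        rng = np.random.default_rng(5)
        vals = [auroc(rng.random(2_000), rng.integers(0, 2, 2_000)) for _ in range(20)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)

    def test_youden_hand_case(self):
        thr, j = youden_cutoff([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
        assert (thr, j) == (0.8, 1.0)


class TestUnseenScenarios:
    def test_unknown_scenario_rejected(self, tiny_dataset, tiny_config):
        with pytest.raises(ValueError, match="unknown scenario"):
            run_unseen_scenarios(tiny_dataset, tiny_config, scenario="bogus")

    def test_pca_train_only_excludes_test_from_fit(self, tiny_dataset, tiny_config):
        fitted_sets = []

        def instrument(ds, res):
            fitted_sets.append(set(ds.features.transform.fitted_on))

        res = run_unseen_scenarios(
            tiny_dataset, tiny_config, scenario="pca-train-only", k=5, repeats=1,
            seed=3, instrument=instrument,
        )
        assert len(res.folds) == 5
        for fold, fitted in zip(res.folds, fitted_sets):
            assert not set(fold.scores) & fitted

    def test_drop_test_completely_isolates_test_nodes(self, tiny_dataset, tiny_config):
        """No test node may enter any training computation graph."""
        from esssubgraph import sample_neighborhood

        audits = []

        def instrument(ds, res):
            audits.append(set(ds.graph.nodes))

        res = run_unseen_scenarios(
            tiny_dataset, tiny_config, scenario="drop-test-completely", k=5, repeats=1,
            seed=4, instrument=instrument,
        )
        assert len(audits) == 5
        for fold, train_nodes in zip(res.folds, audits):
            test_genes = set(fold.scores)
            assert not test_genes & train_nodes
        # and scoring still used the full graph (inductive re-insertion)
        assert all(0 <= f.auprc <= 1 for f in res.folds)

    def test_scenario_names_cover_the_four_regimes(self):
        assert set(SCENARIOS) == {
            "mask-labels-only",
            "drop-test-from-graph",
            "pca-train-only",
            "drop-test-completely",
        }
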