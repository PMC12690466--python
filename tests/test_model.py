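"""Aggregation, forward pass, loss, gradients, and training behavior."""

import numpy as np
import pandas as pd
import pytest

from conftest import dense_reference_forward, random_gene_graph
from esssubgraph import (
    EssSubgraph,
    FeatureMatrix,
    GeneGraph,
    ModelConfig,
    ModelParams,
    aggregate_step,
    forward,
    sample_neighborhood,
    weighted_bce_loss,
)
from esssubgraph.graph import AlignedDataset
from esssubgraph.labeling import LabelSet
from esssubgraph.model import _backward_cg, _dloss_dlogits, _forward_cg, _loss_from_logits


def features_for(graph, X):
    return FeatureMatrix(pd.DataFrame(X, index=list(graph.nodes)))


def small_params(rng, input_dim, hidden, depth):
    cfg = ModelConfig(
        depth=depth, sample_sizes=(99,) * depth, hidden_dims=(hidden,) * depth,
        input_dim=input_dim,
    )
    return ModelParams.initialize(cfg, rng), cfg


class TestAggregateStep:
    def test_hand_computed_identity_weights(self):
        W = np.hstack([np.eye(2), np.eye(2)])  # concat -> sum
        out = aggregate_step(np.array([1.0, 0.0]), [np.array([0.0, 1.0])], W)
        assert np.allclose(out, [1.0, 1.0])

    def test_mean_of_constant_neighbors(self):
        W = np.hstack([np.zeros((2, 2)), np.eye(2)])
        c = np.array([0.3, -0.7])
        for n in (1, 3, 7):
            out = aggregate_step(np.zeros(2), [c] * n, W)
            assert np.allclose(out, np.maximum(c, 0))

    def test_zero_weight_annihilates(self):
        out = aggregate_step(np.ones(3), [np.ones(3)], np.zeros((3, 6)))
        assert np.allclose(out, 0)

    def test_empty_neighborhood_uses_zero_vector(self):
        W = np.hstack([np.eye(2), np.eye(2)])
        assert np.allclose(aggregate_step(np.array([2.0, 3.0]), [], W), [2.0, 3.0])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            aggregate_step(np.ones(2), [np.ones(3)], np.ones((2, 4)))


class TestForward:
    def test_isolated_nodes_with_zero_weights_yield_bias(self):
        g = GeneGraph(["a", "b"], [])
        params, cfg = small_params(np.random.default_rng(0), 2, 3, 2)
        for W in params.layer_weights:
            W[:] = 0.0
        params.output_bias = -1.25
        X = np.random.default_rng(1).random((2, 2))
        logits = forward(params, g, features_for(g, X), ["a", "b"], cfg, np.random.default_rng(2))
        assert np.allclose(logits, -1.25)

    def test_two_passes_bit_identical_with_fixed_seed(self, tiny_dataset):
        cfg = ModelConfig(hidden_dims=(8, 8, 8), input_dim=tiny_dataset.features.dim)
        params = ModelParams.initialize(cfg, np.random.default_rng(3))
        targets = list(tiny_dataset.graph.nodes[:30])
        a = forward(params, tiny_dataset.graph, tiny_dataset.features, targets, cfg,
                    np.random.default_rng(9))
        b = forward(params, tiny_dataset.graph, tiny_dataset.features, targets, cfg,
                    np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_matches_dense_oracle_when_sampling_everything(self):
        """Sampling sizes >= max degree reduce to the dense computation."""
        rng = np.random.default_rng(11)
        for trial in range(10):
            g = random_gene_graph(12, 0.35, seed=trial)
            params, cfg = small_params(rng, 2, 3, 3)
            X = rng.random((g.n_nodes, 2))
            got = forward(params, g, features_for(g, X), list(g.nodes), cfg,
                          np.random.default_rng(trial))
            expected = dense_reference_forward(params, g, X, list(g.nodes))
            assert np.allclose(got, expected, atol=1e-10)

    def test_hand_computed_path_logits(self, path_graph):
        """Step-by-step manual forward on the a-b-c path, frozen by hand.

        h0: a=(1,0) b=(0,1) c=(1,1); W1 = [I|I] so h1 = h0 + neighbor mean:
        h1(a)=(1,1) h1(b)=(1,1.5) h1(c)=(1,2).  W2 = [[1,-1,.5,0],[0,1,-1,2]]
        and output w=(2,-1), bias .25 give logits (-1.75, -3.25, -3.75).
        """
        params = ModelParams(
            layer_weights=[
                np.hstack([np.eye(2), np.eye(2)]),
                np.array([[1.0, -1.0, 0.5, 0.0], [0.0, 1.0, -1.0, 2.0]]),
            ],
            output_weight=np.array([2.0, -1.0]),
            output_bias=0.25,
        )
        cfg = ModelConfig(depth=2, sample_sizes=(2, 2), hidden_dims=(2, 2), input_dim=2)
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        logits = forward(params, path_graph, features_for(path_graph, X),
                         ["a", "b", "c"], cfg, np.random.default_rng(0))
        assert np.allclose(logits, [-1.75, -3.25, -3.75])

    def test_locality_far_edits_do_not_change_logit(self):
        """A logit depends only on the K-hop neighborhood."""
        names = [f"n{i}" for i in range(10)]
        chain = [(names[i], names[i + 1]) for i in range(9)]
        g1 = GeneGraph(names, chain)
        g2 = GeneGraph(names, chain[:-1])  # delete an edge 9 hops away
        rng = np.random.default_rng(21)
        params, cfg = small_params(rng, 2, 3, 3)
        X = rng.random((10, 2))
        kw = dict(targets=["n0"], config=cfg)
        l1 = forward(params, g1, features_for(g1, X), rng=np.random.default_rng(5), **kw)
        l2 = forward(params, g2, features_for(g2, X), rng=np.random.default_rng(5), **kw)
        assert np.allclose(l1, l2)


class TestLoss:
    def test_closed_form_weighted_value(self):
        assert weighted_bce_loss([0.5], [1], (4.0, 1.0)) == pytest.approx(4 * np.log(2))

    def test_perfect_fit_limit(self):
        loss = weighted_bce_loss([1 - 1e-12, 1e-12], [1, 0], (4.0, 1.0))
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_unit_weights_reduce_to_plain_bce(self):
        p = np.array([0.2, 0.7, 0.9])
        y = np.array([0, 1, 1])
        expected = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert weighted_bce_loss(p, y, (1.0, 1.0)) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_bce_loss([0.5], [1, 0])


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Central finite differences vs analytic gradients on a 4-node graph."""
        g = GeneGraph("abcd", [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c")])
        rng = np.random.default_rng(31)
        params, cfg = small_params(rng, 2, 3, 3)
        X = rng.random((4, 2))
        y = np.array([1.0, 0.0, 1.0, 0.0])
        w = (4.0, 1.0)
        cg = sample_neighborhood(g, list(g.nodes), cfg.sample_sizes, np.random.default_rng(0))

        def loss_at(p):
            return _loss_from_logits(_forward_cg(p, cg, X), y, w)

        logits, h_t, pos, cache = _forward_cg(params, cg, X, want_cache=True)
        gW, g_ow, g_ob = _backward_cg(params, cg, cache, h_t, pos,
                                      _dloss_dlogits(logits, y, w))
        eps = 1e-6
        for arr, grad in [*zip(params.layer_weights, gW), (params.output_weight, g_ow)]:
            flat = arr.ravel()
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                up = loss_at(params)
                flat[i] = orig - eps
                dn = loss_at(params)
                flat[i] = orig
                fd = (up - dn) / (2 * eps)
                assert np.asarray(grad).ravel()[i] == pytest.approx(fd, abs=1e-4)
        params.output_bias += eps
        up = loss_at(params)
        params.output_bias -= 2 * eps
        dn = loss_at(params)
        params.output_bias += eps
        assert g_ob == pytest.approx((up - dn) / (2 * eps), abs=1e-4)


def tiny_labeled_dataset(seed=0, n=60):
    """Small separable dataset: essential genes carry a strong feature shift."""
    rng = np.random.default_rng(seed)
    g = random_gene_graph(n, 0.1, seed=seed)
    ess = set(list(g.nodes)[: n // 5])
    X = rng.standard_normal((n, 4))
    X[[i for i, v in enumerate(g.nodes) if v in ess]] += 2.5
    labels = LabelSet(ess, set(g.nodes) - ess, set())
    return AlignedDataset(graph=g, features=features_for(g, X), labels=labels)


class TestTraining:
    def test_zero_epochs_returns_initial_params(self):
        ds = tiny_labeled_dataset()
        m = EssSubgraph(ds, max_epochs=0, hidden_dims=(4, 4, 4))
        res = m.fit(seed=1)
        assert res.history.train_loss == [] and res.history.stopped_epoch == 0

    def test_no_positives_errors(self):
        ds = tiny_labeled_dataset()
        m = EssSubgraph(ds, hidden_dims=(4, 4, 4))
        neg = sorted(ds.labels.nonessential)
        with pytest.raises(ValueError, match="no essential"):
            m.fit(train_nodes=neg[:30], val_nodes=neg[30:40])

    def test_separable_dataset_reaches_high_training_auprc(self):
        from esssubgraph import auprc

        hits = 0
        for seed in range(5):
            ds = tiny_labeled_dataset(seed=seed)
            res = EssSubgraph(ds, hidden_dims=(8, 8, 8), batch_size=64).fit(seed=seed)
            train = sorted(ds.labels.essential | ds.labels.nonessential)
            p = res.predict_scores(train, seed=0)
            y = [1 if gname in ds.labels.essential else 0 for gname in train]
            if auprc(p, y) > 0.95:
                hits += 1
        assert hits >= 4

    def test_early_stopping_respects_patience(self):
        ds = tiny_labeled_dataset()
        res = EssSubgraph(ds, hidden_dims=(4, 4, 4), patience=3, max_epochs=100).fit(seed=2)
        h = res.history
        assert h.stopped_epoch <= h.best_epoch + 3 or h.stopped_epoch == 100

    def test_seeded_training_reproducible(self):
        ds = tiny_labeled_dataset()
        r1 = EssSubgraph(ds, hidden_dims=(4, 4, 4), max_epochs=15, patience=15).fit(seed=3)
        r2 = EssSubgraph(ds, hidden_dims=(4, 4, 4), max_epochs=15, patience=15).fit(seed=3)
        assert r1.history.train_loss == r2.history.train_loss
        assert r1.history.val_loss == r2.history.val_loss

    def test_inductive_scoring_on_supergraph(self):
        """Model trained on a subgraph scores new nodes of a supergraph."""
        ds = tiny_labeled_dataset(seed=4)
        g = ds.graph
        res = EssSubgraph(ds, hidden_dims=(4, 4, 4), max_epochs=10).fit(seed=4)
        extra = ["new1", "new2"]
        g_sup = GeneGraph(
            list(g.nodes) + extra,
            list(g.edges) + [("new1", g.nodes[0]), ("new2", "new1")],
        )
        X_sup = np.vstack([ds.features.frame.to_numpy(), np.zeros((2, 4))])
        f_sup = features_for(g_sup, np.zeros((g_sup.n_nodes, 4)))
        f_sup.frame.loc[list(g.nodes)] = ds.features.frame
        p = res.predict_scores(extra, graph=g_sup, features=f_sup, seed=0)
        assert p.shape == (2,) and np.all((p > 0) & (p < 1))

    def test_sigmoid_of_zero_logit_is_half(self):
        ds = tiny_labeled_dataset()
        m = EssSubgraph(ds, hidden_dims=(4, 4, 4), max_epochs=0)
        res = m.fit(seed=5)
        for W in res.params.layer_weights:
            W[:] = 0.0
        res.params.output_bias = 0.0
        p = res.predict_scores(list(ds.graph.nodes[:3]), seed=0)
        assert np.allclose(p, 0.5)

    def test_summary_mentions_configuration(self):
        ds = tiny_labeled_dataset()
        res = EssSubgraph(ds, hidden_dims=(4, 4, 4), max_epochs=5).fit(seed=6)
        s = res.summary()
        assert "Sample sizes" in s and "[30, 25, 10]" in s
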