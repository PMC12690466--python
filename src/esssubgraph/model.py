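"""The inductive sample-and-aggregate essential-gene classifier.

Each layer k updates a node's representation by averaging the representations
of a sampled neighbor set, concatenating that mean onto the node's own current
representation, and pushing the concatenation through a learnable linear map
with ReLU:

    h_N(v)^k = mean{ h_u^(k-1) : u in sampled N(v) }
    h_v^k    = relu( W^k · concat(h_v^(k-1), h_N(v)^k) )

After K (default 3) such steps a learnable linear projection maps h_v^K to a
single logit; the sigmoid of that logit is the predicted probability that gene
v is essential.  Training minimizes class-weighted binary cross-entropy
(weight 4 on essential, 1 on nonessential by default) with Adam, early
stopping on validation loss.  Because a prediction touches only the sampled
K-hop neighborhood, trained models score nodes of graphs they never saw —
including entirely new genes, provided those have feature vectors.

The network is implemented directly in numpy: forward, analytic backprop
through the aggregation layers, and Adam, with all randomness drawn from
seeded generators so runs are bit-reproducible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .features import FeatureMatrix
from .graph import AlignedDataset, GeneGraph
from .sampling import ComputationGraph, sample_neighborhood

__all__ = [
    "ModelConfig",
    "ModelParams",
    "TrainHistory",
    "EssSubgraph",
    "EssSubgraphResults",
    "aggregate_step",
    "forward",
    "weighted_bce_loss",
    "train_model",
    "predict_scores",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the sampler, network, and optimizer."""

    depth: int = 3
    sample_sizes: tuple[int, ...] = (30, 25, 10)   # hop 1 (direct neighbors) first
    input_dim: int | None = None                    # inferred from features at fit time
    hidden_dims: tuple[int, ...] = (64, 64, 64)
    learning_rate: float = 0.01
    max_epochs: int = 200
    patience: int = 10
    min_delta: float = 1e-4   # minimum val-loss improvement that resets patience
    batch_size: int = 512
    class_weights: tuple[float, float] = (4.0, 1.0)  # (essential, nonessential)
    seed: int = 0

    def __post_init__(self):
        self.sample_sizes = tuple(int(s) for s in self.sample_sizes)
        self.hidden_dims = tuple(int(d) for d in self.hidden_dims)
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if len(self.sample_sizes) != self.depth or len(self.hidden_dims) != self.depth:
            raise ValueError("sample_sizes and hidden_dims must have length == depth")
        if any(s <= 0 for s in self.sample_sizes):
            raise ValueError("sample sizes must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be positive")


@dataclass
class ModelParams:
    """Learnable weights: one W^k per layer plus the output projection."""

    layer_weights: list[np.ndarray]   # W^k of shape (d_k, 2 * d_{k-1})
    output_weight: np.ndarray         # (d_K,)
    output_bias: float

    def copy(self) -> "ModelParams":
        return ModelParams(
            [w.copy() for w in self.layer_weights],
            self.output_weight.copy(),
            float(self.output_bias),
        )

    def flatten(self) -> list[np.ndarray]:
        return [*self.layer_weights, self.output_weight, np.array([self.output_bias])]

    @staticmethod
    def initialize(config: ModelConfig, rng: np.random.Generator) -> "ModelParams":
        dims = [config.input_dim, *config.hidden_dims]
        weights = []
        for k in range(config.depth):
            fan_in, fan_out = 2 * dims[k], dims[k + 1]
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            weights.append(rng.uniform(-bound, bound, size=(fan_out, fan_in)))
        out_w = rng.uniform(-0.1, 0.1, size=dims[-1])
        return ModelParams(weights, out_w, 0.0)

    def save(self, path) -> None:
        arrays = {f"W{k + 1}": w for k, w in enumerate(self.layer_weights)}
        arrays["output_weight"] = self.output_weight
        arrays["output_bias"] = np.array(self.output_bias)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ModelParams":
        z = np.load(path)
        ws = [z[f"W{k + 1}"] for k in range(sum(1 for n in z.files if n.startswith("W")))]
        return cls(ws, z["output_weight"], float(z["output_bias"]))


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def aggregate_step(h_self: np.ndarray, neighbor_vectors, W: np.ndarray) -> np.ndarray:
    """One aggregation: mean of neighbors (zero vector if none), concatenated
    after the node's own vector, multiplied by W, rectified."""
    h_self = np.asarray(h_self, dtype=float)
    neighbor_vectors = [np.asarray(v, dtype=float) for v in neighbor_vectors]
    d = h_self.shape[0]
    for v in neighbor_vectors:
        if v.shape != (d,):
            raise ValueError("neighbor vector dimension mismatch")
    mean = np.mean(neighbor_vectors, axis=0) if neighbor_vectors else np.zeros(d)
    concat = np.concatenate([h_self, mean])
    if W.shape[1] != 2 * d:
        raise ValueError(f"W maps length-{W.shape[1]} input, expected {2 * d}")
    return np.maximum(W @ concat, 0.0)


def _forward_cg(params: ModelParams, cg: ComputationGraph, X: np.ndarray, want_cache: bool = False):
    """Evaluate logits for ``cg.targets`` given node features X (n_nodes × d)."""
    K = cg.depth
    h = X[cg.hops[K - 1].support]  # h^0 for every node the deepest hop touched
    cache = []
    for k in range(1, K + 1):
        hop = cg.hops[K - k]
        M = hop.mean_operator()
        mean = M @ h
        h_self = h[hop.self_pos]
        concat = np.hstack([h_self, mean])
        z = concat @ params.layer_weights[k - 1].T
        h_new = np.maximum(z, 0.0)
        if want_cache:
            cache.append((hop, M, concat, z > 0))
        h = h_new
    # h now holds h^K for the hop-1 frontier (sorted unique targets)
    pos = np.searchsorted(cg.hops[0].frontier, cg.targets)
    h_targets = h[pos]
    logits = h_targets @ params.output_weight + params.output_bias
    if want_cache:
        return logits, h_targets, pos, cache
    return logits


def _backward_cg(params, cg, cache, h_targets, pos, dlogits):
    """Backprop through the cached forward pass; returns gradients shaped
    like the parameter list (layer weights, output weight, output bias)."""
    K = cg.depth
    gW = [None] * K
    g_out_w = h_targets.T @ dlogits
    g_out_b = float(np.sum(dlogits))
    n_front = len(cg.hops[0].frontier)
    dh = np.zeros((n_front, params.output_weight.shape[0]))
    np.add.at(dh, pos, np.outer(dlogits, params.output_weight))
    for k in range(K, 0, -1):
        hop, M, concat, relu_mask = cache[k - 1]
        dz = dh * relu_mask
        gW[k - 1] = dz.T @ concat
        dconcat = dz @ params.layer_weights[k - 1]
        d_prev = concat.shape[1] // 2
        dself = dconcat[:, :d_prev]
        dmean = dconcat[:, d_prev:]
        dh_prev = np.zeros((len(hop.support), d_prev))
        dh_prev[hop.self_pos] += dself
        dh_prev += M.T @ dmean
        dh = dh_prev
    return gW, g_out_w, g_out_b


def forward(
    params: ModelParams,
    graph: GeneGraph,
    features: FeatureMatrix,
    targets,
    config: ModelConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample a computation graph and return one logit per target."""
    cg = sample_neighborhood(graph, targets, config.sample_sizes, rng)
    X = _feature_array(graph, features)
    return _forward_cg(params, cg, X)


def _feature_array(graph: GeneGraph, features: FeatureMatrix) -> np.ndarray:
    missing = [g for g in graph.nodes if g not in features.frame.index]
    if missing:
        raise ValueError(f"feature rows missing for graph nodes: {missing[:5]}")
    return features.frame.loc[list(graph.nodes)].to_numpy(dtype=float)


def weighted_bce_loss(probabilities, labels, weights=(4.0, 1.0)) -> float:
    """Mean class-weighted binary cross-entropy.

    Computed from logits internally for numerical stability; probabilities are
    the mathematical contract."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    z = np.log(p) - np.log1p(-p)  # logits
    return _loss_from_logits(z, y, weights)


def _loss_from_logits(z, y, weights) -> float:
    w_pos, w_neg = weights
    w = np.where(y == 1, w_pos, w_neg)
    # softplus(z) - y z == -[y log σ(z) + (1-y) log(1-σ(z))]
    softplus = np.logaddexp(0.0, z)
    return float(np.mean(w * (softplus - y * z)))


def _dloss_dlogits(z, y, weights) -> np.ndarray:
    w_pos, w_neg = weights
    w = np.where(y == 1, w_pos, w_neg)
    sig = 1.0 / (1.0 + np.exp(-z))
    return w * (sig - y) / len(z)


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params_list, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params_list, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class EssSubgraph:
    """Model object: an aligned dataset plus a configuration.

    Parameters
    ----------
    dataset
        Graph + node features + labels over one gene universe.
    config
        Optional :class:`ModelConfig`; keyword overrides are applied on top.

    ``fit`` trains with Adam and early stopping and returns an
    :class:`EssSubgraphResults`.
    """

    def __init__(self, dataset: AlignedDataset, config: ModelConfig | None = None, **overrides):
        config = config or ModelConfig()
        if overrides:
            config = replace(config, **overrides)
        if config.input_dim is None:
            config = replace(config, input_dim=dataset.features.dim)
        elif config.input_dim != dataset.features.dim:
            raise ValueError("config.input_dim does not match feature dimensionality")
        self.dataset = dataset
        self.config = config
        self._X = _feature_array(dataset.graph, dataset.features)
        self._labels01 = {g: 1 for g in dataset.labels.essential}
        self._labels01.update({g: 0 for g in dataset.labels.nonessential})

    def _node_labels(self, nodes) -> np.ndarray:
        try:
            return np.array([self._labels01[g] for g in nodes], dtype=float)
        except KeyError as e:
            raise ValueError(f"node {e.args[0]!r} is unlabeled") from None

    def fit(
        self,
        train_nodes=None,
        val_nodes=None,
        seed: int | None = None,
    ) -> "EssSubgraphResults":
        """Train on ``train_nodes`` with early stopping on ``val_nodes``.

        When node sets are omitted, all labeled genes are split 90/10
        (stratified) into train and validation using the seed.
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        root = np.random.SeedSequence(seed)
        ss_init, ss_split, ss_epochs, ss_val = root.spawn(4)
        if train_nodes is None or val_nodes is None:
            train_nodes, val_nodes = self._default_split(np.random.default_rng(ss_split))
        train_nodes = list(train_nodes)
        val_nodes = list(val_nodes)
        if set(train_nodes) & set(val_nodes):
            raise ValueError("train and validation nodes must be disjoint")
        y_train = self._node_labels(train_nodes)
        y_val = self._node_labels(val_nodes)
        if not np.any(y_train == 1):
            raise ValueError("no essential genes in the training set")

        params = ModelParams.initialize(cfg, np.random.default_rng(ss_init))
        history = TrainHistory()
        if cfg.max_epochs == 0:
            return EssSubgraphResults(self, params, history)

        adam = _Adam([w.shape for w in params.flatten()], cfg.learning_rate)
        bias_arr = np.array([params.output_bias])
        opt_slots = [*params.layer_weights, params.output_weight, bias_arr]
        graph, X = self.dataset.graph, self._X
        train_ids = np.array([graph.node_index[g] for g in train_nodes])
        val_ids = np.array([graph.node_index[g] for g in val_nodes])
        best = params.copy()
        best_val = np.inf
        epoch_seeds = ss_epochs.spawn(cfg.max_epochs)
        val_rng_seed = ss_val  # fresh generator each epoch, same stream
        since_best = 0
        for epoch in range(cfg.max_epochs):
            rng = np.random.default_rng(epoch_seeds[epoch])
            order = rng.permutation(len(train_ids))
            batch_losses = []
            for start in range(0, len(train_ids), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                cg = sample_neighborhood(graph, train_ids[idx], cfg.sample_sizes, rng)
                logits, h_t, pos, cache = _forward_cg(params, cg, X, want_cache=True)
                yb = y_train[idx]
                batch_losses.append(_loss_from_logits(logits, yb, cfg.class_weights))
                dlogits = _dloss_dlogits(logits, yb, cfg.class_weights)
                gW, g_ow, g_ob = _backward_cg(params, cg, cache, h_t, pos, dlogits)
                adam.step(opt_slots, [*gW, g_ow, np.array([g_ob])])
                params.output_bias = float(bias_arr[0])
            history.train_loss.append(float(np.mean(batch_losses)))
            vrng = np.random.default_rng(val_rng_seed.spawn(1)[0])
            vcg = sample_neighborhood(graph, val_ids, cfg.sample_sizes, vrng)
            vlogits = _forward_cg(params, vcg, X)
            vloss = _loss_from_logits(vlogits, y_val, cfg.class_weights)
            history.val_loss.append(vloss)
            if vloss < best_val - cfg.min_delta:
                best_val = vloss
                best = params.copy()
                history.best_epoch = epoch + 1
                since_best = 0
            else:
                since_best += 1
            history.stopped_epoch = epoch + 1
            if since_best >= cfg.patience:
                break
        return EssSubgraphResults(self, best, history)

    def _default_split(self, rng: np.random.Generator, val_fraction: float = 0.10):
        labeled = sorted(self._labels01)
        y = np.array([self._labels01[g] for g in labeled])
        val = []
        for cls in (0, 1):
            members = [g for g, yy in zip(labeled, y) if yy == cls]
            n_val = max(1, int(round(val_fraction * len(members))))
            val.extend(rng.choice(members, size=n_val, replace=False))
        val_set = set(val)
        train = [g for g in labeled if g not in val_set]
        return train, sorted(val_set)


class EssSubgraphResults:
    """Fitted parameters, training history, and prediction methods."""

    def __init__(self, model: EssSubgraph, params: ModelParams, history: TrainHistory):
        self.model = model
        self.params = params
        self.history = history
        self.config = model.config

    def predict_scores(
        self,
        targets=None,
        graph: GeneGraph | None = None,
        features: FeatureMatrix | None = None,
        seed: int = 0,
    ) -> np.ndarray:
        """Essentiality probabilities for ``targets``.

        A supplied ``graph``/``features`` pair may be a strict supergraph of
        the training data — the inductive path for unseen genes.  One seeded
        neighborhood sample is drawn; repeat with different seeds to quantify
        sampling variance.
        """
        graph = graph or self.model.dataset.graph
        features = features or self.model.dataset.features
        if targets is None:
            targets = list(graph.nodes)
        rng = np.random.default_rng(seed)
        logits = forward(self.params, graph, features, targets, self.config, rng)
        return 1.0 / (1.0 + np.exp(-logits))

    def predict_labels(self, targets=None, cutoff: float = 0.5, **kw) -> np.ndarray:
        return (self.predict_scores(targets, **kw) >= cutoff).astype(int)

    def score_table(self, targets=None, cutoff: float = 0.5, seed: int = 0):
        import pandas as pd

        graph = self.model.dataset.graph
        targets = list(graph.nodes) if targets is None else list(targets)
        p = self.predict_scores(targets, seed=seed)
        return pd.DataFrame(
            {"gene": targets, "probability": p, "predicted": (p >= cutoff).astype(int)}
        )

    def summary(self) -> str:
        cfg = self.config
        n_params = sum(w.size for w in self.params.layer_weights) + self.params.output_weight.size + 1
        buf = io.StringIO()
        w = buf.write
        w("EssSubgraph Results\n")
        w("=" * 54 + "\n")
        w(f"{'Depth (K)':<30}{cfg.depth}\n")
        w(f"{'Sample sizes (hop 1..K)':<30}{list(cfg.sample_sizes)}\n")
        w(f"{'Hidden dims':<30}{list(cfg.hidden_dims)}\n")
        w(f"{'Input dim':<30}{cfg.input_dim}\n")
        w(f"{'Learnable parameters':<30}{n_params}\n")
        w(f"{'Learning rate (Adam)':<30}{cfg.learning_rate}\n")
        w(f"{'Class weights (ess/noness)':<30}{cfg.class_weights[0]:g}/{cfg.class_weights[1]:g}\n")
        w(f"{'Epochs run':<30}{self.history.stopped_epoch}/{cfg.max_epochs}\n")
        w(f"{'Best epoch (val loss)':<30}{self.history.best_epoch}\n")
        if self.history.train_loss:
            w(f"{'Final train loss':<30}{self.history.train_loss[-1]:.4f}\n")
        if self.history.val_loss:
            best = min(self.history.val_loss)
            w(f"{'Best val loss':<30}{best:.4f}\n")
        w("=" * 54 + "\n")
        return buf.getvalue()


def train_model(
    dataset: AlignedDataset, train_nodes, val_nodes, config: ModelConfig
) -> tuple[ModelParams, TrainHistory]:
    """Functional wrapper: train and return (best parameters, history)."""
    res = EssSubgraph(dataset, config).fit(train_nodes, val_nodes)
    return res.params, res.history


def predict_scores(
    params: ModelParams,
    graph: GeneGraph,
    features: FeatureMatrix,
    targets,
    config: ModelConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Functional wrapper: sigmoid of forward logits, no retraining."""
    logits = forward(params, graph, features, targets, config, rng)
    return 1.0 / (1.0 + np.exp(-logits))
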