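"""Differentiable classifiers implemented directly on numpy.

Two binary pathogenicity classifiers are provided:

* ``MLP`` — a three-layer perceptron (input, one rectified hidden layer whose
  width is the tuned hyperparameter, sigmoid output), with optional batch
  normalization on the hidden pre-activation.
* ``NeuralDecisionForest`` — a shallow neural decision forest: a fully
  connected layer produces one split activation ``f_n`` per decision node of
  every tree; the decision function ``d_n(x) = sigmoid(f_n(x))`` routes a
  sample stochastically left/right, a leaf's reach probability is the product
  of routing probabilities along its root-to-leaf path, the tree prediction
  mixes leaf class distributions ``pi_l`` by reach probability, and the
  forest averages the trees. Each tree sees a fixed random subset of input
  features (``feature_rate``). Leaf distributions are trained jointly with
  the split weights by gradient on softmax-mapped logits, which keeps the
  whole model inside a single flat parameter vector as federated exchange
  requires.

Both models expose analytic gradients (validated against finite differences
in the test suite) so that training requires no autodiff framework; the
forward/backward passes are plain vectorized array arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fedvar.params import ParameterVector, flatten_params, unflatten_params

__all__ = ["MLPConfig", "MLP", "ForestConfig", "NeuralDecisionForest"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class MLPConfig:
    """Architecture of the perceptron: one hidden layer of ``n_hidden`` units."""

    input_dim: int
    n_hidden: int = 5
    use_batch_norm: bool = False

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")


class MLP:
    """Three-layer MLP (input -> ReLU hidden -> sigmoid output)."""

    def __init__(self, config: MLPConfig):
        self.config = config
        self.non_trainable = (
            frozenset({"bn_running_mean", "bn_running_var"})
            if config.use_batch_norm
            else frozenset()
        )
        #: names whose exchange is governed by the federation's bn_policy
        self.bn_param_names = (
            frozenset({"bn_gamma", "bn_beta", "bn_running_mean", "bn_running_var"})
            if config.use_batch_norm
            else frozenset()
        )

    def init_params(self, seed: int) -> ParameterVector:
        rng = np.random.default_rng(seed)
        d, h = self.config.input_dim, self.config.n_hidden
        params = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h)),
            "b1": np.zeros(h),
            "W2": rng.normal(0.0, np.sqrt(2.0 / h), size=(h, 1)),
            "b2": np.zeros(1),
        }
        if self.config.use_batch_norm:
            params["bn_gamma"] = np.ones(h)
            params["bn_beta"] = np.zeros(h)
            params["bn_running_mean"] = np.zeros(h)
            params["bn_running_var"] = np.ones(h)
        return flatten_params(params)

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected (n, {self.config.input_dim}) input, got {X.shape}"
            )
        return X

    def scores(self, params: ParameterVector | dict, X: np.ndarray) -> np.ndarray:
        """Pathogenicity scores in [0, 1]; inference mode (running BN stats)."""
        p = unflatten_params(params) if isinstance(params, ParameterVector) else params
        X = self._check_X(X)
        z1 = X @ p["W1"] + p["b1"]
        if self.config.use_batch_norm:
            xhat = (z1 - p["bn_running_mean"]) / np.sqrt(p["bn_running_var"] + _BN_EPS)
            z1 = p["bn_gamma"] * xhat + p["bn_beta"]
        a = np.maximum(z1, 0.0)
        return _sigmoid(a @ p["W2"] + p["b2"]).ravel()

    def loss_grad(
        self, p: dict[str, np.ndarray], X: np.ndarray, y: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean binary cross-entropy and its gradient (training mode).

        With batch normalization, batch statistics are used and the running
        statistics in ``p`` are updated in place (momentum 0.1).
        """
        X = self._check_X(X)
        y = np.asarray(y, dtype=float)
        B = X.shape[0]
        z1 = X @ p["W1"] + p["b1"]
        use_bn = self.config.use_batch_norm
        if use_bn:
            mu = z1.mean(axis=0)
            var = z1.var(axis=0)
            inv = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (z1 - mu) * inv
            h_pre = p["bn_gamma"] * xhat + p["bn_beta"]
            p["bn_running_mean"] *= 1.0 - _BN_MOMENTUM
            p["bn_running_mean"] += _BN_MOMENTUM * mu
            p["bn_running_var"] *= 1.0 - _BN_MOMENTUM
            p["bn_running_var"] += _BN_MOMENTUM * var
        else:
            h_pre = z1
        a = np.maximum(h_pre, 0.0)
        logits = (a @ p["W2"] + p["b2"]).ravel()
        loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
        g_logit = (_sigmoid(logits) - y)[:, None] / B  # (B, 1)
        grads: dict[str, np.ndarray] = {
            "W2": a.T @ g_logit,
            "b2": g_logit.sum(axis=0),
        }
        g_a = g_logit @ p["W2"].T
        g_hpre = g_a * (h_pre > 0)
        if use_bn:
            grads["bn_gamma"] = (g_hpre * xhat).sum(axis=0)
            grads["bn_beta"] = g_hpre.sum(axis=0)
            g_xhat = g_hpre * p["bn_gamma"]
            g_z1 = (inv / B) * (
                B * g_xhat
                - g_xhat.sum(axis=0)
                - xhat * (g_xhat * xhat).sum(axis=0)
            )
            grads["bn_running_mean"] = np.zeros_like(p["bn_running_mean"])
            grads["bn_running_var"] = np.zeros_like(p["bn_running_var"])
        else:
            g_z1 = g_hpre
        grads["W1"] = X.T @ g_z1
        grads["b1"] = g_z1.sum(axis=0)
        return loss, grads


@dataclass(frozen=True)
class ForestConfig:
    """Architecture of the shallow neural decision forest."""

    input_dim: int
    n_trees: int = 5
    depth: int = 3
    feature_rate: float = 0.7
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 < self.feature_rate <= 1.0:
            raise ValueError("feature_rate must lie in (0, 1]")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    @property
    def n_split_nodes(self) -> int:
        return 2 ** self.depth - 1

    @property
    def n_leaves(self) -> int:
        return 2 ** self.depth


class NeuralDecisionForest:
    """Shallow neural decision forest over heap-ordered full binary trees.

    Internal nodes are indexed 0..N-1 in level order (children of ``i`` at
    ``2i+1``/``2i+2``); array slots N..N+L-1 are the leaves. Feature masks are
    drawn once at initialization and travel inside the parameter vector as a
    non-trainable segment, so every federated client routes through identical
    trees.
    """

    def __init__(self, config: ForestConfig):
        self.config = config
        self.non_trainable = frozenset({"masks"})
        self.bn_param_names = frozenset()

    def init_params(self, seed: int) -> ParameterVector:
        rng = np.random.default_rng(seed)
        c = self.config
        d, T, N, L = c.input_dim, c.n_trees, c.n_split_nodes, c.n_leaves
        masks = (rng.random((T, d)) < c.feature_rate).astype(float)
        for t in range(T):  # every tree must see at least one feature
            if masks[t].sum() == 0:
                masks[t, rng.integers(0, d)] = 1.0
        params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / d), size=(T, d, N)),
            "b": np.zeros((T, N)),
            "leaf_logits": np.zeros((T, L, c.n_classes)),
            "masks": masks,
        }
        return flatten_params(params)

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected (n, {self.config.input_dim}) input, got {X.shape}"
            )
        return X

    def _forward(self, p: dict, X: np.ndarray):
        c = self.config
        N, L = c.n_split_nodes, c.n_leaves
        W = p["W"] * p["masks"][:, :, None]
        f = np.einsum("bd,tdn->btn", X, W) + p["b"]  # split activations
        d = _sigmoid(f)  # routing probabilities (left)
        B, T = X.shape[0], c.n_trees
        mu = np.empty((B, T, N + L))
        mu[:, :, 0] = 1.0
        for i in range(N):
            mu[:, :, 2 * i + 1] = mu[:, :, i] * d[:, :, i]
            mu[:, :, 2 * i + 2] = mu[:, :, i] * (1.0 - d[:, :, i])
        leaf_reach = mu[:, :, N:]  # (B, T, L)
        logits = p["leaf_logits"] - p["leaf_logits"].max(axis=-1, keepdims=True)
        e = np.exp(logits)
        pi = e / e.sum(axis=-1, keepdims=True)  # (T, L, C)
        p_tree = np.einsum("btl,tlc->btc", leaf_reach, pi)
        p_forest = p_tree.mean(axis=1)  # (B, C)
        return f, d, mu, leaf_reach, pi, p_tree, p_forest

    def forward(self, params: ParameterVector | dict, X: np.ndarray) -> np.ndarray:
        """Per-row class-probability vectors (forest average of tree mixes)."""
        p = unflatten_params(params) if isinstance(params, ParameterVector) else params
        X = self._check_X(X)
        return self._forward(p, X)[-1]

    def leaf_reach_probabilities(
        self, params: ParameterVector | dict, X: np.ndarray
    ) -> np.ndarray:
        """(n, n_trees, n_leaves) reach probabilities; each tree sums to 1."""
        p = unflatten_params(params) if isinstance(params, ParameterVector) else params
        X = self._check_X(X)
        return self._forward(p, X)[3]

    def scores(self, params: ParameterVector | dict, X: np.ndarray) -> np.ndarray:
        """Pathogenicity score = probability of the pathogenic class."""
        return self.forward(params, X)[:, 1]

    def loss_grad(
        self, p: dict[str, np.ndarray], X: np.ndarray, y: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean negative log-likelihood of the forest probabilities + gradient."""
        X = self._check_X(X)
        y = np.asarray(y, dtype=int)
        c = self.config
        N, L, T = c.n_split_nodes, c.n_leaves, c.n_trees
        B = X.shape[0]
        f, d, mu, leaf_reach, pi, p_tree, p_forest = self._forward(p, X)
        py = np.maximum(p_forest[np.arange(B), y], 1e-12)
        loss = float(-np.mean(np.log(py)))
        g_p = np.zeros_like(p_forest)
        g_p[np.arange(B), y] = -1.0 / (py * B)
        g_ptree = np.repeat(g_p[:, None, :], T, axis=1) / T  # (B, T, C)
        # leaf distributions (softmax jacobian)
        g_pi = np.einsum("btc,btl->tlc", g_ptree, leaf_reach)
        g_leaf_logits = pi * (g_pi - (g_pi * pi).sum(axis=-1, keepdims=True))
        # routing
        g_mu = np.zeros_like(mu)
        g_mu[:, :, N:] = np.einsum("btc,tlc->btl", g_ptree, pi)
        g_d = np.empty_like(d)
        for i in range(N - 1, -1, -1):
            gl, gr = g_mu[:, :, 2 * i + 1], g_mu[:, :, 2 * i + 2]
            g_d[:, :, i] = (gl - gr) * mu[:, :, i]
            g_mu[:, :, i] += gl * d[:, :, i] + gr * (1.0 - d[:, :, i])
        g_f = g_d * d * (1.0 - d)
        g_W = np.einsum("bd,btn->tdn", X, g_f) * p["masks"][:, :, None]
        grads = {
            "W": g_W,
            "b": g_f.sum(axis=0),
            "leaf_logits": g_leaf_logits,
            "masks": np.zeros_like(p["masks"]),
        }
        return loss, grads
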