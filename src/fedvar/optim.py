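"""Local (client-side) mini-batch training.

Clients optimize the received model with SGD (momentum 0.9) or Adam for a
fixed number of local epochs (default 10), with L2 weight decay 1e-4 applied
through the gradient. When a proximal coefficient mu > 0 is set (FedProx),
the loss gains (mu/2)·||w - w_anchor||^2, pulling local updates toward the
broadcast global model; mu = 0 with SGD recovers plain FedAvg local training
exactly.

All randomness (batch shuffling) flows from the seed argument, so two calls
with identical inputs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fedvar.params import ParameterVector, flatten_params, unflatten_params

__all__ = ["LocalTrainConfig", "local_train"]


@dataclass(frozen=True)
class LocalTrainConfig:
    optimizer: str = "sgd"  # "sgd" (momentum 0.9) or "adam"
    learning_rate: float = 0.01
    batch_size: int = 32
    epochs: int = 10
    weight_decay: float = 1e-4
    momentum: float = 0.9
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    proximal_mu: float = 0.0
    anchor: ParameterVector | None = None

    def __post_init__(self) -> None:
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.proximal_mu < 0:
            raise ValueError("proximal_mu must be >= 0")
        if self.proximal_mu > 0 and self.anchor is None:
            raise ValueError("proximal_mu > 0 requires an anchor parameter vector")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


def local_train(
    model,
    params: ParameterVector,
    X: np.ndarray,
    y: np.ndarray,
    cfg: LocalTrainConfig,
    seed: int,
) -> ParameterVector:
    """Run ``cfg.epochs`` passes of mini-batch optimization; returns new params.

    The input vector is left untouched. Non-trainable segments (feature masks,
    batch-norm running statistics) are excluded from optimizer updates; BN
    running statistics still evolve through the forward pass.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("cannot train on empty data")
    rng = np.random.default_rng(seed)
    p = unflatten_params(params)
    anchor = unflatten_params(cfg.anchor) if cfg.anchor is not None else None
    trainable = [k for k in p if k not in model.non_trainable]
    vel = {k: np.zeros_like(p[k]) for k in trainable}
    sq = {k: np.zeros_like(p[k]) for k in trainable} if cfg.optimizer == "adam" else None
    step = 0
    n = len(X)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            _, grads = model.loss_grad(p, X[idx], y[idx])
            step += 1
            for k in trainable:
                g = grads[k]
                if cfg.weight_decay:
                    g = g + cfg.weight_decay * p[k]
                if cfg.proximal_mu > 0.0:
                    g = g + cfg.proximal_mu * (p[k] - anchor[k])
                if cfg.optimizer == "sgd":
                    vel[k] = cfg.momentum * vel[k] + g
                    p[k] = p[k] - cfg.learning_rate * vel[k]
                else:
                    vel[k] = cfg.beta1 * vel[k] + (1.0 - cfg.beta1) * g
                    sq[k] = cfg.beta2 * sq[k] + (1.0 - cfg.beta2) * g * g
                    mhat = vel[k] / (1.0 - cfg.beta1 ** step)
                    vhat = sq[k] / (1.0 - cfg.beta2 ** step)
                    p[k] = p[k] - cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.adam_eps)
    return flatten_params(p)
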