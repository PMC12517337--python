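"""Cross-silo federated training loop and server aggregation algorithms.

One federated round: (i) the server holds a global model; (ii) a random
subset of clients (``client_rate``) receives a copy; (iii) each selected
client optimizes it locally for a fixed number of epochs; (iv) clients return
their updated parameters; (v) the server combines them — by size-weighted
averaging (FedAvg/FedProx) or by an adaptive server optimizer applied to the
average client delta as a pseudo-gradient (FedAdagrad, FedAdam, FedYogi).
Rounds repeat up to ``n_rounds`` or until a validation metric stops improving.

The server only ever receives :class:`ClientUpdate` values (parameters plus a
sample count); raw client feature matrices never cross the interface.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from fedvar.optim import LocalTrainConfig, local_train
from fedvar.params import ParameterVector

__all__ = [
    "ALGORITHMS",
    "AggregatorConfig",
    "ClientUpdate",
    "ServerState",
    "RoundLog",
    "FederationError",
    "sample_clients",
    "aggregate_weighted_mean",
    "init_server_state",
    "server_update_adaptive",
    "run_federated_training",
    "run_centralized_training",
    "run_local_training",
]

ALGORITHMS = ("fedavg", "fedprox", "fedadagrad", "fedadam", "fedyogi")
_ADAPTIVE = ("fedadagrad", "fedadam", "fedyogi")


class FederationError(RuntimeError):
    pass


@dataclass(frozen=True)
class AggregatorConfig:
    """Server-side aggregation algorithm and its hyperparameters.

    ``proximal_mu`` applies to FedProx only; ``server_lr``/``tau`` (adaptivity)
    and the moment coefficients apply to the adaptive family. ``bn_policy``
    decides whether batch-norm parameters and running statistics are averaged
    by the server ("aggregate") or kept local per client ("keep_local").
    """

    algorithm: str = "fedavg"
    proximal_mu: float = 0.0
    server_lr: float = 1.0
    tau: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    client_rate: float = 1.0
    n_rounds: int = 200
    bn_policy: str = "aggregate"

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown aggregation algorithm {self.algorithm!r}")
        if not 0.0 < self.client_rate <= 1.0:
            raise ValueError("client_rate must lie in (0, 1]")
        if self.bn_policy not in ("aggregate", "keep_local"):
            raise ValueError(f"unknown bn_policy {self.bn_policy!r}")
        if self.proximal_mu and self.algorithm != "fedprox":
            raise ValueError("proximal_mu applies to fedprox only")


@dataclass(frozen=True)
class ClientUpdate:
    """What a client returns to the server: parameters and its sample count."""

    params: ParameterVector
    n_samples: int
    client_id: str = ""

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class ServerState:
    """Global model plus the adaptive optimizer's moment accumulators."""

    global_params: ParameterVector
    m: np.ndarray
    v: np.ndarray
    round_index: int = 0


@dataclass
class RoundLog:
    round_index: int
    selected_clients: tuple[str, ...]
    aggregate_norm_delta: float
    validation: float | None = None


def _derive_seed(seed: int, round_index: int, client_index: int) -> int:
    return int(
        np.random.SeedSequence((seed, round_index, client_index)).generate_state(1)[0]
    )


def sample_clients(
    client_ids: list[str], client_rate: float, rng: np.random.Generator
) -> list[str]:
    """Uniform subset of size max(1, round-half-up(rate * n)), order-stable."""
    if not client_ids:
        raise ValueError("empty client registry")
    if not 0.0 < client_rate <= 1.0:
        raise ValueError("client_rate must lie in (0, 1]")
    n = len(client_ids)
    k = max(1, int(np.floor(client_rate * n + 0.5)))  # round half up
    chosen = rng.choice(n, size=k, replace=False)
    return [client_ids[i] for i in sorted(chosen)]


def aggregate_weighted_mean(updates: list[ClientUpdate]) -> ParameterVector:
    """Size-weighted average of client parameters: sum_i (n_i / n) * w_i."""
    if not updates:
        raise ValueError("no updates to aggregate")
    layout = updates[0].params.layout
    for u in updates[1:]:
        if u.params.layout != layout:
            raise ValueError(f"layout mismatch in update from client {u.client_id!r}")
    total = float(sum(u.n_samples for u in updates))
    values = np.zeros_like(updates[0].params.values)
    for u in updates:
        values += (u.n_samples / total) * u.params.values
    return ParameterVector(values, layout)


def init_server_state(params: ParameterVector, cfg: AggregatorConfig) -> ServerState:
    """m = 0 and v = tau^2, the standard adaptive-server initialization."""
    n = len(params.values)
    return ServerState(
        global_params=params.copy(),
        m=np.zeros(n),
        v=np.full(n, cfg.tau ** 2),
    )


def server_update_adaptive(
    state: ServerState, updates: list[ClientUpdate], cfg: AggregatorConfig
) -> ServerState:
    """One adaptive server step on the pseudo-gradient Delta.

    Delta = weighted_mean(updates) - global. FedAdagrad accumulates v += Delta^2
    (m = Delta); FedAdam and FedYogi keep an exponential first moment and
    differ in the second moment: Adam's v = beta2*v + (1-beta2)*Delta^2 versus
    Yogi's v = v - (1-beta2)*Delta^2*sign(v - Delta^2). The global model moves
    by server_lr * m / (sqrt(v) + tau).
    """
    if cfg.algorithm not in _ADAPTIVE:
        raise ValueError(f"{cfg.algorithm!r} is not an adaptive server algorithm")
    mean = aggregate_weighted_mean(updates)
    delta = mean.values - state.global_params.values
    if not np.all(np.isfinite(delta)):
        bad = int(np.sum(~np.isfinite(delta)))
        raise FederationError(
            f"non-finite aggregate delta in round {state.round_index + 1}: "
            f"{bad}/{len(delta)} coordinates"
        )
    d2 = delta * delta
    if cfg.algorithm == "fedadagrad":
        m = delta
        v = state.v + d2
    elif cfg.algorithm == "fedadam":
        m = cfg.beta1 * state.m + (1.0 - cfg.beta1) * delta
        v = cfg.beta2 * state.v + (1.0 - cfg.beta2) * d2
    else:  # fedyogi
        m = cfg.beta1 * state.m + (1.0 - cfg.beta1) * delta
        v = state.v - (1.0 - cfg.beta2) * d2 * np.sign(state.v - d2)
    new = state.global_params.values + cfg.server_lr * m / (np.sqrt(v) + cfg.tau)
    return ServerState(
        global_params=ParameterVector(new, state.global_params.layout),
        m=m,
        v=v,
        round_index=state.round_index + 1,
    )


def _bn_index_mask(params: ParameterVector, bn_names: frozenset) -> np.ndarray:
    mask = np.zeros(len(params.values), dtype=bool)
    for name in bn_names:
        mask[params.segment_slice(name)] = True
    return mask


def run_federated_training(
    clients: dict[str, tuple[np.ndarray, np.ndarray]],
    model,
    local_cfg: LocalTrainConfig,
    agg: AggregatorConfig,
    seed: int,
    validation=None,
    patience: int = 20,
) -> tuple[ParameterVector, list[RoundLog]]:
    """Simulate the full federated loop; returns (final params, round logs).

    ``clients`` maps client id to its local (X, y). ``validation``, if given,
    is a callable mapping a ParameterVector to a metric (higher = better)
    evaluated once per round; training stops early when the metric fails to
    strictly improve for ``patience`` consecutive rounds, and the best-round
    parameters are returned. Deterministic under ``seed``: client sampling,
    weight initialization and every client's batch schedule derive from it.
    """
    if not clients:
        raise ValueError("at least one client is required")
    client_ids = list(clients.keys())
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC11E)))
    global_params = model.init_params(seed)
    state = init_server_state(global_params, agg) if agg.algorithm in _ADAPTIVE else None
    keep_local_bn = agg.bn_policy == "keep_local" and model.bn_param_names
    bn_mask = _bn_index_mask(global_params, model.bn_param_names) if keep_local_bn else None
    client_bn: dict[str, np.ndarray] = {}

    logs: list[RoundLog] = []
    best_metric = -np.inf
    best_params = global_params.copy()
    since_best = 0
    for r in range(1, agg.n_rounds + 1):
        selected = sample_clients(client_ids, agg.client_rate, rng)
        updates = []
        for cid in selected:
            X, y = clients[cid]
            broadcast = global_params.copy()
            if keep_local_bn and cid in client_bn:
                broadcast.values[bn_mask] = client_bn[cid]
            cfg = local_cfg
            if agg.algorithm == "fedprox":
                cfg = dataclasses.replace(
                    local_cfg, proximal_mu=agg.proximal_mu, anchor=broadcast
                )
            try:
                new_params = local_train(
                    model, broadcast, X, y, cfg,
                    seed=_derive_seed(seed, r, client_ids.index(cid)),
                )
            except Exception as e:
                raise FederationError(f"client {cid!r} failed in round {r}: {e}") from e
            if keep_local_bn:
                client_bn[cid] = new_params.values[bn_mask].copy()
                # exclude BN from exchange: server sees its own BN values
                exchanged = new_params.copy()
                exchanged.values[bn_mask] = global_params.values[bn_mask]
                new_params = exchanged
            updates.append(ClientUpdate(new_params, n_samples=len(X), client_id=cid))
        if agg.algorithm in _ADAPTIVE:
            state = server_update_adaptive(state, updates, agg)
            new_global = state.global_params
        else:
            new_global = aggregate_weighted_mean(updates)
        delta_norm = float(np.linalg.norm(new_global.values - global_params.values))
        global_params = new_global
        metric = None
        if validation is not None:
            metric = float(validation(global_params))
            if metric > best_metric:
                best_metric = metric
                best_params = global_params.copy()
                since_best = 0
            else:
                since_best += 1
        logs.append(RoundLog(r, tuple(selected), delta_norm, metric))
        if validation is not None and since_best >= patience:
            break
    final = best_params if validation is not None else global_params
    return final, logs


def run_centralized_training(
    X: np.ndarray,
    y: np.ndarray,
    model,
    local_cfg: LocalTrainConfig,
    seed: int,
    n_rounds: int = 200,
    validation=None,
    patience: int = 20,
) -> tuple[ParameterVector, list[RoundLog]]:
    """Pooled-data (CDS) baseline with the same round structure as federation.

    Training proceeds in blocks of ``local_cfg.epochs`` epochs ("rounds") with
    the same per-round seed derivation as the federated loop, so a federated
    run with a single fully participating client reproduces this trajectory
    bit for bit.
    """
    params = model.init_params(seed)
    logs: list[RoundLog] = []
    best_metric = -np.inf
    best_params = params.copy()
    since_best = 0
    for r in range(1, n_rounds + 1):
        new_params = local_train(model, params, X, y, local_cfg,
                                 seed=_derive_seed(seed, r, 0))
        delta_norm = float(np.linalg.norm(new_params.values - params.values))
        params = new_params
        metric = None
        if validation is not None:
            metric = float(validation(params))
            if metric > best_metric:
                best_metric, best_params, since_best = metric, params.copy(), 0
            else:
                since_best += 1
        logs.append(RoundLog(r, ("pooled",), delta_norm, metric))
        if validation is not None and since_best >= patience:
            break
    return (best_params if validation is not None else params), logs


def run_local_training(
    X: np.ndarray,
    y: np.ndarray,
    model,
    local_cfg: LocalTrainConfig,
    seed: int,
    n_rounds: int = 200,
    validation=None,
    patience: int = 20,
) -> tuple[ParameterVector, list[RoundLog]]:
    """Single-institution baseline: centralized training on one silo."""
    return run_centralized_training(
        X, y, model, local_cfg, seed, n_rounds=n_rounds,
        validation=validation, patience=patience,
    )
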