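"""Evaluation battery for comparing centralized and federated classifiers.

Implements the study's procedures: leave-one-chromosome-out fold planning,
collaborative cross-validation (each silo splits locally; the global
validation fold is the union of per-silo folds), AUC-ROC as the normalized
Mann-Whitney U statistic, client-dropout robustness, the IID-repartition null
(random reassignments of training records to silos of unchanged sizes, giving
a null distribution of median AUCs against which the original partition is
z-scored), hyperparameter-grid enumeration, Spearman score similarity, and
the shared early-stopping rule.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from fedvar.cohorts import CHROMOSOMES
from fedvar.features import FeatureMatrix
from fedvar.federation import (
    AggregatorConfig,
    run_centralized_training,
    run_federated_training,
)
from fedvar.optim import LocalTrainConfig

__all__ = [
    "ChromosomeFoldPlan",
    "CcvPlan",
    "ExperimentResult",
    "NullSummary",
    "plan_loco",
    "make_ccv_plan",
    "run_ccv",
    "auc_roc",
    "score_similarity",
    "wilcoxon_rank_sum",
    "enumerate_grid",
    "early_stopping_controller",
    "dropout_study",
    "iid_null_experiment",
    "LOCAL_LEARNING_RATES",
    "LOCAL_OPTIMIZERS",
    "CLIENT_RATES",
    "FEDPROX_MUS",
    "SERVER_LEARNING_RATES",
    "ADAPTIVITY_TAUS",
    "MODEL_FAMILIES",
]


# ---------------------------------------------------------------------------
# hyperparameter grid (the benchmarked FL settings)
# ---------------------------------------------------------------------------

LOCAL_LEARNING_RATES = (0.1, 0.01, 0.001, 0.0001)
LOCAL_OPTIMIZERS = ("sgd", "adam")
CLIENT_RATES = (0.5, 1.0)
FEDPROX_MUS = (0.5, 0.1, 0.01, 0.001, 0.0001, 0.0)
SERVER_LEARNING_RATES = (1.0, 0.1, 0.01, 0.001)
ADAPTIVITY_TAUS = (0.0001, 0.01, 0.1)
MODEL_FAMILIES = ("mlp", "sndf")


def enumerate_grid(
    models=MODEL_FAMILIES,
    local_lrs=LOCAL_LEARNING_RATES,
    optimizers=LOCAL_OPTIMIZERS,
    client_rates=CLIENT_RATES,
    mus=FEDPROX_MUS,
    server_lrs=SERVER_LEARNING_RATES,
    taus=ADAPTIVITY_TAUS,
) -> list[dict]:
    """Enumerate every benchmarked FL setting as a flat list of config dicts.

    Per model family: FedProx crosses local learning rate x local optimizer x
    client rate x proximal mu; each adaptive algorithm (FedAdagrad, FedAdam,
    FedYogi) crosses local learning rate x local optimizer x client rate x
    server learning rate x adaptivity tau.
    """
    for name, axis in (
        ("models", models), ("local_lrs", local_lrs), ("optimizers", optimizers),
        ("client_rates", client_rates), ("mus", mus),
        ("server_lrs", server_lrs), ("taus", taus),
    ):
        if not tuple(axis):
            raise ValueError(f"empty grid axis {name!r}")
    grid: list[dict] = []
    for model in models:
        for lr, opt, rate, mu in itertools.product(local_lrs, optimizers, client_rates, mus):
            grid.append({
                "model": model, "algorithm": "fedprox", "local_lr": lr,
                "local_optimizer": opt, "client_rate": rate, "proximal_mu": mu,
            })
        for alg in ("fedadagrad", "fedadam", "fedyogi"):
            for lr, opt, rate, slr, tau in itertools.product(
                local_lrs, optimizers, client_rates, server_lrs, taus
            ):
                grid.append({
                    "model": model, "algorithm": alg, "local_lr": lr,
                    "local_optimizer": opt, "client_rate": rate,
                    "server_lr": slr, "tau": tau,
                })
    return grid


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auc_roc(scores, labels) -> float:
    """AUC-ROC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def score_similarity(scores_a, scores_b) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("score vectors must have equal length >= 3")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two AUC samples."""
    stat, p = stats.ranksums(a, b)
    return float(stat), float(p)


def early_stopping_controller(
    metric_history, patience: int = 20
) -> tuple[bool, int]:
    """Apply the stopping rule to a (chronological) metric history.

    Stops once the metric has failed to strictly improve on the running best
    for ``patience`` consecutive evaluations. Returns ``(stopped, best_round)``
    with 1-based best round index.
    """
    history = list(metric_history)
    if not history:
        raise ValueError("empty metric history")
    best = history[0]
    best_round = 1
    since = 0
    for r, m in enumerate(history[1:], start=2):
        if m > best:
            best, best_round, since = m, r, 0
        else:
            since += 1
            if since >= patience:
                return True, best_round
    return False, best_round


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeFoldPlan:
    """23 leave-one-chromosome-out folds (autosomes 1-22 plus X)."""

    folds: tuple[tuple[str, tuple[str, ...]], ...]
    empty_heldout: tuple[str, ...] = ()
    empty_train: tuple[str, ...] = ()


def plan_loco(matrix: FeatureMatrix) -> ChromosomeFoldPlan:
    """Plan the 23-fold leave-one-chromosome-out scheme for a matrix.

    Variants on a chromosome are scored only by the classifier trained on the
    remaining chromosomes, preventing positional leakage. Folds whose held-out
    or training side is empty are retained and flagged.
    """
    seen = set(map(str, matrix.chromosome))
    unknown = seen - set(CHROMOSOMES)
    if unknown:
        raise ValueError(f"unknown chromosome symbols: {sorted(unknown)}")
    folds = []
    empty_heldout, empty_train = [], []
    for chrom in CHROMOSOMES:
        train_set = tuple(c for c in CHROMOSOMES if c != chrom)
        folds.append((chrom, train_set))
        if chrom not in seen:
            empty_heldout.append(chrom)
        if not (seen - {chrom}):
            empty_train.append(chrom)
    return ChromosomeFoldPlan(tuple(folds), tuple(empty_heldout), tuple(empty_train))


@dataclass(frozen=True)
class CcvPlan:
    """Collaborative cross-validation: per-silo fold assignment vectors."""

    k: int
    assignments: dict[str, np.ndarray] = field(compare=False)
    seed: int = 0


def make_ccv_plan(silo_sizes: dict[str, int], k: int = 10, seed: int = 0) -> CcvPlan:
    """Assign each silo's records to k near-equal folds (sizes differ <= 1).

    The global validation fold f is the union of every silo's fold f, so no
    raw record leaves its institution to build the plan.
    """
    rng = np.random.default_rng(seed)
    assignments: dict[str, np.ndarray] = {}
    for silo, n in silo_sizes.items():
        if n < k:
            raise ValueError(f"silo {silo!r} has {n} records, fewer than k={k}")
        folds = np.tile(np.arange(k), int(np.ceil(n / k)))[:n]
        rng.shuffle(folds)
        assignments[silo] = folds
    return CcvPlan(k=k, assignments=assignments, seed=seed)


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentResult:
    """One AUC measurement with full provenance."""

    config_id: str
    mode: str  # "federated" | "centralized" | "local"
    seed: int
    test_set_id: str  # "cv" | "test1" | "test2"
    auc: float
    dropout_client: str | None = None
    partition_id: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"auc out of range: {self.auc}")


def _pool(clients: dict[str, tuple[np.ndarray, np.ndarray]]):
    X = np.vstack([clients[c][0] for c in clients])
    y = np.concatenate([clients[c][1] for c in clients])
    return X, y


def _fit(mode, clients, model, local_cfg, agg, seed):
    if mode == "federated":
        params, _ = run_federated_training(clients, model, local_cfg, agg, seed)
    elif mode == "centralized":
        X, y = _pool(clients)
        params, _ = run_centralized_training(
            X, y, model, local_cfg, seed, n_rounds=agg.n_rounds
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return params


def run_ccv(
    clients: dict[str, tuple[np.ndarray, np.ndarray]],
    model,
    local_cfg: LocalTrainConfig,
    agg: AggregatorConfig,
    plan: CcvPlan,
    seeds,
    mode: str = "federated",
    config_id: str = "ccv",
) -> list[ExperimentResult]:
    """k-fold collaborative cross-validation under a shared fold plan.

    The identical plan object must be passed when comparing centralized and
    federated modes, so both consume the same splits.
    """
    for silo, (X, _) in clients.items():
        if silo not in plan.assignments or len(plan.assignments[silo]) != len(X):
            raise ValueError(f"fold plan does not match silo {silo!r}")
    results = []
    for fold in range(plan.k):
        train_clients = {}
        val_X, val_y = [], []
        for silo, (X, y) in clients.items():
            is_val = plan.assignments[silo] == fold
            train_clients[silo] = (X[~is_val], y[~is_val])
            val_X.append(X[is_val])
            val_y.append(y[is_val])
        Xv = np.vstack(val_X)
        yv = np.concatenate(val_y)
        for seed in seeds:
            params = _fit(mode, train_clients, model, local_cfg, agg, seed)
            results.append(
                ExperimentResult(
                    config_id=f"{config_id}_fold{fold}",
                    mode=mode,
                    seed=int(seed),
                    test_set_id="cv",
                    auc=auc_roc(model.scores(params, Xv), yv),
                )
            )
    return results


def dropout_study(
    clients: dict[str, tuple[np.ndarray, np.ndarray]],
    model,
    local_cfg: LocalTrainConfig,
    agg: AggregatorConfig,
    seeds,
    test_X: np.ndarray,
    test_y: np.ndarray,
    modes=("federated", "centralized"),
    test_set_id: str = "test1",
) -> list[ExperimentResult]:
    """Train with all clients and with each client excluded in turn.

    K clients yield K+1 conditions per mode; the all-clients condition uses
    exactly the same code path and seeds as a standalone run.
    """
    if len(clients) < 2:
        raise ValueError("dropout study requires at least 2 clients")
    conditions: list[str | None] = [None] + list(clients.keys())
    results = []
    for mode in modes:
        for dropped in conditions:
            subset = {c: v for c, v in clients.items() if c != dropped}
            for seed in seeds:
                params = _fit(mode, subset, model, local_cfg, agg, seed)
                results.append(
                    ExperimentResult(
                        config_id="dropout",
                        mode=mode,
                        seed=int(seed),
                        test_set_id=test_set_id,
                        auc=auc_roc(model.scores(params, test_X), test_y),
                        dropout_client=dropped,
                    )
                )
    return results


@dataclass
class NullSummary:
    """IID-repartition null distribution of median AUCs plus the z-score."""

    null_medians: np.ndarray
    original_median: float
    z_score: float  # nan when the null is degenerate (sd = 0)
    p_value: float
    q1: float
    q3: float
    lower_bound: float  # Q1 - 1.5 IQR
    upper_bound: float  # Q3 + 1.5 IQR


def _repartition_rows(
    silo_id: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Random reassignment of row indices to silos, preserving silo sizes."""
    silos, counts = np.unique(silo_id, return_counts=True)
    order = rng.permutation(len(silo_id))
    out = {}
    pos = 0
    for s, n in zip(silos, counts):
        out[str(s)] = order[pos:pos + n]
        pos += n
    return out


def iid_null_experiment(
    train: FeatureMatrix,
    test: FeatureMatrix,
    model,
    local_cfg: LocalTrainConfig,
    agg: AggregatorConfig,
    n_partitions: int = 100,
    seeds=(0, 1, 2),
    seed: int = 0,
    fit_fn=None,
) -> NullSummary:
    """Compare the original silo partition against random IID repartitions.

    For the original grouping and for each of ``n_partitions`` random
    reassignments of training rows to silos of unchanged sizes, a federated
    model is trained per seed and the median test AUC recorded. The original
    median is z-scored against the null distribution; quartiles and 1.5 IQR
    bounds summarize the null as in an outlier box plot.

    ``fit_fn(clients, seed) -> ParameterVector`` replaces the federated
    training step when supplied (used to validate the null machinery against
    reference scorers).
    """
    silos = np.unique(train.silo_id)
    if len(silos) < 2:
        raise ValueError("IID-null experiment requires at least 2 silos")
    rng = np.random.default_rng(seed)

    def median_auc(groups: dict[str, np.ndarray]) -> float:
        clients = {s: (train.X[idx], train.y[idx]) for s, idx in groups.items()}
        aucs = []
        for sd in seeds:
            if fit_fn is not None:
                params = fit_fn(clients, int(sd))
            else:
                params, _ = run_federated_training(clients, model, local_cfg, agg, int(sd))
            aucs.append(auc_roc(model.scores(params, test.X), test.y))
        return float(np.median(aucs))

    original_groups = {
        str(s): np.flatnonzero(train.silo_id == s) for s in silos
    }
    original_median = median_auc(original_groups)
    null_medians = np.array([
        median_auc(_repartition_rows(train.silo_id, rng))
        for _ in range(n_partitions)
    ])
    sd = float(null_medians.std(ddof=1)) if len(null_medians) > 1 else 0.0
    if sd == 0.0:
        warnings.warn("degenerate IID null (sd = 0); z-score undefined")
        z = float("nan")
        p = float("nan")
    else:
        z = (original_median - float(null_medians.mean())) / sd
        p = float(2.0 * stats.norm.sf(abs(z)))
    q1, q3 = np.percentile(null_medians, [25, 75])
    iqr = q3 - q1
    return NullSummary(
        null_medians=null_medians,
        original_median=original_median,
        z_score=float(z),
        p_value=p,
        q1=float(q1),
        q3=float(q3),
        lower_bound=float(q1 - 1.5 * iqr),
        upper_bound=float(q3 + 1.5 * iqr),
    )
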