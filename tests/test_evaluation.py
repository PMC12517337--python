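"""Evaluation battery: fold plans, AUC, grid, dropout, IID-null machinery."""

import json

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from fedvar.cohorts import CHROMOSOMES
from fedvar.evaluation import (
    auc_roc,
    dropout_study,
    early_stopping_controller,
    enumerate_grid,
    iid_null_experiment,
    make_ccv_plan,
    plan_loco,
    run_ccv,
    score_similarity,
    wilcoxon_rank_sum,
)
from fedvar.federation import AggregatorConfig, run_federated_training
from fedvar.nn import MLP, MLPConfig
from fedvar.optim import LocalTrainConfig


from _oracles import brute_force_auc


class TestAucRoc:
    def test_perfect_ranking(self):
        assert auc_roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_roc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_hand_worked_example(self):
        # pairs: (.9>.8), (.9>.2), (.3<.8), (.3>.2) -> 3 of 4 concordant
        assert auc_roc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 201))
            scores = rng.choice([0.1, 0.25, 0.5, 0.8], size=n) + rng.normal(
                0, 0.01, n) * rng.integers(0, 2, n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auc_roc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn_reference(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=150)
        labels = rng.integers(0, 2, 150)
        labels[0], labels[1] = 0, 1
        assert auc_roc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_roc([0.1, 0.2], [1, 1])


class TestScoreSimilarity:
    def test_identical_ranking(self):
        rho, _ = score_similarity([0.1, 0.5, 0.9], [0.2, 0.6, 0.7])
        assert rho == pytest.approx(1.0)

    def test_reversed_ranking(self):
        rho, _ = score_similarity([0.1, 0.5, 0.9], [0.9, 0.5, 0.1])
        assert rho == pytest.approx(-1.0)

    def test_hand_worked_example(self):
        # rho = 1 - 6 * sum(d^2) / (n(n^2-1)) = 1 - 6*2/60 = 0.8
        rho, _ = score_similarity([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_similarity([1, 2], [1, 2, 3])

    def test_rank_sum_test_separates_distinct_samples(self):
        a = np.linspace(0.8, 0.9, 20)
        b = np.linspace(0.5, 0.6, 20)
        stat, p = wilcoxon_rank_sum(a, b)
        assert p < 1e-6 and stat > 0


class TestGrid:
    def test_fedprox_block_size_per_model(self):
        grid = enumerate_grid(models=("mlp",))
        fedprox = [g for g in grid if g["algorithm"] == "fedprox"]
        assert len(fedprox) == 96  # 4 lr x 2 opt x 2 rate x 6 mu

    def test_adaptive_block_size_per_model_per_algorithm(self):
        grid = enumerate_grid(models=("sndf",))
        adam = [g for g in grid if g["algorithm"] == "fedadam"]
        assert len(adam) == 192  # 4 lr x 2 opt x 2 rate x 4 server lr x 3 tau

    def test_total_settings(self):
        assert len(enumerate_grid()) == 1344

    def test_settings_are_unique(self):
        grid = enumerate_grid()
        keys = {json.dumps(g, sort_keys=True) for g in grid}
        assert len(keys) == len(grid)

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="client_rates"):
            enumerate_grid(client_rates=())


class TestEarlyStopping:
    def test_monotone_improvement_never_stops(self):
        stopped, best = early_stopping_controller(np.linspace(0, 1, 100), 20)
        assert not stopped and best == 100

    def test_constant_history_stops_after_patience(self):
        stopped, best = early_stopping_controller([0.7] * 21, 20)
        assert stopped and best == 1

    def test_peak_then_flat(self):
        history = [0.1, 0.2, 0.3, 0.4, 0.9] + [0.5] * 20
        stopped, best = early_stopping_controller(history, 20)
        assert stopped and best == 5

    def test_short_history_does_not_stop(self):
        stopped, best = early_stopping_controller([0.5, 0.4], 20)
        assert not stopped and best == 1


class TestLocoPlan:
    def test_23_folds_covering_all_chromosomes(self, small_iid_matrices):
        tr, _ = small_iid_matrices
        plan = plan_loco(tr)
        assert len(plan.folds) == 23
        assert {held for held, _ in plan.folds} == set(CHROMOSOMES)

    def test_heldout_chromosome_excluded_from_training_side(self, small_iid_matrices):
        tr, _ = small_iid_matrices
        plan = plan_loco(tr)
        for held, train_set in plan.folds:
            assert held not in train_set
            assert len(train_set) == 22
        # a chr2 variant is scored only by the fold that excludes chr2
        others = [t for h, t in plan.folds if h != "2"]
        assert all("2" in t for t in others)

    def test_single_chromosome_matrix_flagged(self, small_iid_matrices):
        tr, _ = small_iid_matrices
        sub = tr.subset(tr.chromosome == "1")
        plan = plan_loco(sub)
        assert "1" in plan.empty_train
        assert set(plan.empty_heldout) == set(CHROMOSOMES) - {"1"}

    def test_unknown_chromosome_rejected(self, small_iid_matrices):
        tr, _ = small_iid_matrices
        sub = tr.subset(tr.chromosome == "1")
        sub.chromosome[:] = "Y"
        with pytest.raises(ValueError, match="Y"):
            plan_loco(sub)


class TestCcv:
    def test_fold_sizes_near_equal_and_exhaustive(self):
        plan = make_ccv_plan({"a": 103, "b": 47}, k=10, seed=0)
        for silo, n in (("a", 103), ("b", 47)):
            counts = np.bincount(plan.assignments[silo], minlength=10)
            assert counts.sum() == n
            assert counts.max() - counts.min() <= 1

    def test_silo_smaller_than_k_named(self):
        with pytest.raises(ValueError, match="tiny"):
            make_ccv_plan({"a": 50, "tiny": 5}, k=10)

    def test_ccv_runs_and_is_deterministic(self, small_clients):
        model = MLP(MLPConfig(input_dim=60, n_hidden=3))
        lc = LocalTrainConfig(epochs=1)
        agg = AggregatorConfig(n_rounds=2)
        plan = make_ccv_plan({c: len(v[0]) for c, v in small_clients.items()},
                             k=3, seed=1)
        r1 = run_ccv(small_clients, model, lc, agg, plan, seeds=(0,), mode="federated")
        r2 = run_ccv(small_clients, model, lc, agg, plan, seeds=(0,), mode="federated")
        assert [r.auc for r in r1] == [r.auc for r in r2]
        assert len(r1) == 3  # one result per fold per seed

    def test_fed_and_cds_consume_identical_fold_manifests(self, small_clients):
        sizes = {c: len(v[0]) for c, v in small_clients.items()}
        plan_f = make_ccv_plan(sizes, k=5, seed=3)
        plan_c = make_ccv_plan(sizes, k=5, seed=3)
        manifest_f = json.dumps({s: a.tolist() for s, a in plan_f.assignments.items()},
                                sort_keys=True)
        manifest_c = json.dumps({s: a.tolist() for s, a in plan_c.assignments.items()},
                                sort_keys=True)
        assert manifest_f == manifest_c

    def test_plan_mismatch_rejected(self, small_clients):
        model = MLP(MLPConfig(input_dim=60, n_hidden=3))
        plan = make_ccv_plan({"zzz": 30}, k=3)
        with pytest.raises(ValueError):
            run_ccv(small_clients, model, LocalTrainConfig(),
                    AggregatorConfig(n_rounds=1), plan, seeds=(0,))


class TestDropout:
    def test_condition_count_and_identity_with_standalone_run(self, small_clients):
        model = MLP(MLPConfig(input_dim=60, n_hidden=3))
        lc = LocalTrainConfig(epochs=1)
        agg = AggregatorConfig(n_rounds=2)
        rng = np.random.default_rng(0)
        Xt = rng.normal(size=(40, 60))
        yt = np.r_[np.ones(20, int), np.zeros(20, int)]
        results = dropout_study(small_clients, model, lc, agg, seeds=(0,),
                                test_X=Xt, test_y=yt)
        # K clients -> K+1 conditions per mode
        k = len(small_clients)
        for mode in ("federated", "centralized"):
            sub = [r for r in results if r.mode == mode]
            assert len(sub) == k + 1
        # all-clients condition reproduces a standalone run exactly
        from fedvar.evaluation import auc_roc
        params, _ = run_federated_training(small_clients, model, lc, agg, seed=0)
        standalone = auc_roc(model.scores(params, Xt), yt)
        all_cond = [r for r in results
                    if r.mode == "federated" and r.dropout_client is None][0]
        assert all_cond.auc == standalone

    def test_requires_two_clients(self, small_clients):
        one = dict(list(small_clients.items())[:1])
        model = MLP(MLPConfig(input_dim=60, n_hidden=3))
        with pytest.raises(ValueError):
            dropout_study(one, model, LocalTrainConfig(), AggregatorConfig(),
                          (0,), np.zeros((2, 60)), np.array([0, 1]))


class TestIidNull:
    def test_partition_sizes_conserved(self):
        from fedvar.evaluation import _repartition_rows

        silo_id = np.array(["a"] * 7 + ["b"] * 3)
        rng = np.random.default_rng(0)
        for _ in range(20):
            groups = _repartition_rows(silo_id, rng)
            assert len(groups["a"]) == 7 and len(groups["b"]) == 3
            assert sorted(np.r_[groups["a"], groups["b"]].tolist()) == list(range(10))

    def test_data_independent_scorer_gives_degenerate_null(self, small_iid_matrices):
        """A scorer blind to the partition yields sd=0: z undefined + warning."""
        tr, t1 = small_iid_matrices
        model = MLP(MLPConfig(input_dim=60, n_hidden=3))
        fixed = model.init_params(0)
        with pytest.warns(UserWarning, match="degenerate"):
            s = iid_null_experiment(
                tr, t1, model, LocalTrainConfig(), AggregatorConfig(n_rounds=1),
                n_partitions=5, seeds=(0,), seed=0,
                fit_fn=lambda clients, seed: fixed)
        assert np.isnan(s.z_score)

    def test_partition_sensitive_reference_scorer_is_calibrated(self, small_iid_matrices):
        """With a scorer that varies with the partition but carries no silo
        effect, the original z stays small (|z| <= 3)."""
        tr, t1 = small_iid_matrices
        model = MLP(MLPConfig(input_dim=60, n_hidden=3))

        def noisy_fit(clients, seed):
            first = next(iter(sorted(clients)))
            token = int(np.abs(clients[first][0][0]).sum() * 1e6) % (2 ** 31)
            return model.init_params(token)

        s = iid_null_experiment(
            tr, t1, model, LocalTrainConfig(), AggregatorConfig(n_rounds=1),
            n_partitions=20, seeds=(0, 1, 2), seed=1, fit_fn=noisy_fit)
        assert abs(s.z_score) <= 3.0
        assert s.lower_bound <= s.q1 <= s.q3 <= s.upper_bound

    def test_requires_two_silos(self, small_iid_matrices):
        tr, t1 = small_iid_matrices
        sub = tr.subset(tr.silo_id == "a")
        model = MLP(MLPConfig(input_dim=60, n_hidden=3))
        with pytest.raises(ValueError):
            iid_null_experiment(sub, t1, model, LocalTrainConfig(),
                                AggregatorConfig())
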