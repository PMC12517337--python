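"""Federated loop: client sampling, aggregation, adaptive servers, equivalences."""

import numpy as np
import pytest

from fedvar.federation import (
    AggregatorConfig,
    ClientUpdate,
    FederationError,
    aggregate_weighted_mean,
    init_server_state,
    run_centralized_training,
    run_federated_training,
    sample_clients,
    server_update_adaptive,
)
from fedvar.nn import MLP, MLPConfig
from fedvar.optim import LocalTrainConfig
from fedvar.params import ParameterVector


def _pv(*values):
    v = np.asarray(values, dtype=float)
    return ParameterVector(v, (("w", (len(v),)),))


class TestSampleClients:
    def test_full_rate_selects_everyone(self):
        ids = [f"c{i}" for i in range(8)]
        rng = np.random.default_rng(0)
        assert sample_clients(ids, 1.0, rng) == ids

    def test_half_rate_selects_half(self):
        ids = [f"c{i}" for i in range(8)]
        sel = sample_clients(ids, 0.5, np.random.default_rng(1))
        assert len(sel) == 4 and set(sel) <= set(ids)

    def test_fractional_count_rounds_half_up(self):
        ids = [f"c{i}" for i in range(7)]
        assert len(sample_clients(ids, 0.5, np.random.default_rng(2))) == 4

    def test_floor_of_one_client(self):
        assert len(sample_clients(["only", "two"], 0.1, np.random.default_rng(3))) == 1

    def test_empty_registry_rejected(self):
        with pytest.raises(ValueError):
            sample_clients([], 1.0, np.random.default_rng(0))

    def test_deterministic_under_rng_state(self):
        ids = [f"c{i}" for i in range(10)]
        a = sample_clients(ids, 0.5, np.random.default_rng(7))
        b = sample_clients(ids, 0.5, np.random.default_rng(7))
        assert a == b


class TestWeightedMean:
    def test_two_client_example(self):
        updates = [ClientUpdate(_pv(1.0), 1), ClientUpdate(_pv(3.0), 3)]
        assert aggregate_weighted_mean(updates).values[0] == pytest.approx(2.5)

    def test_identical_updates_are_fixed_point(self):
        pv = _pv(0.3, -1.2, 4.0)
        updates = [ClientUpdate(pv, n) for n in (2, 5, 9)]
        assert np.allclose(aggregate_weighted_mean(updates).values, pv.values)

    def test_matches_explicit_loop_recomputation(self):
        rng = np.random.default_rng(4)
        updates = [ClientUpdate(_pv(*rng.normal(size=6)), int(n))
                   for n in rng.integers(1, 50, size=3)]
        got = aggregate_weighted_mean(updates).values
        total = sum(u.n_samples for u in updates)
        expected = np.zeros(6)
        for u in updates:
            for j in range(6):
                expected[j] += u.n_samples / total * u.params.values[j]
        assert np.allclose(got, expected)

    def test_layout_mismatch_rejected(self):
        a = ClientUpdate(_pv(1.0), 1)
        b = ClientUpdate(ParameterVector(np.zeros(2), (("w", (2,)),)), 1)
        with pytest.raises(ValueError):
            aggregate_weighted_mean([a, b])


class TestAdaptiveServer:
    """Hand-unrolled scalar oracles for the three adaptive recursions."""

    def _run(self, algorithm, deltas, eta=0.1, tau=1e-3, b1=0.9, b2=0.999):
        cfg = AggregatorConfig(algorithm=algorithm, server_lr=eta, tau=tau,
                               beta1=b1, beta2=b2)
        state = init_server_state(_pv(0.0), cfg)
        for d in deltas:
            update = ClientUpdate(_pv(state.global_params.values[0] + d), 1)
            state = server_update_adaptive(state, [update], cfg)
        return state

    @pytest.mark.parametrize("algorithm", ["fedadagrad", "fedadam", "fedyogi"])
    def test_three_step_recursion_matches_hand_unroll(self, algorithm):
        deltas = [0.5, -0.2, 0.3]
        eta, tau, b1, b2 = 0.1, 1e-3, 0.9, 0.999
        # independent oracle: explicit scalar recursion
        w, m, v = 0.0, 0.0, tau ** 2
        for d in deltas:
            if algorithm == "fedadagrad":
                m = d
                v = v + d * d
            elif algorithm == "fedadam":
                m = b1 * m + (1 - b1) * d
                v = b2 * v + (1 - b2) * d * d
            else:
                m = b1 * m + (1 - b1) * d
                v = v - (1 - b2) * d * d * np.sign(v - d * d)
            w = w + eta * m / (np.sqrt(v) + tau)
        state = self._run(algorithm, deltas, eta, tau, b1, b2)
        assert state.global_params.values[0] == pytest.approx(w, rel=1e-12)
        assert state.m[0] == pytest.approx(m, rel=1e-12)
        assert state.v[0] == pytest.approx(v, rel=1e-12)

    @pytest.mark.parametrize("algorithm", ["fedadagrad", "fedadam", "fedyogi"])
    def test_zero_delta_leaves_global_unchanged(self, algorithm):
        state = self._run(algorithm, [0.0])
        assert state.global_params.values[0] == 0.0

    def test_yogi_and_adam_first_step_nearly_coincide(self):
        """With v0 = tau^2 << delta^2 the two second-moment rules agree to
        O((1-beta2) * v0) on the first step."""
        d = 0.5
        adam = self._run("fedadam", [d])
        yogi = self._run("fedyogi", [d])
        assert yogi.v[0] - adam.v[0] == pytest.approx(0.001 * 1e-6, rel=1e-6)
        # v differs by (1-beta2)*v0 = 1e-9, i.e. ~4e-6 relative, which maps to
        # ~2e-6 relative in the step size
        assert yogi.global_params.values[0] == pytest.approx(
            adam.global_params.values[0], rel=1e-5)

    def test_nonfinite_delta_aborts_with_diagnostics(self):
        cfg = AggregatorConfig(algorithm="fedadam")
        state = init_server_state(_pv(0.0), cfg)
        update = ClientUpdate(_pv(np.inf), 1)
        with pytest.raises(FederationError, match="non-finite"):
            server_update_adaptive(state, [update], cfg)


class TestConfigValidation:
    def test_default_round_budget(self):
        assert AggregatorConfig().n_rounds == 200

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown aggregation algorithm"):
            AggregatorConfig(algorithm="fancyavg")

    def test_client_rate_bounds(self):
        with pytest.raises(ValueError):
            AggregatorConfig(client_rate=0.0)

    def test_mu_restricted_to_fedprox(self):
        with pytest.raises(ValueError):
            AggregatorConfig(algorithm="fedavg", proximal_mu=0.1)


class TestFederatedLoop:
    def test_fedprox_mu_zero_equals_fedavg(self, small_clients):
        model = MLP(MLPConfig(input_dim=60, n_hidden=4))
        lc = LocalTrainConfig(optimizer="sgd", learning_rate=0.01, epochs=2)
        pa, _ = run_federated_training(
            small_clients, model, lc,
            AggregatorConfig(algorithm="fedavg", n_rounds=4), seed=0)
        pp, _ = run_federated_training(
            small_clients, model, lc,
            AggregatorConfig(algorithm="fedprox", proximal_mu=0.0, n_rounds=4),
            seed=0)
        assert np.array_equal(pa.values, pp.values)

    def test_single_client_full_participation_equals_centralized(self, small_clients):
        cid = next(iter(small_clients))
        X, y = small_clients[cid]
        model = MLP(MLPConfig(input_dim=60, n_hidden=4))
        lc = LocalTrainConfig(optimizer="sgd", learning_rate=0.01, epochs=2)
        pf, _ = run_federated_training({cid: (X, y)}, model, lc,
                                       AggregatorConfig(n_rounds=5), seed=3)
        pc, _ = run_centralized_training(X, y, model, lc, seed=3, n_rounds=5)
        assert np.array_equal(pf.values, pc.values)

    def test_history_length_matches_round_budget(self, small_clients):
        model = MLP(MLPConfig(input_dim=60, n_hidden=3))
        lc = LocalTrainConfig(epochs=1)
        _, logs = run_federated_training(small_clients, model, lc,
                                         AggregatorConfig(n_rounds=6), seed=0)
        assert len(logs) == 6
        assert [l.round_index for l in logs] == list(range(1, 7))

    def test_early_stopping_on_flat_validation(self, small_clients):
        model = MLP(MLPConfig(input_dim=60, n_hidden=3))
        lc = LocalTrainConfig(epochs=1)
        _, logs = run_federated_training(
            small_clients, model, lc, AggregatorConfig(n_rounds=50), seed=0,
            validation=lambda p: 0.5, patience=3)
        assert len(logs) == 4  # round 1 sets the best; 3 flat rounds stop it

    def test_deterministic_under_seed(self, small_clients):
        model = MLP(MLPConfig(input_dim=60, n_hidden=3))
        lc = LocalTrainConfig(epochs=1)
        agg = AggregatorConfig(client_rate=0.5, n_rounds=4)
        a, _ = run_federated_training(small_clients, model, lc, agg, seed=11)
        b, _ = run_federated_training(small_clients, model, lc, agg, seed=11)
        assert np.array_equal(a.values, b.values)

    def test_client_failure_attributed(self, small_clients):
        clients = dict(small_clients)
        first = next(iter(clients))
        X, y = clients[first]
        clients["broken"] = (X[:0], y[:0])
        model = MLP(MLPConfig(input_dim=60, n_hidden=3))
        with pytest.raises(FederationError, match="broken"):
            run_federated_training(clients, model, LocalTrainConfig(epochs=1),
                                   AggregatorConfig(n_rounds=1), seed=0)

    def test_empty_registry_rejected(self):
        model = MLP(MLPConfig(input_dim=3, n_hidden=2))
        with pytest.raises(ValueError):
            run_federated_training({}, model, LocalTrainConfig(),
                                   AggregatorConfig(), seed=0)


class TestBatchNormPolicy:
    def _clients(self):
        rng = np.random.default_rng(0)
        return {
            c: (rng.normal(size=(40, 6)), rng.integers(0, 2, 40))
            for c in ("a", "b")
        }

    def test_keep_local_excludes_bn_from_exchange(self):
        model = MLP(MLPConfig(input_dim=6, n_hidden=4, use_batch_norm=True))
        init = model.init_params(5)
        lc = LocalTrainConfig(learning_rate=0.01, epochs=2)
        agg = AggregatorConfig(bn_policy="keep_local", n_rounds=3)
        params, _ = run_federated_training(self._clients(), model, lc, agg, seed=5)
        for name in sorted(model.bn_param_names):
            sl = params.segment_slice(name)
            assert np.array_equal(params.values[sl], init.values[sl]), name
        # the non-BN weights did train
        sl = params.segment_slice("W1")
        assert not np.array_equal(params.values[sl], init.values[sl])

    def test_aggregate_policy_moves_bn_statistics(self):
        model = MLP(MLPConfig(input_dim=6, n_hidden=4, use_batch_norm=True))
        init = model.init_params(5)
        lc = LocalTrainConfig(learning_rate=0.01, epochs=2)
        agg = AggregatorConfig(bn_policy="aggregate", n_rounds=3)
        params, _ = run_federated_training(self._clients(), model, lc, agg, seed=5)
        sl = params.segment_slice("bn_running_mean")
        assert not np.array_equal(params.values[sl], init.values[sl])
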