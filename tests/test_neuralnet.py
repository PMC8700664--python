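import math

import numpy as np
import pytest

from nirchem.neuralnet import (TRANSFER_CATALOG, AnnConfig, Network,
                               TrainingError, init_network, load_network,
                               network_mse, predict, save_network, transfer,
                               train_network, transfer_derivative)


def _closed_forms():
    return {
        "logsig": lambda x: 1.0 / (1.0 + math.exp(-x)),
        "tansig": math.tanh,
        "purelin": lambda x: x,
        "radbas": lambda x: math.exp(-x * x),
        "satlins": lambda x: max(-1.0, min(1.0, x)),
        "hardlim": lambda x: 1.0 if x >= 0 else 0.0,
        "tribas": lambda x: max(0.0, 1.0 - abs(x)),
        "netinv": lambda x: 1.0 / x if x != 0 else 1e12,
    }


class TestTransferFunctions:
    @pytest.mark.parametrize("name, x, expected", [
        ("logsig", 0.0, 0.5),
        ("radbas", 0.0, 1.0),
        ("tribas", 0.0, 1.0),
        ("tribas", 1.0, 0.0),
        ("satlins", 2.0, 1.0),
        ("hardlim", -0.1, 0.0),
        ("netinv", 2.0, 0.5),
        ("purelin", -3.5, -3.5),
    ])
    def test_point_values(self, name, x, expected):
        assert transfer(name, x) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("name", sorted(TRANSFER_CATALOG))
    def test_catalog_matches_closed_form_on_grid(self, name):
        xs = np.linspace(-5, 5, 101)
        got = transfer(name, xs)
        want = np.array([_closed_forms()[name](x) for x in xs])
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="catalog"):
            transfer("mystery", 0.0)

    def test_netinv_at_zero_guarded(self):
        v = transfer("netinv", 0.0)
        assert np.isfinite(v) and v > 0

    @pytest.mark.parametrize("name", ["logsig", "tansig", "radbas", "purelin"])
    def test_derivative_matches_finite_difference(self, name):
        xs = np.linspace(-3, 3, 41)
        h = 1e-6
        fd = (transfer(name, xs + h) - transfer(name, xs - h)) / (2 * h)
        np.testing.assert_allclose(transfer_derivative(name, xs), fd,
                                   atol=1e-6)


class TestAnnConfig:
    def test_lengths_must_match(self):
        with pytest.raises(ValueError):
            AnnConfig(2, (5,), ("logsig", "logsig"))

    def test_unknown_transfer(self):
        with pytest.raises(ValueError):
            AnnConfig(1, (5,), ("mystery",))

    def test_unknown_trainer(self):
        with pytest.raises(ValueError):
            AnnConfig(1, (5,), ("logsig",), train_method="trainlm")


class TestInitNetwork:
    def test_same_seed_identical(self):
        cfg = AnnConfig(2, (4, 3), ("logsig", "tansig"))
        a = init_network(cfg, 5, 1, seed=9)
        b = init_network(cfg, 5, 1, seed=9)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_different_seeds_differ(self):
        cfg = AnnConfig(1, (4,), ("logsig",))
        a = init_network(cfg, 5, 1, seed=1)
        b = init_network(cfg, 5, 1, seed=2)
        assert not np.array_equal(a.weights[0], b.weights[0])

    def test_three_layer_weight_shapes(self):
        cfg = AnnConfig(3, (16, 20, 7), ("satlins", "hardlim", "tribas"),
                        train_method="traincgb", learn_method="learnsom")
        net = init_network(cfg, 4, 1, seed=0)
        shapes = [w.shape for w in net.weights]
        assert shapes == [(4, 16), (16, 20), (20, 7), (7, 1)]


def _linear_data(n=40, p=3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1, 1, (n, p))
    w = np.array([1.5, -2.0, 0.5])
    y = X @ w + 0.3
    return X, y


class TestTraining:
    def test_zero_epochs_identity(self):
        X, y = _linear_data()
        cfg = AnnConfig(1, (4,), ("tansig",))
        net = init_network(cfg, 3, 1, seed=0)
        out, rec = train_network(net, X, y, max_epochs=0)
        assert out is net
        assert rec.train_mse == []

    def test_linear_target_traincgb(self):
        X, y = _linear_data()
        cfg = AnnConfig(1, (4,), ("purelin",), train_method="traincgb")
        net = init_network(cfg, 3, 1, seed=1)
        net, _ = train_network(net, X, y, max_epochs=500)
        assert network_mse(net, X, y) < 1e-3

    def test_xor_learnable_with_traingd(self):
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        y = np.array([0.0, 1, 1, 0])
        ok = False
        for seed in range(5):
            cfg = AnnConfig(1, (2,), ("logsig",), train_method="traingd")
            net = init_network(cfg, 2, 1, seed=seed)
            net, _ = train_network(net, X, y, max_epochs=5000, lr=0.5,
                                   patience=5000)
            if network_mse(net, X, y) < 0.05:
                ok = True
                break
        assert ok, "no seed reached train MSE < 0.05 on XOR"

    def test_trains_incremental_learns_linear(self):
        X, y = _linear_data()
        cfg = AnnConfig(1, (6,), ("tansig",), train_method="trains",
                        learn_method="learnh")
        net = init_network(cfg, 3, 1, seed=0)
        net, _ = train_network(net, X, y, max_epochs=100, seed=0)
        assert network_mse(net, X, y) < 0.05

    def test_traingd_small_lr_descends_on_linear_problem(self):
        X, y = _linear_data()
        cfg = AnnConfig(1, (3,), ("purelin",), train_method="traingd")
        net = init_network(cfg, 3, 1, seed=2)
        before, _ = train_network(net, X, y, max_epochs=0)
        mse0 = None
        stepped, rec = train_network(net, X, y, max_epochs=1, lr=1e-4,
                                     patience=10)
        # one tiny step never increases batch MSE on a quadratic surface
        n2, rec2 = train_network(net, X, y, max_epochs=2, lr=1e-4, patience=10)
        assert rec2.train_mse[1] <= rec2.train_mse[0] + 1e-12

    def test_seeded_training_bit_reproducible(self):
        X, y = _linear_data()
        cfg = AnnConfig(1, (5,), ("tansig",), train_method="trains")
        nets = []
        for _ in range(2):
            net = init_network(cfg, 3, 1, seed=3)
            net, _ = train_network(net, X, y, max_epochs=30, seed=3)
            nets.append(net)
        for wa, wb in zip(nets[0].weights, nets[1].weights):
            np.testing.assert_array_equal(wa, wb)

    def test_validation_early_stopping_runs(self):
        X, y = _linear_data(n=60)
        cfg = AnnConfig(1, (4,), ("tansig",), train_method="traincgb")
        net = init_network(cfg, 3, 1, seed=0)
        net, rec = train_network(net, X[:40], y[:40], val=(X[40:], y[40:]),
                                 max_epochs=400)
        assert rec.val_mse, "validation MSE must be recorded"
        assert rec.stop_reason in ("early_stop", "max_epochs", "converged",
                                   "line_search_failed")


class TestPredict:
    def test_memorizes_two_points(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([1.0, 3.0])
        cfg = AnnConfig(1, (4,), ("tansig",), train_method="traincgb")
        net = init_network(cfg, 2, 1, seed=0)
        net, _ = train_network(net, X, y, max_epochs=500)
        np.testing.assert_allclose(predict(net, X), y, atol=0.05)

    def test_deterministic(self):
        X, y = _linear_data()
        cfg = AnnConfig(1, (4,), ("logsig",))
        net = init_network(cfg, 3, 1, seed=0)
        net, _ = train_network(net, X, y, max_epochs=10)
        np.testing.assert_array_equal(predict(net, X), predict(net, X))

    def test_single_layer_purelin_closed_form(self):
        cfg = AnnConfig(1, (2,), ("purelin",))
        net = init_network(cfg, 2, 1, seed=0)
        # fix weights by hand; identity scaling
        net.weights = [np.array([[1.0, 0.0], [0.0, 1.0]]),
                       np.array([[2.0], [3.0]])]
        net.biases = [np.zeros(2), np.array([0.5])]
        net.x_min = np.array([-1.0, -1.0])
        net.x_max = np.array([1.0, 1.0])
        net.y_min, net.y_max = -1.0, 1.0
        x = np.array([[0.2, -0.4]])
        np.testing.assert_allclose(predict(net, x),
                                   [0.2 * 2 + (-0.4) * 3 + 0.5], atol=1e-12)

    def test_shape_mismatch(self):
        cfg = AnnConfig(1, (2,), ("purelin",))
        net = init_network(cfg, 3, 1, seed=0)
        with pytest.raises(ValueError):
            predict(net, np.zeros((2, 5)))


class TestNetworkMse:
    def test_perfect_predictions_zero(self):
        X, y = _linear_data()
        cfg = AnnConfig(1, (4,), ("purelin",), train_method="traincgb")
        net = init_network(cfg, 3, 1, seed=1)
        net, _ = train_network(net, X, y, max_epochs=500)
        assert network_mse(net, X, y) == pytest.approx(0.0, abs=1e-3)

    def test_matches_evaluate_mse(self):
        from nirchem.evaluate import metrics
        X, y = _linear_data()
        cfg = AnnConfig(1, (4,), ("tansig",))
        net = init_network(cfg, 3, 1, seed=0)
        net, _ = train_network(net, X, y, max_epochs=20)
        m = metrics(y, predict(net, X))
        assert network_mse(net, X, y) == pytest.approx(m.mse, rel=1e-12)


def test_save_load_round_trip(tmp_path):
    X, y = _linear_data()
    cfg = AnnConfig(2, (4, 3), ("radbas", "logsig"), train_method="trains")
    net = init_network(cfg, 3, 1, seed=5)
    net, _ = train_network(net, X, y, max_epochs=10, seed=5)
    path = tmp_path / "net.json"
    save_network(net, path)
    back = load_network(path)
    np.testing.assert_allclose(predict(back, X), predict(net, X), atol=1e-12)
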