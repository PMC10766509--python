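"""Maximum-likelihood committor: links, loss, training, transfer, gradients."""

import numpy as np
import pytest

import tpslearn as t
from tpslearn.committor import (ShootingRecord, TrainingSet, model_nll,
                                nll_from_counts, transfer_retrain_last_layer)


class TestLinks:
    def test_sigmoid_values_and_symmetry(self):
        assert t.sigmoid_link(0.0) == 0.5
        assert t.sigmoid_link(4.0) == pytest.approx(1 / (1 + np.exp(-4)), abs=1e-12)
        q = np.linspace(-30, 30, 13)
        np.testing.assert_allclose(t.sigmoid_link(-q), 1 - t.sigmoid_link(q), atol=1e-12)

    def test_sigmoid_overflow_safe(self):
        assert t.sigmoid_link(1000.0) == 1.0
        assert t.sigmoid_link(-1000.0) == 0.0

    def test_softmax_normalized_and_shift_invariant(self):
        q = np.array([1.3, -0.2, 0.8])
        p = t.softmax_link(q)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(t.softmax_link(q + 5.0), p, atol=1e-12)
        np.testing.assert_allclose(t.softmax_link(np.array([2.0, 2.0, 2.0])),
                                   np.ones(3) / 3, atol=1e-12)

    def test_two_state_softmax_equals_sigmoid(self):
        for q in (-3.0, -0.5, 0.0, 1.0, 4.0):
            p = t.softmax_link(np.array([q, 0.0]))
            # component 2 is the B-probability of the sigmoid parameterization
            assert p[1] == pytest.approx(float(t.sigmoid_link(-q)), abs=1e-12)
            assert t.softmax_link(np.array([0.0, 0.0]))[0] == 0.5


class TestLoss:
    def test_ignorance_value_k_log2(self):
        q = np.zeros(17)
        s = np.where(np.arange(17) % 2 == 0, 1.0, -1.0)
        assert t.shooting_nll(q, s) == pytest.approx(17 * np.log(2), rel=1e-12)

    def test_single_record_hand_value(self):
        # s = -1 (enters B), q = log 9 -> log(1 + e^{-log 9}) = log(10/9)
        assert t.shooting_nll(np.array([np.log(9)]), np.array([-1.0])) == \
            pytest.approx(np.log(10 / 9), rel=1e-12)

    def test_perfect_separation_limit(self):
        q = np.array([-50.0, 50.0])
        s = np.array([1.0, -1.0])
        assert t.shooting_nll(q, s) < 1e-20

    def test_counts_form_equals_per_record_form(self):
        rng = np.random.default_rng(0)
        q = rng.normal(size=6)
        nA = rng.integers(0, 5, size=6)
        nB = rng.integers(0, 5, size=6)
        per_record = t.shooting_nll(np.repeat(q, nA), np.ones(nA.sum())) + \
            t.shooting_nll(np.repeat(q, nB), -np.ones(nB.sum()))
        assert nll_from_counts(q, nA, nB) == pytest.approx(per_record, rel=1e-12)

    def test_empty_data_is_an_error(self):
        with pytest.raises(ValueError):
            t.shooting_nll(np.array([]), np.array([]))

    def test_training_set_unrolls_counts(self):
        ts = TrainingSet([ShootingRecord(np.array([0.1]), counts=(2, 1))])
        X, s = ts.to_arrays()
        assert X.shape == (3, 1) and list(s) == [1, 1, -1]
        with pytest.raises(ValueError):
            ShootingRecord(np.array([0.1]), outcome=1, counts=(1, 0))
        with pytest.raises(ValueError):
            ts.append(ShootingRecord(np.array([0.1, 0.2]), outcome=1))


class TestPyramid:
    def test_geometric_decay_factor(self):
        arch = t.build_pyramid(221, 5, 10, dropout0=0.1)
        f = (10 / 221) ** 0.25
        assert arch.dropouts[1] / arch.dropouts[0] == pytest.approx(f, rel=1e-12)
        assert arch.widths[0] == 221 and arch.widths[-1] == 10
        assert f == pytest.approx(0.4612, abs=2e-4)
        assert np.all(np.diff(arch.widths) < 0)

    def test_degenerate_and_zero_dropout(self):
        arch = t.build_pyramid(8, 3, 8, dropout0=0.0)
        assert arch.widths == (8, 8, 8)
        assert all(d == 0.0 for d in arch.dropouts)
        with pytest.raises(ValueError):
            t.build_pyramid(4, 2, 8)


class TestTraining:
    def test_separable_data_drives_loss_down(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 1))
        s = np.where(X[:, 0] > 0, -1.0, 1.0)  # perfectly separable
        model = t.NeuralCommittor(1, t.build_pyramid(8, 2, 4, 0.0), seed=0)
        trace = model.fit(X, s, epochs=200, learning_rate=1e-2, seed=0)
        assert model.nll(X, s) < 0.1 * 200 * np.log(2)
        assert trace[-1] < trace[0]

    def test_zero_learning_rate_leaves_weights(self):
        model = t.NeuralCommittor(1, t.build_pyramid(4, 2, 2, 0.0), seed=0)
        W0 = [w.copy() for w in model.W]
        model.fit(np.array([[0.5]]), np.array([1.0]), epochs=5, learning_rate=0.0)
        for a, b in zip(W0, model.W):
            np.testing.assert_array_equal(a, b)

    def test_same_seed_identical_weights(self, logistic_data):
        X, s, _ = logistic_data
        runs = []
        for _ in range(2):
            m = t.NeuralCommittor(1, t.build_pyramid(6, 2, 3, 0.2), seed=3)
            m.fit(X[:500], s[:500], epochs=30, seed=9)
            runs.append([w.copy() for w in m.W])
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)

    def test_recovers_planted_logistic_parameters(self, logistic_data):
        # linear special case: the loss is logistic regression; (a, b) within 10%
        X, s, manifest = logistic_data
        model = t.LinearCommittor(np.array([0.0]), 0.0)
        # fit by scipy for the linear model through the same loss surface
        from scipy.optimize import minimize

        def obj(w):
            return t.shooting_nll(X @ w[:1] + w[1], s)

        res = minimize(obj, np.zeros(2), method="BFGS")
        a, b = res.x
        assert a == pytest.approx(manifest["weights"][0], rel=0.1)
        assert b == pytest.approx(manifest["bias"], rel=0.1)

    def test_network_matches_analytic_committor(self, trained_toy_model, logistic_data):
        X, s, manifest = logistic_data
        grid = np.linspace(-0.5, 1.5, 9)[:, None]
        p_true = t.sigmoid_link(grid[:, 0] * manifest["weights"][0] + manifest["bias"])
        p_net = t.sigmoid_link(trained_toy_model.q(grid))
        assert np.max(np.abs(p_true - p_net)) < 0.05

    def test_label_flip_negates_the_fit(self, logistic_data):
        # unique-optimum (linear) case: the fitted q flips sign exactly
        X, s, _ = logistic_data
        from scipy.optimize import minimize

        def fit(labels):
            res = minimize(lambda w: t.shooting_nll(X @ w[:1] + w[1], labels),
                           np.zeros(2), method="BFGS")
            return res.x

        w_fwd, w_rev = fit(s), fit(-s)
        grid = np.linspace(-1, 2, 11)
        p_fwd = t.sigmoid_link(grid * w_fwd[0] + w_fwd[1])
        p_rev = t.sigmoid_link(grid * w_rev[0] + w_rev[1])
        np.testing.assert_allclose(p_fwd, 1 - p_rev, atol=1e-3)

    def test_non_finite_loss_aborts(self):
        model = t.NeuralCommittor(1, t.build_pyramid(4, 1, 4, 0.0), seed=0)
        model.W[-1][:] = np.nan
        with pytest.raises(FloatingPointError):
            model.train_epoch(np.array([[1.0]]), np.array([1.0]), 1e-3)


class TestTransfer:
    def test_frozen_layers_unchanged_and_self_transfer(self, trained_toy_model, logistic_data):
        X, s, _ = logistic_data
        base_loss = trained_toy_model.nll(X, s)
        new = transfer_retrain_last_layer(trained_toy_model, X, s,
                                          learning_rate=1e-2, patience=50, seed=0)
        for w_old, w_new in zip(trained_toy_model.W[:-1], new.W[:-1]):
            np.testing.assert_array_equal(w_old, w_new)
        # retraining on the same data lands within a few percent of the original
        assert new.nll(X, s) < 1.10 * base_loss

    def test_flipped_labels_flip_the_predictor(self, trained_toy_model, logistic_data):
        X, s, _ = logistic_data
        new = transfer_retrain_last_layer(trained_toy_model, X, -s,
                                          learning_rate=1e-2, patience=50, seed=0)
        grid = np.linspace(-0.5, 1.5, 9)[:, None]
        # monotone reversal: q changes sign where the original was confident
        q_old, q_new = trained_toy_model.q(grid), new.q(grid)
        assert np.corrcoef(q_old, q_new)[0, 1] < -0.95

    def test_width_mismatch_rejected(self, trained_toy_model):
        with pytest.raises(ValueError):
            transfer_retrain_last_layer(trained_toy_model, np.zeros((10, 3)),
                                        np.ones(10))


class TestGradientAttribution:
    def test_linear_model_matches_analytic(self):
        model = t.LinearCommittor(np.array([2.0, -3.0]), 0.5)
        pt = t.PhasePoint(np.array([0.3, -0.7]))
        mag = t.gradient_attribution(model, pt, lambda P: P)
        np.testing.assert_allclose(mag, [2.0, 3.0], atol=1e-6)

    def test_mass_scaling_halves_magnitude(self):
        model = t.LinearCommittor(np.array([2.0]), 0.0)
        m1 = t.gradient_attribution(model, t.PhasePoint(np.array([0.1])), lambda P: P)
        m2 = t.gradient_attribution(model, t.PhasePoint(np.array([0.1]),
                                                        masses=np.array([2.0])), lambda P: P)
        assert m2[0] == pytest.approx(m1[0] / 2, rel=1e-9)

    def test_dead_coordinate_has_zero_magnitude(self):
        model = t.LinearCommittor(np.array([1.5, 0.0]), 0.0)
        mag = t.gradient_attribution(model, t.PhasePoint(np.zeros(2)), lambda P: P)
        assert mag[1] == 0.0

    def test_network_gradient_matches_finite_difference(self, trained_toy_model):
        x = np.array([[0.4]])
        analytic = trained_toy_model.input_gradient(x)[0, 0]
        eps = 1e-6
        fd = (trained_toy_model.q(x + eps) - trained_toy_model.q(x - eps))[0] / (2 * eps)
        assert analytic == pytest.approx(fd, rel=1e-5)


def test_model_nll_helper(trained_toy_model, logistic_data):
    X, s, _ = logistic_data
    assert model_nll(trained_toy_model, X, s) == pytest.approx(
        t.shooting_nll(trained_toy_model.q(X), s))
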