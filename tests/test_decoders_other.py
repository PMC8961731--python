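"""Naive Bayes, Kalman filter, and LSTM decoders."""

import numpy as np
import pytest

from eegmanifold.decoders import (
    kf_decode,
    kf_filter,
    kf_fit,
    lstm_fit,
    lstm_predict,
    lstm_step,
    nb_fit,
    nb_predict,
    steady_state_gain,
)
from eegmanifold.decoders.kalman import KFModel
from eegmanifold.decoders.lstm import LSTMParams


class TestNaiveBayes:
    def test_midpoint_of_symmetric_classes_is_equivocal(self, rng):
        x = np.concatenate([rng.normal(-2, 1, 500), rng.normal(2, 1, 500)])
        y = np.repeat([0, 1], 500)
        model = nb_fit(x[:, None], y)
        # exact symmetry at the true midpoint of the fitted model
        mid = (model.means[0, 0] + model.means[1, 0]) / 2
        model.means[1, 0] = 2 * mid - model.means[0, 0]
        model.variances[1] = model.variances[0]
        post, _ = nb_predict(model, np.array([mid]))
        np.testing.assert_allclose(post, [0.5, 0.5], atol=1e-6)

    def test_posteriors_sum_to_one(self, rng):
        X = rng.standard_normal((100, 3))
        y = rng.integers(0, 4, 100)
        model = nb_fit(X, y)
        post, _ = nb_predict(model, rng.standard_normal((40, 3)))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_hand_worked_four_point_fixture(self):
        """Exact Bayes-rule computation on two classes of two 1-D points.

        Class a: {0, 2} -> mean 1, var 1.  Class b: {4, 8} -> mean 6, var 4.
        At u=2: p(u|a) = N(2;1,1), p(u|b) = N(2;6,4); equal priors.
        """
        X = np.array([[0.0], [2.0], [4.0], [8.0]])
        y = np.array(["a", "a", "b", "b"])
        model = nb_fit(X, y)
        like_a = np.exp(-0.5 * (2 - 1) ** 2 / 1) / np.sqrt(2 * np.pi * 1)
        like_b = np.exp(-0.5 * (2 - 6) ** 2 / 4) / np.sqrt(2 * np.pi * 4)
        expected = like_a / (like_a + like_b)
        post, label = nb_predict(model, np.array([2.0]))
        assert post[0] == pytest.approx(expected, abs=1e-12)
        assert label == "a"

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.naive_bayes import GaussianNB

        X = rng.standard_normal((200, 4))
        y = rng.integers(0, 3, 200)
        model = nb_fit(X, y, var_floor=1e-12)
        sk = GaussianNB(var_smoothing=0.0).fit(X, y)
        T = rng.standard_normal((50, 4))
        post, labels = nb_predict(model, T)
        np.testing.assert_allclose(post, sk.predict_proba(T), atol=1e-8)
        np.testing.assert_array_equal(labels, sk.predict(T))

    def test_zero_variance_feature_floored_not_fatal(self):
        X = np.array([[1.0, 0.0], [1.0, 0.1], [2.0, 5.0], [2.0, 5.1]])
        y = np.array([0, 0, 1, 1])
        model = nb_fit(X, y)
        post, _ = nb_predict(model, np.array([1.0, 0.05]))
        assert np.all(np.isfinite(post))

    def test_posterior_invariant_to_prior_rescaling(self, rng):
        X = rng.standard_normal((60, 2))
        y = rng.integers(0, 3, 60)
        model = nb_fit(X, y)
        scaled = nb_fit(X, y)
        scaled.priors = scaled.priors * 7.0  # unnormalized priors
        T = rng.standard_normal((10, 2))
        np.testing.assert_allclose(nb_predict(model, T)[0],
                                   nb_predict(scaled, T)[0], atol=1e-12)


class TestKalman:
    def test_noiseless_identity_system_tracks_observations(self):
        # noise-free observations (V << Q) drive the steady gain to identity
        J = 3
        eye = np.eye(J)
        model = KFModel(A=eye, H=eye, Q=1e-4 * eye, V=1e-12 * eye,
                        gain=None, classes=np.arange(J), n_init=1)
        model.gain = steady_state_gain(model.A, model.H, model.Q, model.V)
        rng = np.random.default_rng(0)
        seq = rng.standard_normal((20, J))
        traj = kf_filter(model, seq)
        np.testing.assert_allclose(traj, seq, atol=1e-6)

    def test_steady_gain_matches_dare_oracle(self, rng):
        """Independent oracle: the discrete algebraic Riccati equation
        solved by scipy gives the same stationary gain."""
        from scipy.linalg import solve_discrete_are

        A = np.array([[0.9, 0.1], [0.0, 0.8]])
        H = rng.standard_normal((2, 2))
        Q = np.diag([0.3, 0.5])
        V = np.diag([0.2, 0.4])
        gain = steady_state_gain(A, H, Q, V)
        P = solve_discrete_are(A.T, H.T, Q, V)
        expected = P @ H.T @ np.linalg.inv(H @ P @ H.T + V)
        np.testing.assert_allclose(gain, expected, atol=1e-8)

    def test_decodes_well_separated_sequences(self, rng):
        # class means away from the origin: a one-hot state with H e_c = 0
        # is unobservable, so the origin is a degenerate class position
        means = {0: np.array([-5.0, -5.0]), 1: np.array([6.0, 0.0]),
                 2: np.array([0.0, 6.0])}
        feats, labs, trials = [], [], []
        for t in range(30):
            lab = t % 3
            feats.append(means[lab] + 0.5 * rng.standard_normal((8, 2)))
            labs.extend([lab] * 8)
            trials.extend([t] * 8)
        X = np.concatenate(feats)
        model = kf_fit(X, np.array(labs), trial_ids=np.array(trials))
        correct = 0
        for t in range(30):
            idx = np.flatnonzero(np.array(trials) == t)
            _, lab = kf_decode(model, X[idx])
            correct += lab == t % 3
        assert correct / 30 >= 0.9

    def test_h_columns_are_class_means(self, rng):
        X, y = [], []
        for c, mu in enumerate([[1.0, 2.0], [3.0, -1.0]]):
            X.append(mu + 0.01 * rng.standard_normal((50, 2)))
            y.extend([c] * 50)
        model = kf_fit(np.concatenate(X), np.array(y))
        np.testing.assert_allclose(model.H[:, 0], [1.0, 2.0], atol=0.01)
        np.testing.assert_allclose(model.H[:, 1], [3.0, -1.0], atol=0.01)


class TestLSTM:
    def test_zero_parameters_closed_form(self):
        hidden = 4
        params = LSTMParams.init(2, hidden, np.random.default_rng(0))
        for name in params.fields():
            setattr(params, name, np.zeros_like(getattr(params, name)))
        c_prev = np.array([0.4, -0.2, 1.0, 0.0])
        h, c, gates = lstm_step(params, np.ones(2), np.zeros(hidden), c_prev)
        np.testing.assert_allclose(gates["f"], 0.5)
        np.testing.assert_allclose(gates["i"], 0.5)
        np.testing.assert_allclose(gates["o"], 0.5)
        np.testing.assert_allclose(c, 0.5 * c_prev, atol=1e-12)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c_prev), atol=1e-12)

    def test_gate_ranges_and_cell_bound(self, rng):
        params = LSTMParams.init(3, 8, rng)
        h0, c0 = rng.standard_normal(8), rng.standard_normal(8)
        h, c, gates = lstm_step(params, rng.standard_normal(3), h0, c0)
        for g in ("f", "i", "o"):
            assert np.all(gates[g] > 0) and np.all(gates[g] < 1)
        assert np.all(np.abs(c) <= np.abs(c0) + 1.0 + 1e-12)

    def test_hand_unrolled_single_unit_two_steps(self):
        """1-unit cell with scalar weights, unrolled by hand for two steps."""
        params = LSTMParams(
            Wfx=np.array([[0.5]]), Wfh=np.array([[0.1]]), bf=np.array([0.0]),
            Wix=np.array([[-0.3]]), Wih=np.array([[0.2]]), bi=np.array([0.1]),
            Wox=np.array([[0.7]]), Woh=np.array([[-0.1]]), bo=np.array([-0.2]),
            Wcx=np.array([[1.0]]), Wch=np.array([[0.4]]), bc=np.array([0.0]),
        )

        def sig(x):
            return 1 / (1 + np.exp(-x))

        h, c = 0.0, 0.0
        for u in (1.0, -0.5):
            f = sig(0.5 * u + 0.1 * h)
            i = sig(-0.3 * u + 0.2 * h + 0.1)
            o = sig(0.7 * u - 0.1 * h - 0.2)
            g = np.tanh(1.0 * u + 0.4 * h)
            c = f * c + i * g
            h = o * np.tanh(c)
        hh, cc = np.array([0.0]), np.array([0.0])
        for u in (1.0, -0.5):
            hh, cc, _ = lstm_step(params, np.array([u]), hh, cc)
            hh, cc = np.atleast_1d(hh), np.atleast_1d(cc)
        assert hh[0] == pytest.approx(h, abs=1e-12)
        assert cc[0] == pytest.approx(c, abs=1e-12)

    def test_learns_trivially_separable_sequences(self, rng):
        # constant +1 sequences vs alternating-sign sequences
        T = 6
        seq_a = np.ones((40, T, 1))
        seq_b = np.tile(np.resize([1.0, -1.0], T)[None, :, None], (40, 1, 1))
        X = np.concatenate([seq_a, seq_b]) + 0.05 * rng.standard_normal((80, T, 1))
        y = np.repeat([0, 1], 40)
        clf = lstm_fit(X, y, hidden_size=8, epochs=200, lr=0.5, seed=0)
        assert np.mean(lstm_predict(clf, X) == y) >= 0.95
        smoothed = np.convolve(clf.history["loss"], np.ones(20) / 20, mode="valid")
        assert smoothed[-1] < smoothed[0]

    def test_untrained_network_is_chance_level(self, rng):
        X = rng.standard_normal((300, 2))
        y = rng.integers(0, 3, 300)
        clf = lstm_fit(X, y, hidden_size=8, epochs=0, seed=1)
        acc = np.mean(lstm_predict(clf, X) == y)
        assert abs(acc - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / 300) + 0.05

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((60, 2))
        y = rng.integers(0, 2, 60)
        c1 = lstm_fit(X, y, epochs=30, seed=7)
        c2 = lstm_fit(X, y, epochs=30, seed=7)
        assert c1.history["final_loss"] == c2.history["final_loss"]

    def test_nan_input_rejected(self, rng):
        params = LSTMParams.init(2, 4, rng)
        with pytest.raises(ValueError):
            lstm_step(params, np.array([np.nan, 0.0]), np.zeros(4), np.zeros(4))
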