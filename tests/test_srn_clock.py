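import numpy as np
import pytest
from scipy import stats

from cpclock import (
    ErrorTrace,
    OscillatorBank,
    SRNConfig,
    SRNWeights,
    build_trajectory,
    dispersion_coefficient,
    error_trace,
    forward_step,
    free_run,
    init_srn,
    simulate_clock,
    tracked_run,
    train_srn,
)
from cpclock.oscillator_bank import TrajectoryDataset


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def reference_train(weights, X, Y, epochs, lr, mom, offset):
    """Independent slow re-statement of the learning rule.

    Vectorised numpy, written from the update equations directly: per-sample
    momentum backprop on squared error, sigmoid output, Fahlman offset added
    to both layers' sigmoid derivatives, context truncated (Elman).
    """
    A, R, U = weights.A.copy(), weights.R.copy(), weights.U.copy()
    bh, by = weights.hidden_bias.copy(), weights.output_bias.copy()
    dA = np.zeros_like(A)
    dR = np.zeros_like(R)
    dU = np.zeros_like(U)
    dbh = np.zeros_like(bh)
    dby = np.zeros_like(by)
    lam = (1.0 - mom) * lr
    for _ in range(epochs):
        h_prev = np.full(A.shape[0], 0.5)
        for t in range(X.shape[0]):
            x, target = X[t], Y[t]
            h = sigmoid(A @ x + R @ h_prev + bh)
            y = sigmoid(U @ h + by)
            delta_o = (y - target) * (y * (1 - y) + offset)
            delta_h = (U.T @ delta_o) * (h * (1 - h) + offset)
            dU = -lam * np.outer(delta_o, h) + mom * dU
            U = U + dU
            dby = -lam * delta_o + mom * dby
            by = by + dby
            dA = -lam * np.outer(delta_h, x) + mom * dA
            A = A + dA
            dR = -lam * np.outer(delta_h, h_prev) + mom * dR
            R = R + dR
            dbh = -lam * delta_h + mom * dbh
            bh = bh + dbh
            h_prev = h
    return SRNWeights(A=A, R=R, U=U, hidden_bias=bh, output_bias=by)


def toy_weights(n_h=2, n_in=2, seed=5):
    rng = np.random.default_rng(seed)
    return SRNWeights(
        A=rng.uniform(-0.5, 0.5, (n_h, n_in)),
        R=rng.uniform(-0.5, 0.5, (n_h, n_h)),
        U=rng.uniform(-0.5, 0.5, (n_in, n_h)),
        hidden_bias=rng.uniform(-0.5, 0.5, n_h),
        output_bias=rng.uniform(-0.5, 0.5, n_in),
    )


def toy_dataset(n_t=6, n_in=2, seed=9):
    rng = np.random.default_rng(seed)
    traj = rng.uniform(0.2, 0.8, (n_t + 1, n_in))
    return TrajectoryDataset(inputs=traj[:-1], targets=traj[1:], horizon_ms=n_t)


class TestInit:
    def test_seeded_determinism(self):
        cfg = SRNConfig(seed=42)
        w1, w2 = init_srn(cfg), init_srn(cfg)
        assert np.array_equal(w1.A, w2.A)
        assert np.array_equal(w1.R, w2.R)
        assert np.array_equal(w1.U, w2.U)

    def test_shapes_follow_hidden_size(self):
        w = init_srn(SRNConfig(hidden_size=16))
        assert w.A.shape == (16, 12)
        assert w.R.shape == (16, 16)
        assert w.U.shape == (12, 16)

    def test_uniform_moments(self):
        # mean of U(-0.5, 0.5) is 0, SD 1/sqrt(12); check to 3 standard errors
        w = init_srn(SRNConfig(hidden_size=200, seed=3))
        entries = np.concatenate([w.A.ravel(), w.R.ravel(), w.U.ravel()])
        se = (1 / np.sqrt(12)) / np.sqrt(entries.size)
        assert abs(entries.mean()) < 3 * se

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"hidden_size": 0},
            {"epochs": -1},
            {"fahlman_offset": -0.1},
            {"attention_horizon_ms": 0},
            {"output_activation": "relu"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SRNConfig(**kwargs)


class TestForwardStep:
    def zero_weights(self, n_h=4):
        return SRNWeights(
            A=np.zeros((n_h, 12)),
            R=np.zeros((n_h, n_h)),
            U=np.zeros((12, n_h)),
            hidden_bias=np.zeros(n_h),
            output_bias=np.zeros(12),
        )

    def test_zero_weights_sigmoid_fixed_point(self):
        h, y = forward_step(self.zero_weights(), np.full(12, 0.3), np.zeros(4))
        assert np.allclose(h, 0.5) and np.allclose(y, 0.5)

    def test_zero_weights_softmax_uniform(self):
        _, y = forward_step(
            self.zero_weights(), np.full(12, 0.3), np.zeros(4), "softmax"
        )
        np.testing.assert_allclose(y, 1.0 / 12.0)

    def test_single_hidden_unit_by_hand(self):
        # 1 input, 1 hidden unit, weights set by hand; pencil evaluation
        w = SRNWeights(
            A=np.array([[0.2]]),
            R=np.array([[0.3]]),
            U=np.array([[0.4]]),
            hidden_bias=np.array([0.1]),
            output_bias=np.array([-0.2]),
        )
        h, y = forward_step(w, np.array([0.6]), np.array([0.5]))
        h_hand = sigmoid(np.array([0.2 * 0.6 + 0.3 * 0.5 + 0.1]))
        y_hand = sigmoid(0.4 * h_hand - 0.2)
        np.testing.assert_allclose(h, h_hand, atol=1e-15)
        np.testing.assert_allclose(y, y_hand, atol=1e-15)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            forward_step(self.zero_weights(), np.zeros(5), np.zeros(4))


class TestTraining:
    def test_zero_epochs_leaves_weights_unchanged(self):
        w0 = toy_weights()
        data = toy_dataset()
        cfg = SRNConfig(hidden_size=2, epochs=0, attention_horizon_ms=len(data))
        w1, log = train_srn(w0, data, cfg)
        assert np.array_equal(w1.A, w0.A) and np.array_equal(w1.U, w0.U)
        assert log.size == 0

    @pytest.mark.parametrize("offset", [0.0, 0.1])
    @pytest.mark.parametrize("epochs", [1, 3])
    def test_matches_independent_reference_loop(self, offset, epochs):
        """Kernel equals a from-the-equations numpy reimplementation to 1e-10.

        offset=0 doubles as the check that the rule reduces to textbook
        sigmoid-derivative backprop when the Fahlman offset vanishes.
        """
        w0 = toy_weights()
        data = toy_dataset()
        cfg = SRNConfig(
            hidden_size=2,
            epochs=epochs,
            fahlman_offset=offset,
            attention_horizon_ms=len(data),
        )
        trained, _ = train_srn(w0, data, cfg)
        ref = reference_train(
            w0, data.inputs, data.targets, epochs, cfg.learning_rate, cfg.momentum, offset
        )
        for name in ("A", "R", "U", "hidden_bias", "output_bias"):
            np.testing.assert_allclose(
                getattr(trained, name), getattr(ref, name), atol=1e-10, rtol=0
            )

    def test_one_step_gradient_by_hand(self):
        """Single sample, single update, hand-derived scalar gradients."""
        w0 = SRNWeights(
            A=np.array([[0.1, -0.2], [0.3, 0.05]]),
            R=np.array([[0.0, 0.1], [-0.1, 0.2]]),
            U=np.array([[0.2, -0.3], [0.15, 0.25]]),
            hidden_bias=np.array([0.05, -0.05]),
            output_bias=np.array([0.1, -0.1]),
        )
        x = np.array([0.6, 0.4])
        target = np.array([0.55, 0.45])
        c, lr, mom = 0.07, 0.1, 0.9
        data = TrajectoryDataset(inputs=x[None, :], targets=target[None, :], horizon_ms=1)
        cfg = SRNConfig(
            hidden_size=2, epochs=1, fahlman_offset=c, attention_horizon_ms=1
        )
        trained, _ = train_srn(w0, data, cfg)
        # hand derivation: forward pass from the 0.5 context, then the
        # offset-augmented deltas; first step so momentum contributes nothing
        h_prev = np.full(2, 0.5)
        h = sigmoid(w0.A @ x + w0.R @ h_prev + w0.hidden_bias)
        y = sigmoid(w0.U @ h + w0.output_bias)
        delta_o = (y - target) * (y * (1 - y) + c)
        delta_h = (w0.U.T @ delta_o) * (h * (1 - h) + c)
        step = (1 - mom) * lr
        np.testing.assert_allclose(
            trained.U, w0.U - step * np.outer(delta_o, h), atol=1e-10, rtol=0
        )
        np.testing.assert_allclose(
            trained.A, w0.A - step * np.outer(delta_h, x), atol=1e-10, rtol=0
        )
        np.testing.assert_allclose(
            trained.R, w0.R - step * np.outer(delta_h, h_prev), atol=1e-10, rtol=0
        )

    def test_training_reduces_error_on_constant_target(self):
        n_t = 40
        X = np.tile(np.linspace(0.3, 0.7, 12), (n_t, 1))
        Y = np.full((n_t, 12), 0.4)
        data = TrajectoryDataset(inputs=X, targets=Y, horizon_ms=n_t)
        cfg = SRNConfig(hidden_size=4, epochs=50, attention_horizon_ms=n_t, seed=0)
        _, log = train_srn(init_srn(cfg), data, cfg)
        assert log[-1] < log[0]

    def test_empty_dataset_rejected(self):
        w0 = toy_weights()
        cfg = SRNConfig(hidden_size=2, epochs=1, attention_horizon_ms=5)
        with pytest.raises(ValueError):
            train_srn(w0, toy_dataset(n_t=3), cfg)


class TestTimingRuns:
    def zero_weight_net(self):
        return SRNWeights(
            A=np.zeros((3, 12)),
            R=np.zeros((3, 3)),
            U=np.zeros((12, 3)),
            hidden_bias=np.zeros(3),
            output_bias=np.zeros(12),
        )

    def test_free_run_length_one(self, bank):
        preds = free_run(self.zero_weight_net(), bank, 1)
        assert preds.shape == (1, 12)

    def test_free_run_zero_weights_sticks_at_half(self, bank):
        preds = free_run(self.zero_weight_net(), bank, 20)
        assert np.allclose(preds, 0.5)

    def test_invalid_duration_rejected(self, bank):
        with pytest.raises(ValueError):
            free_run(self.zero_weight_net(), bank, 0)
        with pytest.raises(ValueError):
            tracked_run(self.zero_weight_net(), bank, 0)

    def test_tracked_run_matches_forward_step_sequence(self, bank):
        w = toy_weights(n_h=3, n_in=12, seed=11)
        preds = tracked_run(w, bank, 30)
        h = np.full(3, 0.5)
        for t in range(30):
            h, y = forward_step(w, bank.state(t), h)
            np.testing.assert_allclose(preds[t], y, atol=1e-12)

    def test_free_run_feeds_back_own_predictions(self, bank):
        w = toy_weights(n_h=3, n_in=12, seed=11)
        preds = free_run(w, bank, 10)
        h = np.full(3, 0.5)
        x = bank.state(0)
        for t in range(10):
            h, y = forward_step(w, x, h)
            np.testing.assert_allclose(preds[t], y, atol=1e-12)
            x = y

    def test_seeded_end_to_end_reproducibility(self, bank, quick_config):
        _, trace_a, fit_a = simulate_clock(quick_config, bank)
        _, trace_b, fit_b = simulate_clock(quick_config, bank)
        assert np.array_equal(trace_a.per_ms_distance, trace_b.per_ms_distance)
        assert fit_a == fit_b


class TestErrorTrace:
    def test_perfect_predictions_give_zero_trace(self, bank):
        preds = bank.states(100)[1:]
        trace = error_trace(preds, bank)
        assert np.all(trace.per_ms_distance == 0)
        assert np.all(trace.cumulative_mean == 0)

    def test_uniform_offset_distance_closed_form(self, bank):
        preds = np.clip(bank.states(200)[1:] + 0.1, 0, 1.1)
        trace = error_trace(preds, bank)
        np.testing.assert_allclose(trace.per_ms_distance, 0.1 * np.sqrt(12), atol=1e-9)
        np.testing.assert_allclose(trace.cumulative_mean, 0.1 * np.sqrt(12), atol=1e-9)

    def test_constant_distance_flat_running_mean(self):
        d = np.full(50, 0.37)
        trace = ErrorTrace(per_ms_distance=d, cumulative_mean=np.cumsum(d) / np.arange(1, 51))
        np.testing.assert_allclose(trace.cumulative_mean, 0.37, atol=1e-12)
        np.testing.assert_allclose(trace.cumulative, 0.37 * np.arange(1, 51), atol=1e-9)


class TestDispersion:
    def make_trace(self, d):
        d = np.asarray(d, dtype=float)
        return ErrorTrace(
            per_ms_distance=d, cumulative_mean=np.cumsum(d) / np.arange(1, d.size + 1)
        )

    def test_constant_distance_slope_and_perfect_fit(self):
        # Euclidean distance 0.25 each ms -> per-oscillator error 0.25/sqrt(12)
        fit = dispersion_coefficient(self.make_trace(np.full(100, 0.25)))
        assert fit.slope == pytest.approx(0.25 / np.sqrt(12), abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_running_mean_r2_defined_as_zero(self):
        fit = dispersion_coefficient(
            self.make_trace(np.zeros(10)), basis="running-mean"
        )
        assert fit.slope == 0.0 and fit.r_squared == 0.0

    def test_exact_line_recovered_on_running_mean_basis(self):
        # build distances whose running mean is exactly 0.01 + 0.0002 * t
        t = np.arange(1, 301, dtype=float)
        cm = 0.01 + 0.0002 * t
        totals = cm * t
        d = np.diff(np.concatenate([[0.0], totals]))
        fit = dispersion_coefficient(self.make_trace(d), basis="running-mean")
        assert fit.slope == pytest.approx(0.0002, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_line_slope_within_two_se(self, rng):
        t = np.arange(1, 2001, dtype=float)
        noise = rng.normal(0, 0.02, t.size)
        d = 0.2 + np.diff(np.concatenate([[0.0], noise]))  # cumsum = 0.2t + noise
        assert np.all(d >= 0)
        fit = dispersion_coefficient(self.make_trace(d))
        r12 = np.sqrt(12)
        se = (0.02 / r12) / np.sqrt(np.sum((t - t.mean()) ** 2))
        assert fit.slope == pytest.approx(0.2 / r12, abs=2 * se + 1e-6)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            dispersion_coefficient(self.make_trace([0.1]))

    def test_ols_matches_closed_form_normal_equations(self, rng):
        d = rng.uniform(0.05, 0.4, 500)
        trace = self.make_trace(d)
        fit = dispersion_coefficient(trace)
        t = trace.t_ms.astype(float)
        y = np.cumsum(trace.per_ms_rms)
        slope = ((t - t.mean()) * (y - y.mean())).sum() / ((t - t.mean()) ** 2).sum()
        intercept = y.mean() - slope * t.mean()
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)


class TestTrainedClockBehaviour:
    def test_error_accumulates_with_elapsed_time(self, bank, quick_config):
        """Cumulative error grows steadily and near-linearly over the run."""
        _, trace, fit = simulate_clock(quick_config, bank)
        rho = stats.spearmanr(trace.cumulative, trace.t_ms).statistic
        assert rho > 0.9
        assert fit.r_squared >= 0.98
        assert fit.slope > 0

    def test_attention_limited_clock_degrades_late(self, bank, quick_config):
        """Beyond the studied horizon the one-step error grows: the late
        window of the timed interval is noisier than the early one."""
        _, trace, _ = simulate_clock(quick_config, bank)
        horizon = quick_config.attention_horizon_ms
        early = trace.per_ms_distance[:horizon].mean()
        late = trace.per_ms_distance[horizon:].mean()
        assert late > early
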