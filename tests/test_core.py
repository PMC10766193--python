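import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from dynattractor import ModelParams, NetworkState, RateHistory
from dynattractor import core


class TestTransfer:
    def test_midpoint(self, params):
        assert core.transfer(0.3, 0.3, params) == pytest.approx(0.5)

    def test_resting_leak(self, params):
        # h=0 against the base threshold: 1 / (1 + e^15)
        assert core.transfer(0.0, 0.15, params) == pytest.approx(
            1.0 / (1.0 + np.exp(15.0)))

    def test_saturation_and_overflow_guard(self, params):
        assert core.transfer(1e6, 0.15, params) == pytest.approx(1.0)
        assert core.transfer(-1e6, 0.15, params) == pytest.approx(0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(h=st.floats(-2, 2), dh=st.floats(1e-4, 1.0),
           th=st.floats(-1, 2))
    def test_monotone_in_drive_and_threshold(self, h, dh, th):
        p = ModelParams()
        lo, hi = core.transfer(h, th, p), core.transfer(h + dh, th, p)
        assert hi >= lo
        assert core.transfer(h, th + dh, p) <= core.transfer(h, th, p)
        # mathematically open range (0, r_max); saturation to the closed
        # endpoints is float rounding
        assert 0.0 <= hi <= p.r_max


class TestNormalizers:
    def test_synaptic_norm_hand_value(self, params):
        row = np.full(10, 0.3)
        row[0] = 0.0  # self-connection
        assert core.synaptic_norm(row, params) == pytest.approx(1 / 3.7)

    def test_weights_at_threshold_do_not_contribute(self, params):
        row = np.full(5, params.w_thr)
        assert core.synaptic_norm(row, params) == 1.0

    def test_synaptic_norm_disabled(self, params):
        p = params.replace(alpha_w=0.0)
        assert core.synaptic_norm(np.full(9, 0.3), p) == 1.0

    def test_divisive_norm_hand_value(self, params):
        r = np.zeros(100)
        r[:10] = 1.0
        s = core.divisive_norm(r, params)
        # an inactive neuron sees all 10 active ones
        assert s[50] == pytest.approx(1 / 1.02)
        # an active neuron excludes itself
        assert s[0] == pytest.approx(1 / (1 + 2 * 0.001 * 9))

    def test_divisive_norm_trivial_cases(self, params):
        assert np.all(core.divisive_norm(np.zeros(100), params) == 1.0)
        p = params.replace(alpha_r=0.0)
        assert np.all(core.divisive_norm(np.ones(100), p) == 1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_normalizers_bounded_in_unit_interval(self, seed):
        p = ModelParams(N=20)
        rng = np.random.default_rng(seed)
        W = rng.uniform(p.w_min, p.w_max, (20, 20))
        np.fill_diagonal(W, 0.0)
        r = rng.normal(0, 0.1, 20)
        sw = core.synaptic_norm(W, p)
        sr = core.divisive_norm(r, p)
        assert np.all((sw > 0) & (sw <= 1))
        assert np.all((sr > 0) & (sr <= 1))


class TestInputField:
    def test_zero_network(self, params):
        N = params.N
        h = core.input_field(np.zeros((N, N)), np.zeros(N), np.zeros(N), params)
        np.testing.assert_array_equal(h, np.zeros(N))

    def test_reduces_to_plain_field_without_normalization(self, params):
        p = params.replace(alpha_w=0.0, alpha_r=0.0)
        rng = np.random.default_rng(0)
        W = rng.uniform(p.w_min, p.w_max, (p.N, p.N))
        np.fill_diagonal(W, 0.0)
        r = rng.uniform(0, 1, p.N)
        I = rng.uniform(0, 1, p.N)
        np.testing.assert_array_equal(core.input_field(W, r, I, p), W @ r + I)

    def test_single_strong_pair_hand_value(self, params):
        # one strong recurrent input plus direct external drive:
        # h_1 = S_W * S_R * w12 * r2 + I1 with S_W = 1/1.3, S_R = 1/1.002
        N = params.N
        W = np.zeros((N, N))
        W[0, 1] = 0.3
        r = np.zeros(N)
        r[1] = 1.0
        I = np.zeros(N)
        I[0] = 1.0
        h = core.input_field(W, r, I, params)
        expected = (1 / 1.3) * (1 / 1.002) * 0.3 + 1.0
        assert h[0] == pytest.approx(expected)
        assert expected == pytest.approx(1.230308, abs=1e-6)

    def test_shape_mismatch_rejected(self, params):
        with pytest.raises(ValueError, match="shape"):
            core.input_field(np.zeros((3, 3)), np.zeros(3), np.zeros(4),
                             ModelParams(N=3, gamma=0.5))


class TestRateDynamics:
    def test_full_relaxation_in_one_step_at_dt_equal_tau(self, params):
        r = np.array([0.2, 0.8])
        h = np.array([1.0, -1.0])
        theta = np.array([0.15, 0.15])
        out = core.step_rates(r, h, theta, None, params)
        np.testing.assert_allclose(
            out, params.r0 + core.transfer(h, theta, params), atol=1e-15)

    def test_noiseless_fixed_point_matches_self_consistency_oracle(self):
        # gentle sigmoid so the Euler map is a smooth contraction
        p = ModelParams(N=10, gamma=0.5, b=4.0, C=0.0, alpha_w=0.0, dt=0.5)
        I0 = 0.5

        def residual(r):
            # all neurons identical: S_R sees N-1 others at rate r
            sr = 1.0 / (1.0 + p.alpha_r * (p.gamma / p.N) * (p.N - 1) * r)
            h = sr * 0.0 + I0  # W = 0
            theta = p.theta0 + p.D_theta * r
            return p.r0 + core.transfer(h, theta, p) - r

        r_star = brentq(residual, 0.0, 1.0)
        state = NetworkState.rest(p)
        I = np.full(p.N, I0)
        for _ in range(500):
            core.step(state, I, p, None, learn=False)  # W stays 0
        np.testing.assert_allclose(state.r, r_star, atol=1e-8)

    def test_stationary_noise_variance_matches_ar1_oracle(self):
        # low drive keeps the sigmoid silent, leaving a pure AR(1) process:
        # r_{k+1} = (1-a) r_k + C sqrt(a) xi, a = dt/tau_r
        p = ModelParams(N=200, dt=0.5, alpha_w=0.0, alpha_r=0.0)
        a = p.dt / p.tau_r
        expected_var = (p.C ** 2) * p.sigma ** 2 * a / (1 - (1 - a) ** 2)
        rng = np.random.default_rng(7)
        state = NetworkState.rest(p)
        I = np.zeros(p.N)
        samples = []
        for k in range(4000):
            core.step(state, I, p, rng.standard_normal(p.N), learn=False)
            if k > 200:
                samples.append(state.r.copy())
        var = np.var(np.concatenate(samples))
        assert var == pytest.approx(expected_var, rel=0.05)


class TestThresholdDynamics:
    def test_relaxes_to_base_without_firing(self, params):
        theta = np.full(3, 0.9)
        for _ in range(300):
            theta = core.step_thresholds(theta, np.zeros(3), params)
        np.testing.assert_allclose(theta, params.theta0, atol=1e-8)

    def test_fixed_point_under_saturated_firing(self, params):
        theta = np.full(3, params.theta0)
        for _ in range(300):
            theta = core.step_thresholds(theta, np.ones(3), params)
        np.testing.assert_allclose(theta, 1.15, atol=1e-8)

    def test_euler_tracks_exponential_solution(self):
        p = ModelParams(dt=0.01)
        r_const = 0.6
        theta = np.array([p.theta0])
        for _ in range(700):  # 7 a.u. = one time constant
            theta = core.step_thresholds(theta, np.array([r_const]), p)
        target = p.theta0 + p.D_theta * r_const
        exact = target - (target - p.theta0) * np.exp(-7.0 / p.tau_theta)
        assert theta[0] == pytest.approx(exact, abs=1e-3)


class TestRateHistory:
    def test_mean_over_partial_and_full_buffer(self):
        hist = RateHistory(4, 2)
        with pytest.raises(ValueError):
            hist.mean()
        np.testing.assert_array_equal(
            hist.mean(default=np.array([1.0, 2.0])), [1.0, 2.0])
        for k in range(6):
            hist.push(np.full(2, float(k)))
        # window now holds 2,3,4,5
        np.testing.assert_allclose(hist.mean(), 3.5)

    def test_box_filter_ramp_response(self):
        hist = RateHistory(15, 1)
        for _ in range(15):
            hist.push(np.zeros(1))
        means = []
        for _ in range(15):
            hist.push(np.ones(1))
            means.append(hist.mean()[0])
        np.testing.assert_allclose(means, np.arange(1, 16) / 15)

    def test_center_sample(self):
        hist = RateHistory(15, 1)
        for k in range(20):
            hist.push(np.array([float(k)]))
        # newest is 19, full window 5..19, centre is 7 back
        assert hist.center()[0] == 12.0

    def test_incremental_sum_stays_exact_over_long_runs(self):
        hist = RateHistory(15, 3)
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(10_000, 3))
        for v in vals:
            hist.push(v)
        np.testing.assert_allclose(hist.mean(), vals[-15:].mean(axis=0),
                                   atol=1e-12)


class TestWeightDynamics:
    def test_pure_decay_matches_closed_form(self, params):
        rng = np.random.default_rng(0)
        W0 = rng.uniform(params.w_min, params.w_max, (30, 30))
        np.fill_diagonal(W0, 0.0)
        W = W0.copy()
        r = np.full(30, 0.4)
        n = 5000
        for _ in range(n):
            W = core.step_weights(W, r, r, params)  # zero Hebbian term
        expected = W0 * np.exp(-params.beta * n * params.dt / params.tau_w)
        np.testing.assert_allclose(W - np.diag(np.diag(W)),
                                   expected - np.diag(np.diag(expected)),
                                   rtol=1e-4)

    def test_coactive_pair_grows_to_ceiling(self, params):
        W = np.zeros((2, 2))
        r = np.ones(2)
        r_avg = np.zeros(2)
        for _ in range(100):
            W = core.step_weights(W, r, r_avg, params)
        assert W[0, 1] == params.w_max
        assert W[1, 0] == params.w_max
        assert W[0, 0] == 0.0

    def test_hard_bounds_and_zero_diagonal_after_noisy_run(self):
        p = ModelParams(N=30, gamma=0.2)
        rng = np.random.default_rng(11)
        state = NetworkState.rest(p)
        I = np.zeros(p.N)
        for k in range(3000):
            I[:] = 0.0
            if (k // 30) % 2 == 0 and k % 30 < 5:
                I[:6] = 1.0
            core.step(state, I, p, rng.standard_normal(p.N))
        assert np.all(state.W <= p.w_max + 1e-15)
        assert np.all(state.W >= p.w_min - 1e-15)
        np.testing.assert_array_equal(np.diag(state.W), 0.0)

    def test_constant_rate_epoch_gives_exactly_zero_hebbian_increment(self):
        p = ModelParams(N=10, gamma=0.5, C=0.0, beta=0.0, b=4.0)
        state = NetworkState.rest(p)
        I = np.full(p.N, 0.5)
        for _ in range(200):  # converge and fill the averaging window
            core.step(state, I, p, None)
        W_ref = state.W.copy()
        for _ in range(100):
            core.step(state, I, p, None)
        np.testing.assert_allclose(state.W, W_ref, atol=1e-12)


class TestStep:
    def test_rest_is_a_fixed_point_without_noise(self, params):
        p = params.replace(C=0.0)
        state = NetworkState.rest(p)
        I = np.zeros(p.N)
        for _ in range(50):
            core.step(state, I, p, None)
        # the sigmoid leaks ~3e-7 at rest; theta stays pinned near theta0
        np.testing.assert_allclose(state.r, 0.0, atol=1e-5)
        np.testing.assert_allclose(state.theta, p.theta0, atol=1e-5)
        np.testing.assert_allclose(state.W, 0.0, atol=1e-8)

    def test_step_equals_hand_composed_sub_operations(self, small_params):
        p = small_params
        rng = np.random.default_rng(5)
        state = NetworkState.rest(p)
        # scramble the state a bit first
        I = np.zeros(p.N)
        I[:2] = 1.0
        for _ in range(20):
            core.step(state, I, p, rng.standard_normal(p.N))

        manual = state.copy()
        noise = np.random.default_rng(99).standard_normal(p.N)

        h = core.input_field(manual.W, manual.r, I, p)
        r_new = core.step_rates(manual.r, h, manual.theta, noise, p)
        theta_new = core.step_thresholds(manual.theta, manual.r, p)
        manual.history.push(r_new)
        W_new = core.step_weights(manual.W, manual.history.center(),
                                  manual.history.mean(), p)

        core.step(state, I, p, noise)
        np.testing.assert_array_equal(state.r, r_new)
        np.testing.assert_array_equal(state.theta, theta_new)
        np.testing.assert_array_equal(state.W, W_new)

    def test_non_finite_state_aborts_with_diagnostic(self, small_params):
        state = NetworkState.rest(small_params)
        state.r[0] = np.nan
        with pytest.raises(FloatingPointError, match="non-finite"):
            core.step(state, np.zeros(small_params.N), small_params, None)
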