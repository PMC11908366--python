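"""Forward kernels, Gaussian posterior, and the few-step reverse sampler."""

import numpy as np
import pytest

import shiftsr as s
from shiftsr.diffusion import (
    DiffusionState,
    PairedSlice,
    forward_marginal,
    forward_step,
    posterior_params,
    reverse_sample,
)


def gaussian_product_moments(mu1, var1, mu2, var2, n_grid=20001):
    """Numeric product of two 1-D Gaussian densities on a fine grid.

    Independent oracle for the posterior: normalize the pointwise product
    and read off mean and variance by quadrature.
    """
    lo = min(mu1 - 8 * np.sqrt(var1), mu2 - 8 * np.sqrt(var2))
    hi = max(mu1 + 8 * np.sqrt(var1), mu2 + 8 * np.sqrt(var2))
    x = np.linspace(lo, hi, n_grid)
    logp = -0.5 * ((x - mu1) ** 2 / var1 + (x - mu2) ** 2 / var2)
    p = np.exp(logp - logp.max())
    p /= np.trapezoid(p, x)
    mean = np.trapezoid(x * p, x)
    var = np.trapezoid((x - mean) ** 2 * p, x)
    return mean, var


class TestPairedSlice:
    def test_residual_recomputed_not_trusted(self):
        hr = np.ones((4, 4))
        lr = np.full((4, 4), 1.5)
        pair = PairedSlice(hr=hr, lr=lr)
        np.testing.assert_array_equal(pair.e0, lr - hr)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PairedSlice(hr=np.zeros((4, 4)), lr=np.zeros((4, 5)))
        with pytest.raises(ValueError):
            PairedSlice(hr=np.zeros((4, 4)), lr=np.zeros((4, 4)), mask=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            PairedSlice(hr=np.zeros(4), lr=np.zeros(4))


class TestForwardKernels:
    def test_step_is_identity_for_degenerate_pair_without_noise(self, default_schedule):
        x = np.random.default_rng(0).random((8, 8))
        state = forward_step(DiffusionState(x=x, t=0), np.zeros((8, 8)),
                             default_schedule, noise=np.zeros((8, 8)))
        np.testing.assert_array_equal(state.x, x)
        assert state.t == 1

    def test_deterministic_drift_is_alpha_times_residual(self, default_schedule, small_pair):
        for t in (1, 7, 15):
            prev = DiffusionState(x=small_pair.hr.copy(), t=t - 1)
            state = forward_step(prev, small_pair.e0, default_schedule,
                                 noise=np.zeros(small_pair.shape))
            np.testing.assert_allclose(
                state.x - prev.x, default_schedule.alpha(t) * small_pair.e0, rtol=0, atol=1e-15
            )

    def test_step_noise_variance_matches_law(self, default_schedule):
        # per-pixel sample variance of x_t - x_{t-1} ~ gamma^2 * alpha_t
        t, n = 5, 20000
        rng = np.random.default_rng(42)
        e0 = np.zeros((n, 8, 8))
        prev = DiffusionState(x=np.zeros((n, 8, 8)), t=t - 1)
        state = forward_step(prev, e0, default_schedule, rng=rng)
        var = (state.x - prev.x).var(axis=0)
        expected = default_schedule.gamma**2 * default_schedule.alpha(t)
        se = expected * np.sqrt(2.0 / (n - 1))
        assert np.all(np.abs(var - expected) < 4 * se)

    def test_marginal_mean_and_terminal_behavior(self, default_schedule, small_pair):
        zero = np.zeros(small_pair.shape)
        for t in (1, 8, 15):
            state = forward_marginal(small_pair, t, default_schedule, noise=zero)
            expect = small_pair.hr + default_schedule.beta(t) * small_pair.e0
            np.testing.assert_allclose(state.x, expect, atol=1e-14)
        # at t=T with beta_T ~ 1 the mean is essentially the LR image
        terminal = forward_marginal(small_pair, 15, default_schedule, noise=zero)
        assert np.abs(terminal.x - small_pair.lr).max() < 1e-3

    def test_degenerate_pair_marginal_is_noise_around_hr(self, default_schedule):
        hr = np.full((8, 8), 0.3)
        pair = PairedSlice(hr=hr, lr=hr.copy())
        rng = np.random.default_rng(1)
        draws = np.stack([
            forward_marginal(pair, 7, default_schedule, rng=rng).x for _ in range(5000)
        ])
        expected_var = default_schedule.gamma**2 * default_schedule.beta(7)
        assert np.abs(draws.mean() - 0.3) < 0.05
        assert abs(draws.var() / expected_var - 1.0) < 0.05

    def test_out_of_range_times_rejected(self, default_schedule, small_pair):
        with pytest.raises(IndexError):
            forward_marginal(small_pair, 0, default_schedule)
        with pytest.raises(IndexError):
            forward_marginal(small_pair, 16, default_schedule)
        with pytest.raises(IndexError):
            forward_step(DiffusionState(x=small_pair.hr, t=15), small_pair.e0,
                         default_schedule)
        with pytest.raises(ValueError):
            forward_step(DiffusionState(x=small_pair.hr, t=0), np.zeros((2, 2)),
                         default_schedule)


class TestPosterior:
    def test_final_transition_collapses_onto_estimate(self, default_schedule):
        x_t = np.random.default_rng(2).random((6, 6))
        x0 = np.random.default_rng(3).random((6, 6))
        mean, var = posterior_params(x_t, x0, 1, 0, default_schedule)
        np.testing.assert_array_equal(mean, x0)
        assert var == 0.0

    def test_constant_inputs_give_constant_mean(self, default_schedule):
        c = np.full((5, 5), 0.7)
        for t_hi, t_lo in [(15, 14), (15, 10), (8, 3), (2, 0)]:
            mean, _ = posterior_params(c, c, t_hi, t_lo, default_schedule)
            np.testing.assert_allclose(mean, 0.7, rtol=1e-14)

    def test_adjacent_posterior_matches_grid_product_oracle(self, default_schedule):
        rng = np.random.default_rng(7)
        sched = default_schedule
        for _ in range(50):
            t = int(rng.integers(2, 16))
            hr, lr, x_t = rng.normal(0.5, 0.5, size=3)
            e0 = lr - hr
            # factor 1: x_t = x_{t-1} + alpha_t e0 + noise, as a density in x_{t-1}
            mu1 = x_t - sched.alpha(t) * e0
            var1 = sched.gamma**2 * sched.alpha(t)
            # factor 2: marginal of x_{t-1} around hr
            mu2 = hr + sched.beta(t - 1) * e0
            var2 = sched.gamma**2 * sched.beta(t - 1)
            om, ov = gaussian_product_moments(mu1, var1, mu2, var2)
            mean, var = posterior_params(
                np.array([[x_t]]), np.array([[hr]]), t, t - 1, sched
            )
            assert abs(mean[0, 0] - om) < 1e-6
            assert abs(var - ov) < 1e-6

    def test_invalid_level_order_rejected(self, default_schedule):
        x = np.zeros((3, 3))
        with pytest.raises(IndexError):
            posterior_params(x, x, 3, 3, default_schedule)
        with pytest.raises(IndexError):
            posterior_params(x, x, 3, 5, default_schedule)
        with pytest.raises(IndexError):
            posterior_params(x, x, 16, 14, default_schedule)


class TestReverseSample:
    @pytest.mark.parametrize("n_steps", [1, 4, 15])
    @pytest.mark.parametrize("seed", [0, 1234])
    def test_oracle_denoiser_recovers_hr_exactly(self, default_schedule, small_pair,
                                                 n_steps, seed):
        steps = s.select_sampling_timesteps(default_schedule, n_steps)
        out = reverse_sample(small_pair.lr, lambda x, lr, t: small_pair.hr,
                             default_schedule, steps, rng_seed=seed)
        np.testing.assert_allclose(out, small_pair.hr, atol=1e-12)

    def test_degenerate_pair_oracle_still_exact(self, default_schedule):
        hr = np.random.default_rng(5).random((16, 16))
        pair = PairedSlice(hr=hr, lr=hr.copy())
        out = reverse_sample(pair.lr, lambda x, lr, t: hr, default_schedule,
                             rng_seed=9)
        np.testing.assert_allclose(out, hr, atol=1e-12)

    def test_single_step_is_one_denoiser_collapse(self, default_schedule, small_pair):
        calls = []

        def denoiser(x_t, lr, t):
            calls.append((x_t.copy(), t))
            return 0.5 * x_t  # arbitrary deterministic map

        out = reverse_sample(small_pair.lr, denoiser, default_schedule, steps=[15],
                            rng_seed=4)
        assert len(calls) == 1 and calls[0][1] == 15
        np.testing.assert_allclose(out, 0.5 * calls[0][0], atol=1e-14)

    def test_seed_determinism_and_stochasticity(self, default_schedule, small_pair):
        steps = s.select_sampling_timesteps(default_schedule, 4)
        # denoiser must depend on x_t, otherwise the final collapse onto the
        # estimate erases all injected noise
        den = lambda x, lr, t: 0.5 * (x + lr)
        a = reverse_sample(small_pair.lr, den, default_schedule, steps, rng_seed=10)
        b = reverse_sample(small_pair.lr, den, default_schedule, steps, rng_seed=10)
        c = reverse_sample(small_pair.lr, den, default_schedule, steps, rng_seed=11)
        np.testing.assert_array_equal(a, b)
        assert np.abs(a - c).max() > 0
        assert np.abs(a - c).max() < 5 * default_schedule.gamma

    def test_transition_count_matches_subsequence_length(self, default_schedule,
                                                         small_pair):
        for n_steps in (1, 4, 15):
            steps = s.select_sampling_timesteps(default_schedule, n_steps)
            _, traj = reverse_sample(small_pair.lr, lambda x, lr, t: lr,
                                     default_schedule, steps, rng_seed=0,
                                     return_trajectory=True)
            assert len(traj) == n_steps + 1  # initial state + one per transition
            assert traj[0].t == 15 and traj[-1].t == 0

    def test_bad_subsequence_and_denoiser_shape_rejected(self, default_schedule,
                                                         small_pair):
        with pytest.raises(ValueError):
            reverse_sample(small_pair.lr, lambda x, lr, t: lr, default_schedule,
                           steps=[1, 4])  # does not end at T
        with pytest.raises(ValueError):
            reverse_sample(small_pair.lr, lambda x, lr, t: lr, default_schedule,
                           steps=[4, 4, 15])
        with pytest.raises(ValueError):
            reverse_sample(small_pair.lr, lambda x, lr, t: np.zeros((2, 2)),
                           default_schedule)


def test_forward_composition_matches_marginal_moments(default_schedule):
    """Composing the stepwise kernel matches the closed-form marginal
    (Monte-Carlo moment check; the full 1e5-draw version runs in the
    acceptance suite)."""
    sched = default_schedule
    rng = np.random.default_rng(123)
    n = 20000
    hr = np.linspace(0, 1, 16).reshape(4, 4)
    lr = np.roll(hr, 1, axis=0)
    pair = PairedSlice(hr=hr, lr=lr)
    t_target = 9
    x = np.broadcast_to(hr, (n, 4, 4)).copy()
    state = DiffusionState(x=x, t=0)
    e0 = np.broadcast_to(pair.e0, (n, 4, 4))
    for _ in range(t_target):
        state = forward_step(state, e0, sched, rng=rng)
    mean_mc = state.x.mean(axis=0)
    var_mc = state.x.var(axis=0)
    mean_true = hr + sched.beta(t_target) * pair.e0
    var_true = sched.gamma**2 * sched.beta(t_target)
    se_mean = np.sqrt(var_true / n)
    se_var = var_true * np.sqrt(2.0 / (n - 1))
    assert np.all(np.abs(mean_mc - mean_true) < 4 * se_mean)
    assert np.all(np.abs(var_mc - var_true) < 4 * se_var)
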