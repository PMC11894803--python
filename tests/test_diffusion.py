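"""Noise-schedule arithmetic, forward-marginal law, and the DDIM/ODE bridge."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gembridge.diffusion import (
    NoiseSchedule,
    ancestral_sample,
    ddim_step,
    loss_simple,
    make_schedule,
    ode_decode,
    ode_encode,
    ode_timestep_grid,
    predict_x0,
    q_sample,
)


class TestSchedule:
    def test_two_step_product_arithmetic(self):
        sch = make_schedule(T=2, beta_min=0.1, beta_max=0.2)
        np.testing.assert_allclose(sch.alpha_bar, [0.9, 0.72])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=2, max_value=500),
        st.floats(min_value=1e-5, max_value=0.01),
        st.floats(min_value=0.02, max_value=0.5),
    )
    def test_alpha_bar_strictly_decreasing(self, T, bmin, bmax):
        sch = make_schedule(T=T, beta_min=bmin, beta_max=bmax)
        assert np.all(np.diff(sch.alpha_bar) < 0)
        assert 0 < sch.alpha_bar[-1] < sch.alpha_bar[0] < 1

    def test_default_schedule_terminal_coefficient_tiny(self):
        sch = make_schedule()  # T=1000, beta 1e-4..0.02
        assert sch.alpha_bar[-1] < 1e-4

    def test_cosine_schedule_valid(self):
        sch = make_schedule(T=100, kind="cosine")
        assert np.all(np.diff(sch.alpha_bar) < 0)

    def test_abar_boundary_convention(self):
        sch = make_schedule(T=10, beta_min=0.01, beta_max=0.1)
        assert sch.abar(0) == 1.0
        with pytest.raises(ValueError):
            sch.abar(11)

    def test_invalid_beta_range(self):
        with pytest.raises(ValueError):
            make_schedule(T=10, beta_min=0.2, beta_max=0.1)

    def test_dict_round_trip(self):
        sch = make_schedule(T=50, beta_min=1e-3, beta_max=0.1)
        back = NoiseSchedule.from_dict(sch.to_dict())
        np.testing.assert_allclose(back.alpha_bar, sch.alpha_bar)


class TestQSample:
    def make(self):
        # schedule with abar exactly 0.25 at step 2 for hand arithmetic
        betas = np.array([0.5, 0.5])
        return NoiseSchedule(T=2, betas=betas, alpha_bar=np.cumprod(1 - betas))

    def test_hand_value(self):
        sch = self.make()
        x = q_sample(np.array([[1.0]]), [2], np.array([[1.0]]), sch)
        assert x[0, 0] == pytest.approx(0.5 + np.sqrt(0.75), abs=1e-12)

    def test_zero_noise_scales_signal(self):
        sch = self.make()
        x = q_sample(np.array([[2.0]]), [1], np.zeros((1, 1)), sch)
        assert x[0, 0] == pytest.approx(2.0 * np.sqrt(0.5))

    def test_t_out_of_range(self):
        with pytest.raises(ValueError):
            q_sample(np.zeros((1, 1)), [3], np.zeros((1, 1)), self.make())

    def test_forward_marginal_moments_match_theory(self):
        """Mean/variance of 1e5 draws at fixed t agree within 3 MC standard errors."""
        sch = make_schedule(T=100, beta_min=1e-3, beta_max=0.2)
        rng = np.random.default_rng(0)
        n = 100_000
        x0 = 0.6
        t = 37
        eps = rng.standard_normal((n, 1))
        draws = q_sample(np.full((n, 1), x0), np.full(n, t), eps, sch)
        ab = sch.abar(t)
        mu_th, var_th = np.sqrt(ab) * x0, 1 - ab
        se_mu = np.sqrt(var_th / n)
        se_var = var_th * np.sqrt(2.0 / (n - 1))
        assert abs(draws.mean() - mu_th) < 3 * se_mu
        assert abs(draws.var() - var_th) < 3 * se_var


class TestLossAndInversion:
    sch = make_schedule(T=50, beta_min=1e-3, beta_max=0.2)

    def batch(self, n=64, g=8, seed=0):
        rng = np.random.default_rng(seed)
        return {
            "x0": rng.uniform(-1, 1, size=(n, g)),
            "t": rng.integers(1, 51, size=n),
            "eps": rng.standard_normal((n, g)),
            "condition": rng.integers(0, 2, size=n),
        }

    def test_perfect_denoiser_zero_loss(self):
        b = self.batch()
        oracle = lambda x, t, c: b["eps"]
        assert loss_simple(oracle, b, self.sch) == pytest.approx(0.0, abs=1e-15)

    def test_zero_denoiser_unit_loss_in_expectation(self):
        b = self.batch(n=20000, g=4, seed=1)
        zero = lambda x, t, c: np.zeros_like(x)
        # E||eps||^2 / dim = 1; MC standard error ~ sqrt(2/(n*g))
        assert loss_simple(zero, b, self.sch) == pytest.approx(1.0, abs=0.05)

    def test_predict_x0_inverts_q_sample_to_1e9(self):
        rng = np.random.default_rng(2)
        x0 = rng.uniform(-1, 1, size=(32, 6))
        t = rng.integers(1, 51, size=32)
        eps = rng.standard_normal((32, 6))
        x_t = q_sample(x0, t, eps, self.sch)
        np.testing.assert_allclose(predict_x0(x_t, eps, t, self.sch), x0, atol=1e-9)

    def test_predict_x0_with_zero_eps_estimate(self):
        x_t = np.array([[1.0]])
        out = predict_x0(x_t, np.zeros((1, 1)), [10], self.sch)
        assert out[0, 0] == pytest.approx(1.0 / np.sqrt(self.sch.abar(10)))


class TestDdimStep:
    sch = make_schedule(T=50, beta_min=1e-3, beta_max=0.2)

    def test_sigma_zero_with_true_eps_lands_on_forward_marginal(self):
        """With the true eps the deterministic step reproduces the exact
        forward-marginal point at t_prev (same noise direction)."""
        rng = np.random.default_rng(4)
        x0 = rng.uniform(-1, 1, size=(16, 5))
        eps = rng.standard_normal((16, 5))
        t = np.full(16, 40)
        t_prev = np.full(16, 17)
        x_t = q_sample(x0, t, eps, self.sch)
        stepped = ddim_step(x_t, eps, t, t_prev, 0.0, self.sch)
        np.testing.assert_allclose(stepped, q_sample(x0, t_prev, eps, self.sch), atol=1e-9)

    def test_step_to_zero_returns_x0(self):
        rng = np.random.default_rng(5)
        x0 = rng.uniform(-1, 1, size=(4, 3))
        eps = rng.standard_normal((4, 3))
        t = np.full(4, 12)
        x_t = q_sample(x0, t, eps, self.sch)
        out = ddim_step(x_t, eps, t, np.zeros(4, dtype=int), 0.0, self.sch)
        np.testing.assert_allclose(out, x0, atol=1e-9)

    def test_deterministic_and_validates_arguments(self):
        rng = np.random.default_rng(6)
        x_t = rng.normal(size=(3, 2))
        eps = rng.normal(size=(3, 2))
        a = ddim_step(x_t, eps, [30] * 3, [10] * 3, 0.0, self.sch)
        b = ddim_step(x_t, eps, [30] * 3, [10] * 3, 0.0, self.sch)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError, match="t_prev"):
            ddim_step(x_t, eps, [10] * 3, [30] * 3, 0.0, self.sch)
        with pytest.raises(ValueError, match="sigma"):
            ddim_step(x_t, eps, [30] * 3, [1] * 3, 5.0, self.sch)


class StubDenoiser:
    """eps_hat = 0 everywhere: the ODE then scales rows by sqrt(abar) exactly."""

    def __call__(self, x, t, cond):
        return np.zeros_like(x)


class TestOdeBridge:
    sch = make_schedule(T=100, beta_min=1e-3, beta_max=0.2)

    def test_grid_bounds_and_errors(self):
        grid = ode_timestep_grid(self.sch, 10)
        assert grid[0] == 0 and grid[-1] == 100
        assert np.all(np.diff(grid) > 0)
        with pytest.raises(ValueError):
            ode_timestep_grid(self.sch, 101)

    def test_zero_eps_stub_gives_exact_sqrt_abar_scaling(self):
        rng = np.random.default_rng(7)
        x0 = rng.uniform(-1, 1, size=(6, 4))
        latent = ode_encode(StubDenoiser(), x0, 0, self.sch, n_ode_steps=25)
        np.testing.assert_allclose(
            latent.values, np.sqrt(self.sch.abar(100)) * x0, atol=1e-12
        )

    def test_stub_cycle_consistency_is_exact(self):
        rng = np.random.default_rng(8)
        x0 = rng.uniform(-0.9, 0.9, size=(6, 4))
        latent = ode_encode(StubDenoiser(), x0, 0, self.sch, n_ode_steps=25)
        back = ode_decode(StubDenoiser(), latent, 0, self.sch)
        np.testing.assert_allclose(back, x0, atol=1e-9)

    def test_encode_decode_deterministic_and_shape_preserving(self):
        rng = np.random.default_rng(9)
        x0 = rng.uniform(-1, 1, size=(5, 3))
        l1 = ode_encode(StubDenoiser(), x0, 1, self.sch, n_ode_steps=20)
        l2 = ode_encode(StubDenoiser(), x0, 1, self.sch, n_ode_steps=20)
        np.testing.assert_array_equal(l1.values, l2.values)
        assert l1.values.shape == x0.shape


def test_ancestral_sample_contract_with_stub():
    sch = make_schedule(T=20, beta_min=1e-3, beta_max=0.3)
    a = ancestral_sample(StubDenoiser(), 7, 0, 5, sch, seed=3)
    b = ancestral_sample(StubDenoiser(), 7, 0, 5, sch, seed=3)
    assert a.shape == (7, 5)
    np.testing.assert_array_equal(a, b)
    assert np.all(a >= -1) and np.all(a <= 1)
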