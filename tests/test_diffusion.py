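import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icodiff.diffusion import (
    NoisePrediction,
    cosine_schedule,
    p_sample_step,
    partial_reconstruct,
    q_sample,
    sample_chain,
    training_loss,
    v_target,
    x0_eps_from_v,
)


@pytest.fixture(scope="module")
def sched():
    return cosine_schedule(100)


class TestCosineSchedule:
    def test_normalization_and_monotonicity(self):
        s = cosine_schedule(1000)
        assert s.alpha_bar(0) == 1.0
        assert np.all(np.diff(s.alpha_bars) < 0)
        assert s.alpha_bars[-1] < 1e-3

    def test_beta_range_and_posterior_bound(self):
        s = cosine_schedule(1000)
        assert np.all(s.betas > 0) and np.all(s.betas <= 0.999)
        assert np.all(s.posterior_vars <= s.betas + 1e-12)

    def test_alpha_bar_is_product_of_clipped_alphas(self):
        s = cosine_schedule(50)
        assert np.allclose(s.alpha_bars, np.cumprod(1.0 - s.betas), atol=1e-14)

    def test_rejects_bad_T(self):
        with pytest.raises(ValueError):
            cosine_schedule(0)


class TestForwardProcess:
    def test_no_noise_gives_scaled_signal(self, sched, rng):
        x0 = rng.standard_normal((2, 12, 1))
        out = q_sample(x0, 10, np.zeros_like(x0), sched)
        assert np.allclose(out, np.sqrt(sched.alpha_bars[9]) * x0)

    def test_early_step_close_to_signal(self, sched, rng):
        x0 = rng.standard_normal((2, 12, 1))
        eps = rng.standard_normal(x0.shape)
        assert np.allclose(q_sample(x0, 1, eps, sched), x0, atol=0.2)

    def test_marginal_variance_matches_closed_form(self, sched, rng):
        t = sched.T // 2
        eps = rng.standard_normal((10_000, 1, 1))
        xt = q_sample(np.zeros((10_000, 1, 1)), t, eps, sched)
        target = 1.0 - sched.alpha_bars[t - 1]
        se = target * np.sqrt(2.0 / (10_000 - 1))
        assert abs(xt.var(ddof=1) - target) < 3 * se

    def test_rejects_out_of_range_t(self, sched):
        x = np.zeros((1, 4, 1))
        with pytest.raises(ValueError):
            q_sample(x, 0, x, sched)
        with pytest.raises(ValueError):
            q_sample(x, sched.T + 1, x, sched)


class TestVParameterization:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(1, 100), st.integers(0, 2**31 - 1))
    def test_roundtrip_is_exact(self, t, seed):
        sched = cosine_schedule(100)
        rng = np.random.default_rng(seed)
        x0 = rng.standard_normal((2, 12, 2))
        eps = rng.standard_normal(x0.shape)
        xt = q_sample(x0, t, eps, sched)
        v = v_target(x0, eps, t, sched)
        x0h, epsh = x0_eps_from_v(xt, v, t, sched)
        assert np.abs(x0h - x0).max() < 1e-10
        assert np.abs(epsh - eps).max() < 1e-10
        # forward consistency of the recovered pair
        assert np.abs(q_sample(x0h, t, epsh, sched) - xt).max() < 1e-10

    def test_limits(self, sched, rng):
        x0 = rng.standard_normal((1, 12, 1))
        t = 50
        ab = sched.alpha_bars[t - 1]
        assert np.allclose(
            v_target(x0, np.zeros_like(x0), t, sched), -np.sqrt(1 - ab) * x0
        )
        eps = rng.standard_normal(x0.shape)
        assert np.allclose(
            v_target(np.zeros_like(x0), eps, t, sched), np.sqrt(ab) * eps
        )

    def test_rotation_identity(self, sched, rng):
        # (x0, eps) -> (xt, v) is an orthogonal rotation: norms are conserved
        x0 = rng.standard_normal((3, 12, 2))
        eps = rng.standard_normal(x0.shape)
        for t in (1, 37, 100):
            xt = q_sample(x0, t, eps, sched)
            v = v_target(x0, eps, t, sched)
            assert np.allclose(
                (v**2 + xt**2).sum(), (x0**2 + eps**2).sum(), rtol=1e-10
            )


class TestReverseProcess:
    def test_final_step_is_deterministic(self, sched, rng):
        xt = rng.standard_normal((1, 12, 1))
        v = rng.standard_normal(xt.shape)
        a = p_sample_step(xt, v, 1, sched, np.random.default_rng(0))
        b = p_sample_step(xt, v, 1, sched, np.random.default_rng(99))
        assert np.array_equal(a, b)

    def test_perfect_constant_prediction_recovers_constant(self):
        sched = cosine_schedule(100)
        c = 1.7
        rng = np.random.default_rng(3)

        def oracle(xt, t, cond):
            ab = sched.alpha_bars[t - 1]
            return (np.sqrt(ab) * xt - c) / np.sqrt(1.0 - ab)

        x = rng.standard_normal((4, 12, 1))
        out = sample_chain(oracle, x, sched.T, None, sched, rng, clip_x0=None)
        assert np.abs(out - c).max() < 1e-6

    def test_rejects_out_of_range_t(self, sched):
        x = np.zeros((1, 4, 1))
        with pytest.raises(ValueError):
            p_sample_step(x, x, 0, sched, np.random.default_rng(0))

    def test_noise_prediction_views(self, sched, rng):
        x0 = rng.standard_normal((1, 12, 1))
        eps = rng.standard_normal(x0.shape)
        t = 40
        xt = q_sample(x0, t, eps, sched)
        pred = NoisePrediction(v=v_target(x0, eps, t, sched))
        assert np.allclose(pred.x0_hat(xt, t, sched), x0, atol=1e-10)
        assert np.allclose(pred.eps_hat(xt, t, sched), eps, atol=1e-10)


class TestPartialReconstruct:
    def test_t_start_zero_returns_copies(self, sched, rng):
        x0 = rng.standard_normal((2, 12, 1))
        out = partial_reconstruct(x0, 0, None, None, 3, sched, rng)
        assert out.shape == (3, 2, 12, 1)
        assert np.array_equal(out[0], x0) and np.array_equal(out[2], x0)

    def test_fixed_seed_is_bit_identical(self, sched, rng):
        x0 = rng.standard_normal((2, 12, 1))

        def oracle(xt, t, cond):
            return np.zeros_like(xt)

        a = partial_reconstruct(x0, 20, oracle, None, 2, sched, np.random.default_rng(5))
        b = partial_reconstruct(x0, 20, oracle, None, 2, sched, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_memorizing_oracle_reproduces_target(self, rng):
        sched = cosine_schedule(200)
        m = rng.standard_normal((1, 12, 1))

        def oracle(xt, t, cond):
            ab = sched.alpha_bars[t - 1]
            return (np.sqrt(ab) * xt - m) / np.sqrt(1.0 - ab)

        x0 = rng.standard_normal((1, 12, 1))
        out = partial_reconstruct(x0, 150, oracle, None, 4, sched, rng, clip_x0=None)
        assert np.abs(out - m).max() < 1e-4


class TestTrainingLoss:
    def test_exact_denoiser_has_zero_loss(self, sched, rng):
        x0 = rng.standard_normal((8, 12, 1))
        store = {}

        def exact(xt, t, cond):
            return store["target"]

        # wrap rng so eps/t used inside are recoverable: replicate computation
        seed_rng = np.random.default_rng(11)
        t = seed_rng.integers(1, sched.T + 1, size=8)
        eps = seed_rng.standard_normal(x0.shape)
        store["target"] = v_target(x0, eps, t, sched)
        loss = training_loss(x0, None, exact, sched, np.random.default_rng(11))
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_zero_denoiser_loss_is_mean_squared_target(self, sched, rng):
        x0 = rng.standard_normal((8, 12, 1))
        seed_rng = np.random.default_rng(13)
        t = seed_rng.integers(1, sched.T + 1, size=8)
        eps = seed_rng.standard_normal(x0.shape)
        expected = float(np.mean(v_target(x0, eps, t, sched) ** 2))

        def zero(xt, t, cond):
            return np.zeros_like(xt)

        loss = training_loss(x0, None, zero, sched, np.random.default_rng(13))
        assert loss == pytest.approx(expected, rel=1e-12)

    def test_monte_carlo_stability_for_linear_denoiser(self, sched, rng):
        # a fixed linear map of xt: loss estimates agree across seeds to 3 se
        x0 = rng.standard_normal((1000, 12, 1))

        def linear(xt, t, cond):
            return -0.5 * xt

        losses = [
            training_loss(x0, None, linear, sched, np.random.default_rng(s))
            for s in range(5)
        ]
        spread = np.std(losses)
        assert spread < 0.1 * np.mean(losses)

    def test_rejects_empty_batch(self, sched):
        with pytest.raises(ValueError):
            training_loss(np.zeros((0, 12, 1)), None, None, sched, np.random.default_rng(0))
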