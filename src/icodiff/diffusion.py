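"""Denoising-diffusion (DDPM) mathematical core on per-vertex feature maps.

States are arrays with a trailing ``(..., V, C)`` layout (vertices, channels),
typically ``(batch, V, C)``.  The module is agnostic to what produces the
denoising prediction: samplers accept any callable
``denoise_fn(x_t, t, conditions) -> v_hat``.

The network target is the *velocity* ``v = sqrt(abar_t) * eps -
sqrt(1 - abar_t) * x0``, an exact invertible reparameterization of the
(noise, signal) pair: together with ``x_t`` it recovers both ``x0`` and
``eps`` in closed form.  Training minimizes mean-squared error in v-space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiffusionSchedule",
    "NoisePrediction",
    "cosine_schedule",
    "q_sample",
    "v_target",
    "x0_eps_from_v",
    "p_sample_step",
    "sample_chain",
    "partial_reconstruct",
    "training_loss",
]


@dataclass(frozen=True)
class DiffusionSchedule:
    """Variance schedule and the per-step quantities derived from it.

    Steps are indexed ``t = 1..T``; array index ``t-1`` holds step ``t``.
    ``alpha_bar_0 = 1`` by convention (no noise).
    """

    T: int
    betas: np.ndarray
    alphas: np.ndarray
    alpha_bars: np.ndarray
    posterior_vars: np.ndarray

    def alpha_bar(self, t):
        """``abar_t`` for integer step(s) ``t`` in ``0..T``."""
        t = np.asarray(t)
        ab = np.concatenate([[1.0], self.alpha_bars])
        return ab[t]

    def to_dict(self) -> dict:
        return {"T": int(self.T)}


def cosine_schedule(T: int, s: float = 0.008, clip: float = 0.999) -> DiffusionSchedule:
    """Cosine noise schedule.

    ``abar_t = f(t)/f(0)`` with ``f(t) = cos^2(((t/T + s)/(1 + s)) * pi/2)``;
    betas are derived from consecutive ratios and clipped at ``clip``, and all
    downstream quantities are recomputed from the clipped betas.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    t = np.arange(T + 1, dtype=np.float64)
    f = np.cos(((t / T + s) / (1.0 + s)) * np.pi / 2.0) ** 2
    abar = f / f[0]
    betas = np.clip(1.0 - abar[1:] / abar[:-1], 0.0, clip)
    alphas = 1.0 - betas
    alpha_bars = np.cumprod(alphas)
    abar_prev = np.concatenate([[1.0], alpha_bars[:-1]])
    posterior_vars = betas * (1.0 - abar_prev) / (1.0 - alpha_bars)
    return DiffusionSchedule(
        T=T,
        betas=betas,
        alphas=alphas,
        alpha_bars=alpha_bars,
        posterior_vars=posterior_vars,
    )


def _ab_at(sched: DiffusionSchedule, t) -> np.ndarray:
    """``abar_t`` broadcast to a trailing (V, C) state: shape (...,1,1)."""
    t = np.asarray(t, dtype=np.int64)
    if np.any(t < 1) or np.any(t > sched.T):
        raise ValueError(f"t must lie in 1..{sched.T}")
    ab = sched.alpha_bars[t - 1]
    if ab.ndim:
        ab = ab.reshape(ab.shape + (1, 1))
    return ab


def q_sample(x0: np.ndarray, t, eps: np.ndarray, sched: DiffusionSchedule) -> np.ndarray:
    """Closed-form forward marginal: ``sqrt(abar_t) x0 + sqrt(1-abar_t) eps``."""
    ab = _ab_at(sched, t)
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def v_target(x0: np.ndarray, eps: np.ndarray, t, sched: DiffusionSchedule) -> np.ndarray:
    """Velocity target ``v = sqrt(abar_t) eps - sqrt(1-abar_t) x0``."""
    ab = _ab_at(sched, t)
    return np.sqrt(ab) * eps - np.sqrt(1.0 - ab) * x0


def x0_eps_from_v(
    xt: np.ndarray, v: np.ndarray, t, sched: DiffusionSchedule
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the v-parameterization: ``(x_t, v) -> (x0_hat, eps_hat)``."""
    ab = _ab_at(sched, t)
    x0_hat = np.sqrt(ab) * xt - np.sqrt(1.0 - ab) * v
    eps_hat = np.sqrt(1.0 - ab) * xt + np.sqrt(ab) * v
    return x0_hat, eps_hat


@dataclass
class NoisePrediction:
    """A denoiser output in v-parameterization, with derived views on demand."""

    v: np.ndarray

    def x0_hat(self, xt, t, sched):
        return x0_eps_from_v(xt, self.v, t, sched)[0]

    def eps_hat(self, xt, t, sched):
        return x0_eps_from_v(xt, self.v, t, sched)[1]


def p_sample_step(
    xt: np.ndarray,
    pred: "NoisePrediction | np.ndarray",
    t: int,
    sched: DiffusionSchedule,
    rng: np.random.Generator,
    clip_x0: float | None = 6.0,
) -> np.ndarray:
    """One reverse step ``x_t -> x_{t-1}``.

    The prediction is converted to ``x0_hat`` (optionally clipped to
    ``+-clip_x0`` in standardized units), the exact forward-posterior mean is
    formed, and posterior noise ``sqrt(beta_tilde_t) z`` is added for ``t > 1``
    (the final step is deterministic).
    """
    if not 1 <= t <= sched.T:
        raise ValueError(f"t must lie in 1..{sched.T}")
    v = pred.v if isinstance(pred, NoisePrediction) else pred
    x0_hat, _ = x0_eps_from_v(xt, v, t, sched)
    if clip_x0 is not None:
        x0_hat = np.clip(x0_hat, -clip_x0, clip_x0)

    i = t - 1
    beta = sched.betas[i]
    alpha = sched.alphas[i]
    ab_t = sched.alpha_bars[i]
    ab_prev = sched.alpha_bars[i - 1] if t > 1 else 1.0
    mean = (
        np.sqrt(ab_prev) * beta / (1.0 - ab_t) * x0_hat
        + np.sqrt(alpha) * (1.0 - ab_prev) / (1.0 - ab_t) * xt
    )
    if t == 1:
        return mean
    return mean + np.sqrt(sched.posterior_vars[i]) * rng.standard_normal(xt.shape)


def sample_chain(
    denoise_fn,
    x_start: np.ndarray,
    t_start: int,
    conditions,
    sched: DiffusionSchedule,
    rng: np.random.Generator,
    clip_x0: float | None = 6.0,
) -> np.ndarray:
    """Run the reverse chain from ``x_{t_start}`` down to ``x_0``."""
    x = x_start
    for t in range(t_start, 0, -1):
        v = denoise_fn(x, t, conditions)
        x = p_sample_step(x, v, t, sched, rng, clip_x0=clip_x0)
    return x


def partial_reconstruct(
    x0_obs: np.ndarray,
    t_start: int,
    denoise_fn,
    conditions,
    n_samples: int,
    sched: DiffusionSchedule,
    rng: np.random.Generator,
    clip_x0: float | None = 6.0,
) -> np.ndarray:
    """Pseudo-healthy reconstruction by partial noising.

    The observed map is pushed ``t_start`` steps into the forward process with
    fresh noise (independently per sample) and denoised back under the learned
    reverse dynamics, with the conditions (anatomical mask, age, sex) held
    fixed.  Returns ``(n_samples,) + x0_obs.shape``.

    ``t_start = 0`` is the degenerate no-noise case and returns copies of the
    input.
    """
    if not 0 <= t_start <= sched.T:
        raise ValueError(f"t_start must lie in 0..{sched.T}")
    if t_start == 0:
        return np.repeat(x0_obs[None], n_samples, axis=0).copy()
    out = np.empty((n_samples,) + x0_obs.shape, dtype=np.float64)
    for k in range(n_samples):
        eps = rng.standard_normal(x0_obs.shape)
        x = q_sample(x0_obs, t_start, eps, sched)
        out[k] = sample_chain(denoise_fn, x, t_start, conditions, sched, rng, clip_x0)
    return out


def training_loss(
    x0_batch: np.ndarray,
    conditions,
    denoise_fn,
    sched: DiffusionSchedule,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo estimate of the simplified diffusion objective (v-space MSE).

    Per batch item: draw ``t`` uniform on ``1..T`` and ``eps`` standard normal,
    noise the item to ``x_t``, and score the denoiser's velocity prediction
    against the exact target.
    """
    if x0_batch.shape[0] == 0:
        raise ValueError("batch must be non-empty")
    n = x0_batch.shape[0]
    t = rng.integers(1, sched.T + 1, size=n)
    eps = rng.standard_normal(x0_batch.shape)
    xt = q_sample(x0_batch, t, eps, sched)
    target = v_target(x0_batch, eps, t, sched)
    v_hat = denoise_fn(xt, t, conditions)
    return float(np.mean((v_hat - target) ** 2))
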