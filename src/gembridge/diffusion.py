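"""Diffusion-process primitives: noise schedules, forward sampling, the training
objective, ancestral (DDPM) sampling and the deterministic DDIM/ODE bridge.

Conventions
-----------
``alpha_bar[t-1]`` is the cumulative signal-retention coefficient at integer
timestep ``t`` in ``1..T``; ``t = 0`` denotes the clean-data boundary where the
cumulative coefficient is exactly 1.  The forward marginal is

    x_t = sqrt(abar_t) * x_0 + sqrt(1 - abar_t) * eps,     eps ~ N(0, I)

and the sigma=0 DDIM update iterated over a timestep grid defines a
deterministic ODE that maps data to a Gaussian-like latent and back; running
it up with one phenotype condition and down with the other is the
state-bridging operation.

A *denoiser* here is any callable ``(x_t, t, condition) -> eps_hat`` mapping
numpy arrays shape-preservingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NoiseSchedule",
    "make_schedule",
    "q_sample",
    "loss_simple",
    "predict_x0",
    "ddim_step",
    "ancestral_sample",
    "ode_timestep_grid",
    "ode_encode",
    "ode_decode",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step betas and cumulative signal coefficients for T diffusion steps."""

    T: int
    betas: np.ndarray  # length T, beta_t for t = 1..T
    alpha_bar: np.ndarray  # length T, strictly decreasing in (0, 1)
    kind: str = "linear_beta"

    def __post_init__(self) -> None:
        ab = np.asarray(self.alpha_bar)
        if len(ab) != self.T or len(self.betas) != self.T:
            raise ValueError("schedule arrays must have length T")
        if not (np.all(ab > 0) and np.all(ab < 1) and np.all(np.diff(ab) < 0)):
            raise ValueError("alpha_bar must be strictly decreasing within (0, 1)")

    def abar(self, t) -> np.ndarray:
        """Cumulative coefficient at integer step(s) t, with abar(0) = 1."""
        t = np.asarray(t, dtype=np.int64)
        if np.any(t < 0) or np.any(t > self.T):
            raise ValueError(f"timestep out of range [0, {self.T}]")
        padded = np.concatenate([[1.0], self.alpha_bar])
        return padded[t]

    def to_dict(self) -> dict:
        return {"T": self.T, "kind": self.kind, "betas": self.betas.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSchedule":
        betas = np.asarray(d["betas"], dtype=np.float64)
        alphas = 1.0 - betas
        return cls(T=int(d["T"]), betas=betas, alpha_bar=np.cumprod(alphas), kind=d["kind"])


def make_schedule(
    T: int = 1000,
    kind: str = "linear_beta",
    beta_min: float = 1e-4,
    beta_max: float = 0.02,
) -> NoiseSchedule:
    """Build a noise schedule.

    ``linear_beta`` spaces the per-step variances linearly (the standard DDPM
    default); ``cosine`` follows the squared-cosine cumulative profile with
    per-step betas clipped at 0.999.
    """
    if T < 2:
        raise ValueError(f"T must be >= 2, got {T}")
    if kind == "linear_beta":
        if not 0 < beta_min < beta_max < 1:
            raise ValueError(f"need 0 < beta_min < beta_max < 1, got ({beta_min}, {beta_max})")
        betas = np.linspace(beta_min, beta_max, T)
    elif kind == "cosine":
        s = 0.008
        f = np.cos((np.arange(T + 1) / T + s) / (1 + s) * np.pi / 2.0) ** 2
        abar = f / f[0]
        betas = np.clip(1.0 - abar[1:] / abar[:-1], 0.0, 0.999)
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    alpha_bar = np.cumprod(1.0 - betas)
    return NoiseSchedule(T=T, betas=betas, alpha_bar=alpha_bar, kind=kind)


def _abar_col(schedule: NoiseSchedule, t) -> np.ndarray:
    """abar(t) shaped (n, 1) for row-wise broadcasting over a (n, genes) batch."""
    ab = schedule.abar(t)
    return np.atleast_1d(ab)[:, None]


def q_sample(x0: np.ndarray, t, eps: np.ndarray, schedule: NoiseSchedule) -> np.ndarray:
    """Forward marginal draw: sqrt(abar_t) x0 + sqrt(1 - abar_t) eps."""
    x0 = np.asarray(x0, dtype=np.float64)
    t = np.asarray(t, dtype=np.int64)
    if np.any(t < 1) or np.any(t > schedule.T):
        raise ValueError(f"t must lie in [1, {schedule.T}]")
    ab = _abar_col(schedule, t)
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def loss_simple(denoiser, batch, schedule: NoiseSchedule) -> float:
    """Noise-prediction MSE: mean squared error between eps and eps_hat.

    ``batch`` carries ``x0``, ``t``, ``eps`` and ``condition`` attributes (or
    keys).  This is the evaluation-side loss on plain arrays; the training
    loop builds the differentiable counterpart internally.
    """
    get = batch.get if isinstance(batch, dict) else lambda k: getattr(batch, k)
    x0, t, eps, cond = get("x0"), get("t"), get("eps"), get("condition")
    x_t = q_sample(x0, t, eps, schedule)
    eps_hat = denoiser(x_t, np.asarray(t), np.asarray(cond))
    return float(np.mean((np.asarray(eps_hat) - eps) ** 2))


def predict_x0(x_t: np.ndarray, eps_hat: np.ndarray, t, schedule: NoiseSchedule) -> np.ndarray:
    """Algebraic inverse of the forward marginal given a noise estimate."""
    ab = _abar_col(schedule, t)
    return (np.asarray(x_t) - np.sqrt(1.0 - ab) * np.asarray(eps_hat)) / np.sqrt(ab)


def ddim_step(
    x_t: np.ndarray,
    eps_hat: np.ndarray,
    t,
    t_prev,
    sigma_t: float,
    schedule: NoiseSchedule,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """One (possibly stochastic) DDIM update from step t to step t_prev < t.

    With ``sigma_t = 0`` the update is deterministic and iterating it
    integrates the probability-flow ODE.
    """
    t = np.asarray(t, dtype=np.int64)
    t_prev = np.asarray(t_prev, dtype=np.int64)
    if np.any(t_prev >= t):
        raise ValueError("t_prev must be strictly less than t")
    ab_prev = _abar_col(schedule, t_prev)
    if sigma_t < 0:
        raise ValueError("sigma_t must be >= 0")
    resid = 1.0 - ab_prev - sigma_t**2
    if np.any(resid < 0):
        raise ValueError("sigma_t^2 exceeds 1 - alpha_bar(t_prev)")
    x0_hat = predict_x0(x_t, eps_hat, t, schedule)
    out = np.sqrt(ab_prev) * x0_hat + np.sqrt(resid) * np.asarray(eps_hat)
    if sigma_t > 0:
        if noise is None:
            raise ValueError("stochastic step (sigma_t > 0) requires noise")
        out = out + sigma_t * noise
    return out


def ancestral_sample(
    denoiser,
    n: int,
    condition: int,
    n_genes: int,
    schedule: NoiseSchedule,
    seed: int = 0,
    clip: bool = True,
) -> np.ndarray:
    """Stochastic DDPM reverse chain from pure Gaussian noise down to x_0.

    Uses the simple sigma_t^2 = beta_t reverse variance; the final step adds
    no noise.  Output is clipped to the normalized data domain [-1, 1].
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, n_genes))
    cond = np.full(n, condition, dtype=np.int64)
    abar = schedule.abar
    for t in range(schedule.T, 0, -1):
        tv = np.full(n, t, dtype=np.int64)
        eps_hat = np.asarray(denoiser(x, tv, cond))
        beta_t = schedule.betas[t - 1]
        alpha_t = 1.0 - beta_t
        ab_t = abar(t)
        mean = (x - beta_t / np.sqrt(1.0 - ab_t) * eps_hat) / np.sqrt(alpha_t)
        if t > 1:
            x = mean + np.sqrt(beta_t) * rng.standard_normal(x.shape)
        else:
            x = mean
    return np.clip(x, -1.0, 1.0) if clip else x


def ode_timestep_grid(schedule: NoiseSchedule, n_ode_steps: int) -> np.ndarray:
    """Evenly spaced integer grid 0 = tau_0 < tau_1 < ... < tau_n = T."""
    if n_ode_steps < 1:
        raise ValueError("n_ode_steps must be >= 1")
    if n_ode_steps > schedule.T:
        raise ValueError(
            f"n_ode_steps={n_ode_steps} exceeds schedule T={schedule.T}"
        )
    grid = np.unique(np.round(np.linspace(0, schedule.T, n_ode_steps + 1)).astype(int))
    return grid


@dataclass(frozen=True)
class LatentMatrix:
    """Step-T encoding of a batch of samples under the deterministic forward ODE."""

    values: np.ndarray
    condition: int
    n_ode_steps: int
    schedule_T: int = field(default=0)


def ode_encode(
    denoiser,
    x0_rows: np.ndarray,
    condition: int,
    schedule: NoiseSchedule,
    n_ode_steps: int = 100,
) -> LatentMatrix:
    """Integrate the sigma=0 ODE forward (t: 0 -> T) under the source condition."""
    grid = ode_timestep_grid(schedule, n_ode_steps)
    x = np.asarray(x0_rows, dtype=np.float64).copy()
    n = x.shape[0]
    cond = np.full(n, condition, dtype=np.int64)
    for t_cur, t_next in zip(grid[:-1], grid[1:]):
        t_eval = max(int(t_cur), 1)  # the denoiser is trained on t in [1, T]
        eps_hat = np.asarray(denoiser(x, np.full(n, t_eval, dtype=np.int64), cond))
        ab_cur = schedule.abar(int(t_cur))
        ab_next = schedule.abar(int(t_next))
        x0_hat = (x - np.sqrt(1.0 - ab_cur) * eps_hat) / np.sqrt(ab_cur)
        x = np.sqrt(ab_next) * x0_hat + np.sqrt(1.0 - ab_next) * eps_hat
    return LatentMatrix(
        values=x, condition=condition, n_ode_steps=n_ode_steps, schedule_T=schedule.T
    )


def ode_decode(
    denoiser,
    latent: LatentMatrix,
    condition: int,
    schedule: NoiseSchedule,
    n_ode_steps: int | None = None,
    clip: bool = True,
) -> np.ndarray:
    """Integrate the sigma=0 ODE in reverse (t: T -> 0) under the target condition.

    Row pairing is preserved: output row i is the bridged image of input row i.
    """
    if n_ode_steps is None:
        n_ode_steps = latent.n_ode_steps
    grid = ode_timestep_grid(schedule, n_ode_steps)[::-1]
    x = np.asarray(latent.values, dtype=np.float64).copy()
    n = x.shape[0]
    cond = np.full(n, condition, dtype=np.int64)
    for t_cur, t_next in zip(grid[:-1], grid[1:]):
        t_eval = max(int(t_cur), 1)
        eps_hat = np.asarray(denoiser(x, np.full(n, t_eval, dtype=np.int64), cond))
        x = ddim_step(
            x,
            eps_hat,
            np.full(n, int(t_cur)),
            np.full(n, int(t_next)),
            sigma_t=0.0,
            schedule=schedule,
        )
    return np.clip(x, -1.0, 1.0) if clip else x
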