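"""High-level estimator: a phenotype-conditioned diffusion model over a GEM.

:class:`ExpressionDiffusion` follows scikit-learn conventions — ``fit(X, y)``
trains the conditional denoiser on normalized expression rows, ``sample``
draws new synthetic rows for a phenotype, and ``transform`` bridges rows from
one phenotype state to the other through the deterministic ODE latent.  One
shared conditional model serves both tasks; only the condition input changes
between the encode and decode legs of the bridge.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import diffusion
from .denoiser import DenoiserConfig, TrainOptions, TransformerDenoiser, train

__all__ = ["ExpressionDiffusion"]


class ExpressionDiffusion(BaseEstimator):
    """Conditional denoising diffusion model for normalized expression matrices.

    Parameters
    ----------
    n_steps : int
        Number of diffusion timesteps T.
    schedule : {"linear_beta", "cosine"}
        Noise-schedule family.
    beta_min, beta_max : float
        Per-step variance range for the linear schedule.
    embed_dim, n_blocks, n_heads, feedforward_dim, dropout
        Transformer denoiser architecture.
    batch_size, learning_rate, n_iterations, ema_decay
        Training-loop options.
    n_ode_steps : int
        Timestep-grid resolution of the deterministic encode/decode bridge.
    random_state : int
        Seed for weight init, batching and noise draws.

    Attributes
    ----------
    classes_ : ndarray
        The two phenotype labels, sorted; their indices are the condition ids.
    denoiser_ : TransformerDenoiser
        Trained noise predictor (EMA weights used for sampling).
    schedule_ : NoiseSchedule
    loss_trace_ : list of float
        Interval-averaged training losses.
    """

    def __init__(
        self,
        n_steps: int = 1000,
        schedule: str = "linear_beta",
        beta_min: float = 1e-4,
        beta_max: float = 0.02,
        embed_dim: int = 128,
        n_blocks: int = 4,
        n_heads: int = 4,
        feedforward_dim: int | None = None,
        dropout: float = 0.0,
        batch_size: int = 32,
        learning_rate: float = 1e-4,
        n_iterations: int = 4000,
        ema_decay: float = 0.999,
        n_ode_steps: int = 100,
        random_state: int = 0,
    ):
        self.n_steps = n_steps
        self.schedule = schedule
        self.beta_min = beta_min
        self.beta_max = beta_max
        self.embed_dim = embed_dim
        self.n_blocks = n_blocks
        self.n_heads = n_heads
        self.feedforward_dim = feedforward_dim
        self.dropout = dropout
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.n_iterations = n_iterations
        self.ema_decay = ema_decay
        self.n_ode_steps = n_ode_steps
        self.random_state = random_state

    # ------------------------------------------------------------------

    def fit(self, X, y):
        """Train the conditional denoiser on normalized rows X with labels y."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x genes)")
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        self.classes_ = np.array(sorted({str(v) for v in y}), dtype=object)
        if len(self.classes_) != 2:
            raise ValueError(
                f"exactly two phenotype labels required, found {list(self.classes_)}"
            )
        cond = np.searchsorted(self.classes_, y.astype(str))
        self.n_genes_ = X.shape[1]
        self.schedule_ = diffusion.make_schedule(
            T=self.n_steps, kind=self.schedule,
            beta_min=self.beta_min, beta_max=self.beta_max,
        )
        config = DenoiserConfig(
            embed_dim=self.embed_dim,
            n_blocks=self.n_blocks,
            n_heads=self.n_heads,
            feedforward_dim=self.feedforward_dim,
            dropout=self.dropout,
            n_conditions=2,
        )
        self.denoiser_ = TransformerDenoiser(config, self.n_genes_, seed=self.random_state)
        opts = TrainOptions(
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            n_iterations=self.n_iterations,
            ema_decay=self.ema_decay,
            seed=self.random_state,
        )
        self.loss_trace_ = train(self.denoiser_, X, cond, self.schedule_, opts)
        return self

    # ------------------------------------------------------------------

    def _condition_index(self, label) -> int:
        check_is_fitted(self, "denoiser_")
        matches = np.flatnonzero(self.classes_ == str(label))
        if len(matches) == 0:
            raise ValueError(f"unknown label {label!r}; fitted on {list(self.classes_)}")
        return int(matches[0])

    def sample(self, n: int, label, seed: int | None = None) -> np.ndarray:
        """Draw n new rows for a phenotype via the stochastic reverse chain."""
        cond = self._condition_index(label)
        seed = self.random_state if seed is None else seed
        return diffusion.ancestral_sample(
            self.denoiser_, n, cond, self.n_genes_, self.schedule_, seed=seed
        )

    def encode(self, X, label) -> diffusion.LatentMatrix:
        """Deterministic forward ODE to the step-T latent under ``label``."""
        cond = self._condition_index(label)
        return diffusion.ode_encode(
            self.denoiser_, np.asarray(X, dtype=np.float64), cond,
            self.schedule_, self.n_ode_steps,
        )

    def decode(self, latent: diffusion.LatentMatrix, label) -> np.ndarray:
        """Deterministic reverse ODE from a latent under ``label``."""
        cond = self._condition_index(label)
        return diffusion.ode_decode(
            self.denoiser_, latent, cond, self.schedule_, self.n_ode_steps
        )

    def transform(self, X, source_label, target_label) -> np.ndarray:
        """Bridge rows from one phenotype state to another (row-paired).

        Encodes ``X`` under the source condition and decodes the latent under
        the target condition; with ``source == target`` this is the
        reconstruction (cycle-consistency) regime.
        """
        return self.decode(self.encode(X, source_label), target_label)
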