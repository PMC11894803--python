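"""Transformer-based conditional noise predictor eps_theta(x_t, t, condition).

Each gene is one token: its scalar expression value is linearly projected to
an embedding, a learned per-gene position embedding, a projected sinusoidal
timestep embedding and a learned phenotype-condition embedding are added, the
sequence passes through a stack of pre-norm transformer encoder blocks, and a
final linear head maps every token back to one scalar — so the output always
has the input's samples x genes shape.  Self-attention lets the predictor use
relationships between arbitrary gene pairs rather than only neighbouring
features.

Training minimizes the standard noise-prediction MSE with uniformly sampled
timesteps; an exponential moving average (EMA) of the weights is maintained
and used for all sampling.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .diffusion import NoiseSchedule, q_sample
from .nn import Adam, Parameter, Tensor, sinusoidal_embedding

__all__ = [
    "DenoiserConfig",
    "TrainOptions",
    "TransformerDenoiser",
    "init_denoiser",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture hyper-parameters of the noise predictor."""

    embed_dim: int = 128
    n_blocks: int = 4
    n_heads: int = 4
    feedforward_dim: int | None = None  # defaults to 4 * embed_dim
    dropout: float = 0.0
    n_conditions: int = 2

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim={self.embed_dim} not divisible by n_heads={self.n_heads}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_conditions < 1:
            raise ValueError("n_conditions must be >= 1")

    @property
    def ff_dim(self) -> int:
        return self.feedforward_dim or 4 * self.embed_dim


@dataclass(frozen=True)
class TrainOptions:
    batch_size: int = 32
    learning_rate: float = 1e-4
    n_iterations: int = 4000
    ema_decay: float = 0.999
    seed: int = 0
    log_interval: int = 50

    def __post_init__(self) -> None:
        if min(self.batch_size, self.n_iterations, self.log_interval) < 1:
            raise ValueError("batch_size, n_iterations and log_interval must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.ema_decay < 1.0:
            raise ValueError("ema_decay must be in (0, 1)")


class TransformerDenoiser:
    """One-token-per-gene transformer encoder predicting the added noise."""

    def __init__(self, config: DenoiserConfig, n_genes: int, seed: int = 0):
        self.config = config
        self.n_genes = int(n_genes)
        d, ff = config.embed_dim, config.ff_dim
        rng = np.random.default_rng(seed)

        def init(*shape, scale=None):
            scale = scale if scale is not None else 1.0 / math.sqrt(shape[0])
            return Parameter(rng.normal(0.0, scale, size=shape))

        p: dict[str, Tensor] = {}
        p["in_w"] = init(1, d, scale=1.0)
        p["in_b"] = Parameter(np.zeros(d))
        p["pos"] = Parameter(rng.normal(0.0, 0.02, size=(self.n_genes, d)))
        p["cond"] = Parameter(rng.normal(0.0, 0.02, size=(config.n_conditions, d)))
        p["t_w1"] = init(d, d)
        p["t_b1"] = Parameter(np.zeros(d))
        p["t_w2"] = init(d, d)
        p["t_b2"] = Parameter(np.zeros(d))
        for i in range(config.n_blocks):
            for name in ("q", "k", "v", "o"):
                p[f"blk{i}_{name}_w"] = init(d, d)
                p[f"blk{i}_{name}_b"] = Parameter(np.zeros(d))
            p[f"blk{i}_ln1_g"] = Parameter(np.ones(d))
            p[f"blk{i}_ln1_b"] = Parameter(np.zeros(d))
            p[f"blk{i}_ln2_g"] = Parameter(np.ones(d))
            p[f"blk{i}_ln2_b"] = Parameter(np.zeros(d))
            p[f"blk{i}_ff1_w"] = init(d, ff)
            p[f"blk{i}_ff1_b"] = Parameter(np.zeros(ff))
            p[f"blk{i}_ff2_w"] = init(ff, d)
            p[f"blk{i}_ff2_b"] = Parameter(np.zeros(d))
        p["ln_f_g"] = Parameter(np.ones(d))
        p["ln_f_b"] = Parameter(np.zeros(d))
        p["out_w"] = init(d, 1)
        p["out_b"] = Parameter(np.zeros(1))
        self.params = p
        self.ema_params: dict[str, np.ndarray] = {
            k: v.data.copy() for k, v in p.items()
        }

    # -- forward pass ---------------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        t: np.ndarray,
        condition: np.ndarray,
        params: dict[str, Tensor] | None = None,
        dropout_rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Differentiable forward pass; returns a (batch, n_genes) Tensor."""
        p = params if params is not None else self.params
        cfg = self.config
        d, h = cfg.embed_dim, cfg.n_heads
        dh = d // h
        x = np.asarray(x, dtype=np.float64)
        b, g = x.shape
        if g != self.n_genes:
            raise ValueError(f"expected {self.n_genes} genes, got {g}")

        tok = Tensor(x[:, :, None]) @ p["in_w"] + p["in_b"]  # (b, g, d)
        temb = Tensor(sinusoidal_embedding(t, d))
        temb = ((temb @ p["t_w1"] + p["t_b1"]).gelu() @ p["t_w2"]) + p["t_b2"]
        cemb = p["cond"].take_rows(np.asarray(condition, dtype=np.int64))
        # timestep + phenotype context, re-injected at every block so the
        # condition steers generation even at high noise levels
        ctx = (temb + cemb).reshape(b, 1, d)
        hdd = tok + p["pos"] + ctx

        for i in range(cfg.n_blocks):
            hdd = hdd + ctx
            z = hdd.layer_norm(p[f"blk{i}_ln1_g"], p[f"blk{i}_ln1_b"])
            q = (z @ p[f"blk{i}_q_w"] + p[f"blk{i}_q_b"]).reshape(b, g, h, dh).swapaxes(1, 2)
            k = (z @ p[f"blk{i}_k_w"] + p[f"blk{i}_k_b"]).reshape(b, g, h, dh).swapaxes(1, 2)
            v = (z @ p[f"blk{i}_v_w"] + p[f"blk{i}_v_b"]).reshape(b, g, h, dh).swapaxes(1, 2)
            scores = (q @ k.swapaxes(2, 3)) * (1.0 / math.sqrt(dh))
            attn = scores.softmax(axis=-1) @ v  # (b, h, g, dh)
            attn = attn.swapaxes(1, 2).reshape(b, g, d)
            attn = attn @ p[f"blk{i}_o_w"] + p[f"blk{i}_o_b"]
            attn = self._dropout(attn, dropout_rng)
            hdd = hdd + attn
            z = hdd.layer_norm(p[f"blk{i}_ln2_g"], p[f"blk{i}_ln2_b"])
            ffo = (z @ p[f"blk{i}_ff1_w"] + p[f"blk{i}_ff1_b"]).gelu()
            ffo = ffo @ p[f"blk{i}_ff2_w"] + p[f"blk{i}_ff2_b"]
            hdd = hdd + self._dropout(ffo, dropout_rng)

        hdd = hdd.layer_norm(p["ln_f_g"], p["ln_f_b"])
        out = hdd @ p["out_w"] + p["out_b"]  # (b, g, 1)
        return out.reshape(b, g)

    def _dropout(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        rate = self.config.dropout
        if rate == 0.0 or rng is None:
            return x
        mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
        return x * Tensor(mask)

    def __call__(self, x, t, condition) -> np.ndarray:
        """Inference with the EMA weights; plain numpy in, plain numpy out."""
        ema = {k: Tensor(v) for k, v in self.ema_params.items()}
        return self.forward(x, t, condition, params=ema).data

    def raw_call(self, x, t, condition) -> np.ndarray:
        """Inference with the current (non-EMA) weights."""
        return self.forward(x, t, condition).data

    # -- weight management -----------------------------------------------------

    def update_ema(self, decay: float) -> None:
        for k, v in self.params.items():
            self.ema_params[k] = decay * self.ema_params[k] + (1.0 - decay) * v.data

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {f"param/{k}": v.data for k, v in self.params.items()}
        out.update({f"ema/{k}": v for k, v in self.ema_params.items()})
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k].data = np.array(arrays[f"param/{k}"], dtype=np.float64)
            self.ema_params[k] = np.array(arrays[f"ema/{k}"], dtype=np.float64)


def init_denoiser(config: DenoiserConfig, n_genes: int, seed: int = 0) -> TransformerDenoiser:
    return TransformerDenoiser(config, n_genes, seed=seed)


def train(
    denoiser: TransformerDenoiser,
    x0: np.ndarray,
    conditions: np.ndarray,
    schedule: NoiseSchedule,
    opts: TrainOptions,
) -> list[float]:
    """Noise-prediction training loop; returns the per-log-interval loss trace.

    ``x0`` is the normalized training matrix in [-1, 1]; ``conditions`` the
    integer phenotype index per row.  Timesteps are drawn uniformly from
    [1, T] and fresh Gaussian noise from the seeded generator each iteration.
    """
    x0 = np.asarray(x0, dtype=np.float64)
    conditions = np.asarray(conditions, dtype=np.int64)
    if np.any(np.abs(x0) > 1.0 + 1e-9):
        raise ValueError("training data must lie in [-1, 1]; run the scaler first")
    n = x0.shape[0]
    rng = np.random.default_rng(opts.seed)
    optim = Adam(denoiser.params, lr=opts.learning_rate)
    trace: list[float] = []
    window: list[float] = []
    for it in range(opts.n_iterations):
        idx = rng.integers(0, n, size=min(opts.batch_size, n))
        t = rng.integers(1, schedule.T + 1, size=len(idx))
        eps = rng.standard_normal((len(idx), x0.shape[1]))
        x_t = q_sample(x0[idx], t, eps, schedule)
        pred = denoiser.forward(
            x_t, t, conditions[idx], dropout_rng=rng if denoiser.config.dropout else None
        )
        diff = pred - Tensor(eps)
        loss = (diff * diff).mean()
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite training loss at iteration {it}; "
                "lower the learning rate or check the input scaling"
            )
        optim.zero_grad()
        loss.backward()
        optim.step()
        # warm-up keeps the random init from lingering in the average
        denoiser.update_ema(min(opts.ema_decay, (1 + it) / (10 + it)))
        window.append(float(loss.data))
        if (it + 1) % opts.log_interval == 0 or it == opts.n_iterations - 1:
            trace.append(float(np.mean(window)))
            window = []
    return trace


# -- checkpointing ----------------------------------------------------------------


def save_checkpoint(
    denoiser: TransformerDenoiser,
    schedule: NoiseSchedule,
    path,
    scaler_params=None,
    gene_ids: list[str] | None = None,
    label_vocabulary: list[str] | None = None,
) -> None:
    """Bundle weights + config + schedule (+ scaler, gene ids, labels) into one file."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(denoiser.config),
        "n_genes": denoiser.n_genes,
        "schedule": schedule.to_dict(),
        "gene_ids": gene_ids,
        "label_vocabulary": label_vocabulary,
        "scaler": None
        if scaler_params is None
        else {
            "gene_ids": scaler_params.gene_ids,
            "mins": scaler_params.mins.tolist(),
            "maxs": scaler_params.maxs.tolist(),
        },
    }
    arrays = denoiser.state_arrays()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Restore (denoiser, schedule, scaler_params, gene_ids, label_vocabulary)."""
    from .preprocess import ScalerParams

    try:
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
    except Exception as exc:
        raise OSError(f"cannot read checkpoint {path}: {exc}") from exc
    if "__meta__" not in arrays:
        raise OSError(f"checkpoint {path} is missing its metadata record")
    meta = json.loads(arrays.pop("__meta__").tobytes().decode())
    if meta.get("version") != CHECKPOINT_VERSION:
        raise OSError(
            f"checkpoint version {meta.get('version')} != supported {CHECKPOINT_VERSION}"
        )
    config = DenoiserConfig(**meta["config"])
    denoiser = TransformerDenoiser(config, meta["n_genes"], seed=0)
    denoiser.load_state_arrays(arrays)
    schedule = NoiseSchedule.from_dict(meta["schedule"])
    scaler = None
    if meta["scaler"] is not None:
        scaler = ScalerParams(
            gene_ids=meta["scaler"]["gene_ids"],
            mins=np.asarray(meta["scaler"]["mins"]),
            maxs=np.asarray(meta["scaler"]["maxs"]),
        )
    return denoiser, schedule, scaler, meta["gene_ids"], meta["label_vocabulary"]
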