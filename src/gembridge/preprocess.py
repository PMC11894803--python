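"""Expression preprocessing: log2(n+1), per-gene min-max scaling to (-1, 1), splits.

The transform chain is ``v -> log2(v + 1) -> -1 + 2 (v - min_g) / (max_g - min_g)``
with the per-gene extrema taken from the fitting (training) data only; values
seen at inference outside the fitted range are clipped to [-1, 1].  Zeros map
to zero under log2(n+1), so unexpressed genes stay identifiable.  Constant
genes map to the interval midpoint 0 and are restored to their constant on
inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import GEM

__all__ = [
    "Log2MinMaxScaler",
    "ScalerParams",
    "log2p1",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
    "split_train_test",
]


class Log2MinMaxScaler(TransformerMixin, BaseEstimator):
    """Map non-negative FPKM-like values to the diffusion model's (-1, 1) domain.

    ``fit`` records per-gene min/max of log2(x+1) on the training matrix;
    ``transform`` applies log2(x+1) followed by the affine rescale and clips to
    [-1, 1]; ``inverse_transform`` undoes both steps, returning values on the
    original non-negative scale.

    Attributes
    ----------
    min_, max_ : ndarray of shape (n_genes,)
        Per-gene extrema on the log2(x+1) scale.
    constant_mask_ : ndarray of bool
        Genes whose fitted max equals their min; they transform to 0.
    """

    def __init__(self, clip: bool = True):
        self.clip = clip

    def fit(self, X, y=None):
        X = self._validate(X)
        L = np.log2(X + 1.0)
        self.min_ = L.min(axis=0)
        self.max_ = L.max(axis=0)
        self.constant_mask_ = self.max_ == self.min_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "min_")
        X = self._validate(X)
        L = np.log2(X + 1.0)
        return self.transform_log2(L)

    def transform_log2(self, L):
        """Scale values already on the log2(x+1) scale."""
        check_is_fitted(self, "min_")
        span = np.where(self.constant_mask_, 1.0, self.max_ - self.min_)
        out = -1.0 + 2.0 * (L - self.min_) / span
        out[:, self.constant_mask_] = 0.0
        if self.clip:
            out = np.clip(out, -1.0, 1.0)
        return out

    def inverse_transform_log2(self, Z):
        """Invert the affine rescale only, back to the log2(x+1) scale."""
        check_is_fitted(self, "min_")
        Z = np.asarray(Z, dtype=np.float64)
        L = self.min_ + (Z + 1.0) * (self.max_ - self.min_) / 2.0
        L[:, self.constant_mask_] = self.min_[self.constant_mask_]
        return L

    def inverse_transform(self, Z):
        return np.clip(np.exp2(self.inverse_transform_log2(Z)) - 1.0, 0.0, None)

    def _validate(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("expected a 2-D samples x genes matrix")
        if np.any(X < 0):
            i, j = np.argwhere(X < 0)[0]
            raise ValueError(f"negative expression value at row {i}, column {j}")
        return X


@dataclass
class ScalerParams:
    """Serializable per-gene scaling parameters (log2 scale min/max per gene)."""

    gene_ids: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    lo: float = -1.0
    hi: float = 1.0

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=np.float64)
        self.maxs = np.asarray(self.maxs, dtype=np.float64)
        if np.any(self.maxs < self.mins):
            raise ValueError("per-gene max must be >= min")

    @property
    def constant_mask(self) -> np.ndarray:
        return self.maxs == self.mins

    def to_scaler(self) -> Log2MinMaxScaler:
        sc = Log2MinMaxScaler()
        sc.min_ = self.mins.copy()
        sc.max_ = self.maxs.copy()
        sc.constant_mask_ = self.constant_mask
        sc.n_features_in_ = len(self.gene_ids)
        return sc

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"gene": self.gene_ids, "min": self.mins, "max": self.maxs}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ScalerParams":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
        return cls(
            gene_ids=list(df["gene"]),
            mins=df["min"].to_numpy(),
            maxs=df["max"].to_numpy(),
        )

    def _check_genes(self, gem: GEM) -> None:
        if gem.gene_ids != self.gene_ids:
            unknown = set(gem.gene_ids) - set(self.gene_ids)
            raise ValueError(
                f"gene set mismatch with scaler params"
                + (f"; unknown genes {sorted(unknown)[:5]}" if unknown else "")
            )


# -- GEM-level functional surface ------------------------------------------------


def log2p1(gem: GEM) -> GEM:
    """log2(v + 1) on every value; zeros map to zero."""
    if np.any(gem.values < 0):
        i, j = np.argwhere(gem.values < 0)[0]
        raise ValueError(
            f"negative value at sample {gem.sample_ids[i]!r}, gene {gem.gene_ids[j]!r}"
        )
    return replace(gem, values=np.log2(gem.values + 1.0))


def fit_scaler(gem_log2: GEM) -> ScalerParams:
    """Record per-gene min/max from an already log2(n+1)-transformed matrix."""
    return ScalerParams(
        gene_ids=list(gem_log2.gene_ids),
        mins=gem_log2.values.min(axis=0),
        maxs=gem_log2.values.max(axis=0),
    )


def apply_scaler(gem_log2: GEM, params: ScalerParams, clip: bool = True) -> GEM:
    """Rescale a log2-transformed matrix to [-1, 1] with the fitted extrema."""
    params._check_genes(gem_log2)
    sc = params.to_scaler()
    sc.clip = clip
    return replace(gem_log2, values=sc.transform_log2(gem_log2.values))


def invert_scaler(matrix: np.ndarray, params: ScalerParams, to_fpkm: bool = True):
    """Undo the (-1, 1) rescale; optionally also undo log2(n+1) (``2**v - 1``)."""
    sc = params.to_scaler()
    L = sc.inverse_transform_log2(np.asarray(matrix, dtype=np.float64))
    if to_fpkm:
        return np.clip(np.exp2(L) - 1.0, 0.0, None)
    return L


def split_train_test(
    gem: GEM, train_fraction: float, seed: int = 0, stratify: bool = True
) -> tuple[GEM, GEM]:
    """Disjoint, exhaustive, seeded train/test split.

    The train size is ``floor(train_fraction * n)``; under stratification it is
    allocated across labels by largest remainder so per-label proportions are
    preserved to within one sample.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    n = gem.n_samples
    n_train = int(np.floor(train_fraction * n))
    if stratify:
        if gem.labels is None:
            raise ValueError("stratified split requires labels")
        vocab = gem.label_vocabulary()
        counts = {lab: int(np.sum(gem.labels == lab)) for lab in vocab}
        small = [lab for lab, c in counts.items() if c < 2]
        if small:
            raise ValueError(f"labels with fewer than 2 samples: {small}")
        exact = {lab: train_fraction * counts[lab] for lab in vocab}
        base = {lab: int(np.floor(exact[lab])) for lab in vocab}
        short = n_train - sum(base.values())
        for lab in sorted(vocab, key=lambda l: exact[l] - base[l], reverse=True)[:short]:
            base[lab] += 1
        train_idx: list[int] = []
        for lab in vocab:
            pool = np.flatnonzero(gem.labels == lab)
            pool = rng.permutation(pool)
            train_idx.extend(pool[: base[lab]].tolist())
        train_idx = sorted(train_idx)
    else:
        train_idx = sorted(rng.permutation(n)[:n_train].tolist())
    test_idx = sorted(set(range(n)) - set(train_idx))
    return gem.subset_samples(train_idx), gem.subset_samples(test_idx)
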