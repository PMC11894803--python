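"""Two-phenotype expression matrix simulator with planted signal genes.

The generator draws per-gene baselines in log2 space, shifts a chosen subset
of "signal" genes in the tumor class, and exponentiates back to an FPKM-like
scale, so the standard log2(n+1) preprocessing approximately recovers the
Gaussian log-scale structure.  It emulates co-normalized bulk RNA-seq
abundances, not raw counts: no negative-binomial dispersion, batch effects or
sample covariates are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GEM

__all__ = ["SyntheticSpec", "generate_two_state_gem", "generate_gene_set_collection"]

NORMAL, TUMOR = "normal", "tumor"


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one simulated two-state matrix.

    Attributes
    ----------
    n_per_class : int
        Samples per phenotype; total samples are ``2 * n_per_class``.
    n_genes : int
        Total gene features.
    n_signal : int
        Number of differentially expressed genes (``<= n_genes``).
    effect_size : float
        Mean shift, in log2 units, applied to signal genes in tumor samples.
    base_mean_range : (float, float)
        Uniform range for the per-gene baseline log2 mean.
    noise_sd : float
        Per-gene Gaussian standard deviation in log2 space.
    seed : int
        Generator seed; identical specs produce bit-identical matrices.
    """

    n_per_class: int
    n_genes: int
    n_signal: int
    effect_size: float
    base_mean_range: tuple[float, float] = (2.0, 10.0)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        if not 0 <= self.n_signal <= self.n_genes:
            raise ValueError(
                f"n_signal must lie in [0, n_genes={self.n_genes}], got {self.n_signal}"
            )
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        lo, hi = self.base_mean_range
        if not lo <= hi:
            raise ValueError(f"base_mean_range must be ordered, got {self.base_mean_range}")


def generate_two_state_gem(spec: SyntheticSpec) -> tuple[GEM, list[str]]:
    """Simulate a labelled normal/tumor matrix with planted signal genes.

    Returns the matrix on the non-negative FPKM-like scale (``2**x - 1``,
    clipped at 0) together with the list of planted signal gene ids.  Signal
    genes are drawn uniformly at random among the gene ids.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"gene_{i:04d}" for i in range(spec.n_genes)]
    mu = rng.uniform(*spec.base_mean_range, size=spec.n_genes)
    signal_idx = np.sort(rng.choice(spec.n_genes, size=spec.n_signal, replace=False))

    n = spec.n_per_class
    means = np.tile(mu, (2 * n, 1))
    means[n:, signal_idx] += spec.effect_size  # rows [n:] are the tumor class
    log2_expr = rng.normal(means, spec.noise_sd)
    values = np.clip(np.exp2(log2_expr) - 1.0, 0.0, None)

    sample_ids = [f"{NORMAL}_{i:04d}" for i in range(n)] + [
        f"{TUMOR}_{i:04d}" for i in range(n)
    ]
    labels = np.array([NORMAL] * n + [TUMOR] * n, dtype=object)
    gem = GEM(values=values, gene_ids=gene_ids, sample_ids=sample_ids, labels=labels)
    return gem, [gene_ids[i] for i in signal_idx]


def generate_gene_set_collection(
    gene_ids: list[str], set_sizes: list[int], seed: int = 0
) -> dict[str, list[str]]:
    """Draw disjoint named gene sets of the requested sizes (a GMT-shaped fixture)."""
    if any(s < 1 for s in set_sizes):
        raise ValueError("set sizes must be positive")
    total = sum(set_sizes)
    if total > len(gene_ids):
        raise ValueError(
            f"requested {total} genes across sets but only {len(gene_ids)} available"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(gene_ids))
    collection: dict[str, list[str]] = {}
    start = 0
    for k, size in enumerate(set_sizes):
        idx = order[start : start + size]
        collection[f"SET_{k:03d}"] = [gene_ids[i] for i in idx]
        start += size
    return collection
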