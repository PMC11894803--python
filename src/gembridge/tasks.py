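"""Headline applications: data augmentation, state-bridging perturbation,
core-gene calling, perturbation-silhouette correlation and local enrichment.

The perturbation score of a gene is the mean signed change, in normalized
(-1, 1) units, between the original rows and their bridged images; its sign
is the perturbation direction.  Pooling the scores of all screened subsets
and flagging genes beyond +/- ``k_sd`` (default 2) population standard
deviations from the pooled mean yields the "core genes" — the genes the
bridge must move furthest to carry a sample from one phenotype state to the
other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .denoiser import load_checkpoint
from .diffusion import ancestral_sample, ode_decode, ode_encode
from .io import GEM
from .preprocess import apply_scaler, invert_scaler, log2p1

__all__ = [
    "PerturbationResult",
    "augment",
    "perturb",
    "pool_scores",
    "correlate_perturbation_silhouette",
    "enrich",
]


@dataclass(frozen=True)
class PerturbationResult:
    """Row-paired original/bridged matrices and per-gene signed scores."""

    gene_ids: tuple[str, ...]
    original: np.ndarray  # normalized scale
    perturbed: np.ndarray  # normalized scale, row-paired with original
    per_gene_score: np.ndarray  # mean over samples of (perturbed - original)
    subset_name: str = "subset"

    @property
    def per_gene_direction(self) -> np.ndarray:
        return np.sign(self.per_gene_score)

    def score_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.gene_ids),
                "score": self.per_gene_score,
                "direction": self.per_gene_direction,
                "subset": self.subset_name,
            }
        )


def _checkpoint_parts(checkpoint):
    if isinstance(checkpoint, (str, bytes)) or hasattr(checkpoint, "__fspath__"):
        return load_checkpoint(checkpoint)
    return checkpoint  # already a (denoiser, schedule, scaler, gene_ids, vocab) tuple


def augment(checkpoint, n_per_label: dict[str, int], seed: int = 0) -> GEM:
    """Sample new labelled rows from noise and return them on the original scale.

    ``checkpoint`` is a path or a loaded bundle; sampling uses the stored EMA
    weights, and the stored scaler parameters map the normalized draws back to
    the non-negative FPKM-like scale.
    """
    denoiser, schedule, scaler, gene_ids, vocab = _checkpoint_parts(checkpoint)
    if scaler is None or gene_ids is None or vocab is None:
        raise ValueError("checkpoint lacks scaler/gene/label metadata needed to augment")
    blocks, sample_ids, labels = [], [], []
    for j, (label, n) in enumerate(sorted(n_per_label.items())):
        if label not in vocab:
            raise ValueError(f"unknown label {label!r}; checkpoint labels are {vocab}")
        cond = vocab.index(label)
        raw = ancestral_sample(
            denoiser, n, cond, denoiser.n_genes, schedule, seed=seed + j
        )
        blocks.append(invert_scaler(raw, scaler))
        sample_ids.extend(f"synthetic_{label}_{i:04d}" for i in range(n))
        labels.extend([label] * n)
    return GEM(
        values=np.vstack(blocks),
        gene_ids=list(gene_ids),
        sample_ids=sample_ids,
        labels=np.array(labels, dtype=object),
    )


def perturb(
    checkpoint,
    gem_rows: GEM,
    source_label: str,
    target_label: str,
    n_ode_steps: int = 100,
    subset_name: str = "subset",
    already_normalized: bool = False,
) -> PerturbationResult:
    """Bridge source-state rows to the target state through the ODE latent.

    ``gem_rows`` must be restricted to the checkpoint's genes and to
    source-label samples; values are FPKM-like unless ``already_normalized``.
    """
    denoiser, schedule, scaler, gene_ids, vocab = _checkpoint_parts(checkpoint)
    if gene_ids is not None and list(gem_rows.gene_ids) != list(gene_ids):
        raise ValueError(
            "gene set of the input does not match the checkpoint "
            f"({gem_rows.gene_ids[:3]}... vs {list(gene_ids)[:3]}...)"
        )
    if vocab is None:
        raise ValueError("checkpoint lacks a label vocabulary")
    for lab in (source_label, target_label):
        if lab not in vocab:
            raise ValueError(f"unknown label {lab!r}; checkpoint labels are {vocab}")
    if already_normalized:
        X = np.asarray(gem_rows.values, dtype=np.float64)
    else:
        if scaler is None:
            raise ValueError("checkpoint lacks scaler parameters")
        X = apply_scaler(log2p1(gem_rows), scaler).values
    latent = ode_encode(denoiser, X, vocab.index(source_label), schedule, n_ode_steps)
    bridged = ode_decode(denoiser, latent, vocab.index(target_label), schedule, n_ode_steps)
    score = (bridged - X).mean(axis=0)
    return PerturbationResult(
        gene_ids=tuple(gem_rows.gene_ids),
        original=X,
        perturbed=bridged,
        per_gene_score=score,
        subset_name=subset_name,
    )


def pool_scores(results: list[PerturbationResult], k_sd: float = 2.0) -> pd.DataFrame:
    """Pool per-gene scores across disjoint subsets and call core genes.

    Core rule: strictly ``|score - mean| > k_sd * sd`` with mean/sd (population)
    taken over the pooled score distribution of all genes.  Genes must appear
    in exactly one subset.
    """
    genes, scores, subsets = [], [], []
    seen: set[str] = set()
    for r in results:
        for g, s in zip(r.gene_ids, r.per_gene_score):
            if g in seen:
                raise ValueError(f"gene {g!r} appears in more than one subset")
            seen.add(g)
            genes.append(g)
            scores.append(float(s))
            subsets.append(r.subset_name)
    scores_arr = np.array(scores)
    m = scores_arr.mean()
    sd = scores_arr.std()
    z = np.zeros_like(scores_arr) if sd == 0 else (scores_arr - m) / sd
    core = np.abs(scores_arr - m) > k_sd * sd if sd > 0 else np.zeros(len(genes), bool)
    return pd.DataFrame(
        {
            "gene": genes,
            "score": scores_arr,
            "direction": np.sign(scores_arr),
            "z": z,
            "core": core,
            "subset": subsets,
        }
    )


def correlate_perturbation_silhouette(
    subset_mean_abs_scores: list[float], silhouettes: list[float]
) -> float:
    """Pearson correlation between subset perturbation magnitude and silhouette."""
    x = np.asarray(subset_mean_abs_scores, dtype=np.float64)
    y = np.asarray(silhouettes, dtype=np.float64)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length lists with at least 3 entries")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero variance in an input")
    return float(stats.pearsonr(x, y).statistic)


def enrich(
    query_genes: set[str],
    annotation_sets: dict[str, list[str]],
    background: set[str],
    q_threshold: float = 1e-10,
) -> pd.DataFrame:
    """Hypergeometric over-representation with Benjamini-Yekutieli FDR control.

    One-sided tail probability of drawing at least the observed overlap when
    sampling ``|query|`` genes from the background; the BY adjustment is valid
    under arbitrary dependence between the annotation sets.  Rows with
    ``q < q_threshold`` are flagged significant.
    """
    if not background:
        raise ValueError("background gene set is empty")
    query = set(query_genes)
    if not query <= set(background):
        raise ValueError("query genes must be a subset of the background")
    N, n = len(background), len(query)
    names, ps, overlaps, set_sizes = [], [], [], []
    for name, genes in annotation_sets.items():
        members = set(genes) & set(background)
        k = len(query & members)
        K = len(members)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        names.append(name)
        ps.append(min(p, 1.0))
        overlaps.append(k)
        set_sizes.append(K)
    if names:
        _, q, _, _ = multipletests(ps, method="fdr_by")
    else:
        q = np.array([])
    df = pd.DataFrame(
        {
            "set": names,
            "set_size": set_sizes,
            "overlap": overlaps,
            "p": ps,
            "q": q,
            "significant": q < q_threshold if len(names) else [],
        }
    )
    return df.sort_values("p", kind="stable").reset_index(drop=True)
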