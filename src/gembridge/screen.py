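"""Gene-subset screening: partitioning, 2D embedding, silhouette scoring and
extreme-subset selection.

A gene-set collection is broken into disjoint fixed-size subsets; for each
subset the samples (restricted to those genes, on the normalized scale) are
embedded to 2D with UMAP and the separation of the two phenotype clusters is
summarized by the mean silhouette score.  Subsets whose scores sit more than
``k_sd`` standard deviations above (below) the mean over all screened subsets
are flagged as high (low) cluster potential; the high ones feed the
perturbation stage.

The silhouette here is the classical per-sample statistic
``s(i) = (b(i) - a(i)) / max(a(i), b(i))`` with a(i) the mean intra-cluster
distance to the *other* members and b(i) the smallest mean distance to
another cluster, computed on the 2D embedding with Euclidean distance;
singleton clusters contribute s(i) = 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .io import GEM

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSubset",
    "ScreenResult",
    "partition_gene_set",
    "embed_2d",
    "silhouette",
    "screen_subsets",
    "select_extremes",
    "random_background",
]

DEFAULT_N_NEIGHBORS = 90
DEFAULT_MIN_DIST = 0.3


@dataclass(frozen=True)
class GeneSubset:
    parent_set_name: str
    subset_index: int
    gene_ids: tuple[str, ...]


@dataclass(frozen=True)
class ScreenResult:
    subset: GeneSubset
    silhouette: float
    selected: str = "neither"  # {"high", "low", "neither"}


def partition_gene_set(
    genes: list[str],
    subset_size: int,
    seed: int = 0,
    parent_name: str = "geneset",
) -> list[GeneSubset]:
    """Shuffle and cut a gene set into disjoint subsets of exactly ``subset_size``.

    The trailing incomplete block is dropped so every subset is symmetric; an
    empty input yields an empty list.
    """
    if subset_size < 1:
        raise ValueError(f"subset_size must be >= 1, got {subset_size}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    n_full = len(genes) // subset_size
    subsets = []
    for k in range(n_full):
        idx = order[k * subset_size : (k + 1) * subset_size]
        subsets.append(
            GeneSubset(
                parent_set_name=parent_name,
                subset_index=k,
                gene_ids=tuple(genes[i] for i in idx),
            )
        )
    return subsets


def embed_2d(
    matrix: np.ndarray,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    min_dist: float = DEFAULT_MIN_DIST,
    seed: int = 0,
) -> np.ndarray:
    """UMAP 2D embedding with fixed neighborhood parameters and seed.

    When there are fewer than ``n_neighbors + 1`` samples the neighborhood is
    shrunk to ``n_samples - 1`` with a warning rather than failing.
    """
    import umap  # deferred: numba JIT import is slow

    matrix = np.asarray(matrix, dtype=np.float64)
    n = matrix.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to embed")
    if n_neighbors >= n:
        logger.warning(
            "n_neighbors=%d >= n_samples=%d; reducing to %d", n_neighbors, n, n - 1
        )
        n_neighbors = n - 1
    with warnings.catch_warnings():
        # umap warns that a fixed random_state disables parallelism; that
        # determinism is exactly what we want
        warnings.filterwarnings("ignore", category=UserWarning)
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            random_state=seed,
        )
        return np.asarray(reducer.fit_transform(matrix), dtype=np.float64)


def silhouette(coords: np.ndarray, labels) -> float:
    """Mean silhouette of a labelled 2D point set (Euclidean distance)."""
    coords = np.asarray(coords, dtype=np.float64)
    labels = np.asarray(labels)
    classes, inv = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("silhouette requires at least two clusters")
    D = cdist(coords, coords)
    n = len(coords)
    counts = np.bincount(inv)
    # mean distance from every point to every cluster
    sums = np.zeros((n, len(classes)))
    for c in range(len(classes)):
        sums[:, c] = D[:, inv == c].sum(axis=1)
    s = np.zeros(n)
    for i in range(n):
        c = inv[i]
        if counts[c] == 1:
            s[i] = 0.0
            continue
        a = sums[i, c] / (counts[c] - 1)
        b = np.min(
            [sums[i, k] / counts[k] for k in range(len(classes)) if k != c]
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def screen_subsets(
    gem: GEM,
    subsets: list[GeneSubset],
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    min_dist: float = DEFAULT_MIN_DIST,
    seed: int = 0,
) -> list[ScreenResult]:
    """Embed each gene subset's restricted matrix and score phenotype separation.

    ``gem`` must be labelled and already on the normalized scale.
    """
    if gem.labels is None:
        raise ValueError("screening requires a labelled GEM")
    results = []
    for sub in subsets:
        missing = [g for g in sub.gene_ids if g not in gem.gene_ids]
        if missing:
            raise ValueError(
                f"subset {sub.parent_set_name}#{sub.subset_index} has genes "
                f"missing from the matrix: {missing}"
            )
        coords = embed_2d(
            gem.subset_genes(list(sub.gene_ids)).values,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            seed=seed,
        )
        results.append(ScreenResult(subset=sub, silhouette=silhouette(coords, gem.labels)))
    return results


def select_extremes(results: list[ScreenResult], k_sd: float = 1.0) -> list[ScreenResult]:
    """Flag subsets beyond +/- k_sd population standard deviations from the mean."""
    if len(results) < 2:
        raise ValueError("need at least two screened subsets to select extremes")
    scores = np.array([r.silhouette for r in results])
    m, s = scores.mean(), scores.std()  # population sd: thresholding a census
    out = []
    for r in results:
        if r.silhouette > m + k_sd * s:
            sel = "high"
        elif r.silhouette < m - k_sd * s:
            sel = "low"
        else:
            sel = "neither"
        out.append(replace(r, selected=sel))
    return out


def random_background(
    gem: GEM,
    subset_size: int,
    n_reps: int,
    seed: int = 0,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    min_dist: float = DEFAULT_MIN_DIST,
    exclude_genes: list[str] | None = None,
) -> tuple[float, float]:
    """Mean and sd of silhouettes over repeated random gene draws.

    Mirrors the random-control protocol: ``n_reps`` subsets of ``subset_size``
    genes drawn uniformly from the matrix (optionally excluding e.g. planted
    signal genes), each screened exactly like a candidate subset.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    pool = [g for g in gem.gene_ids if not exclude_genes or g not in set(exclude_genes)]
    if len(pool) < subset_size:
        raise ValueError("not enough genes to draw a background subset")
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_reps):
        draw = [pool[i] for i in rng.choice(len(pool), size=subset_size, replace=False)]
        coords = embed_2d(
            gem.subset_genes(draw).values,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            seed=seed,
        )
        scores.append(silhouette(coords, gem.labels))
    scores = np.array(scores)
    return float(scores.mean()), float(scores.std())


def write_screen_report(results: list[ScreenResult], path) -> None:
    """TSV report: parent set, subset index, genes, silhouette, selection flag."""
    with open(path, "w") as fh:
        fh.write("parent_set\tsubset_index\tgenes\tsilhouette\tselected\n")
        for r in results:
            fh.write(
                f"{r.subset.parent_set_name}\t{r.subset.subset_index}\t"
                f"{','.join(r.subset.gene_ids)}\t{r.silhouette:.6f}\t{r.selected}\n"
            )
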