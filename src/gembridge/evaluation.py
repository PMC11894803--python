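"""Quality metrics for synthetic and perturbed expression data.

Two complementary views: maximum mean discrepancy (MMD) with a Gaussian
kernel compares whole sample distributions, and an RBF support-vector
classifier measures whether a model trained on real data assigns synthetic
rows their intended phenotype.  A report combines both against a
train-vs-test baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .io import GEM

__all__ = [
    "KernelParams",
    "mmd",
    "median_bandwidth",
    "classifier_accuracy",
    "build_eval_report",
]


@dataclass(frozen=True)
class KernelParams:
    """Gaussian kernel bandwidth; ``"median"`` uses the median pairwise distance."""

    sigma: float | str = "median"

    def __post_init__(self) -> None:
        if not isinstance(self.sigma, str) and self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if isinstance(self.sigma, str) and self.sigma != "median":
            raise ValueError(f"unknown bandwidth rule {self.sigma!r}")


def median_bandwidth(X: np.ndarray, Y: np.ndarray) -> float:
    """Median of the pooled pairwise Euclidean distances (the median heuristic)."""
    Z = np.vstack([X, Y])
    D = cdist(Z, Z)
    med = float(np.median(D[np.triu_indices_from(D, k=1)]))
    return med if med > 0 else 1.0


def mmd(X: np.ndarray, Y: np.ndarray, kernel: KernelParams = KernelParams()) -> float:
    """Biased (V-statistic) squared MMD with Gaussian kernel; always >= 0.

    mean k(X,X) + mean k(Y,Y) - 2 mean k(X,Y) with
    k(x,y) = exp(-||x-y||^2 / (2 sigma^2)), diagonal terms included.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    sigma = median_bandwidth(X, Y) if kernel.sigma == "median" else float(kernel.sigma)
    c = 1.0 / (2.0 * sigma**2)
    kxx = np.exp(-c * cdist(X, X, "sqeuclidean")).mean()
    kyy = np.exp(-c * cdist(Y, Y, "sqeuclidean")).mean()
    kxy = np.exp(-c * cdist(X, Y, "sqeuclidean")).mean()
    return float(kxx + kyy - 2.0 * kxy)


def _fit_svm(train_gem: GEM) -> SVC:
    train_gem.require_two_labels()
    return SVC(C=1.0, kernel="rbf", gamma="scale").fit(
        train_gem.values, np.asarray(train_gem.labels, dtype=str)
    )


def classifier_accuracy(train_gem: GEM, eval_gem: GEM) -> float:
    """RBF-SVM accuracy (percent) on ``eval_gem`` after training on ``train_gem``.

    Fixed hyper-parameters: C = 1, bandwidth 1 / (d * var) ("scale"); the
    result is deterministic given the inputs.
    """
    if train_gem.gene_ids != eval_gem.gene_ids:
        raise ValueError("train and eval matrices must share the same gene set")
    if eval_gem.labels is None:
        raise ValueError("eval GEM must be labelled")
    svm = _fit_svm(train_gem)
    pred = svm.predict(eval_gem.values)
    return float(np.mean(pred == np.asarray(eval_gem.labels, dtype=str)) * 100.0)


def build_eval_report(
    train: GEM,
    test: GEM,
    synthetic_by_size: dict[int, GEM],
    kernel: KernelParams = KernelParams(),
) -> pd.DataFrame:
    """Augmentation-quality table: a baseline row plus one row per feature size.

    For every feature size, restricted to that synthetic matrix's genes:
    baseline = MMD(test, train) and accuracy of the train-fitted classifier
    on the test split; model = MMD(synthetic, test) and accuracy of the same
    classifier on the synthetic rows with their intended labels.
    """
    rows = []
    for size in sorted(synthetic_by_size):
        syn = synthetic_by_size[size]
        if syn.n_genes != size:
            raise ValueError(f"synthetic GEM for size {size} has {syn.n_genes} genes")
        tr = train.subset_genes(syn.gene_ids)
        te = test.subset_genes(syn.gene_ids)
        rows.append(
            {
                "feature_size": size,
                "baseline_mmd": mmd(te.values, tr.values, kernel),
                "baseline_acc": classifier_accuracy(tr, te),
                "model_mmd": mmd(syn.values, te.values, kernel),
                "model_acc": classifier_accuracy(tr, syn),
            }
        )
    return pd.DataFrame(rows)
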