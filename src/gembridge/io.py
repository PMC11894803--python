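"""Readers and writers for gene expression matrices, label tables and GMT gene sets.

The on-disk matrix dialect is the tab-separated layout common to TCGA/GTEx
FPKM releases: a header row of sample ids, a leading gene-identifier column,
one row per gene.  Internally everything is held samples x genes because each
sample row is one data point for the diffusion model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GEM",
    "read_gem",
    "write_gem",
    "write_labels",
    "attach_labels",
    "merge_gems",
    "read_gmt",
    "write_gmt",
]


class GEMValidationError(ValueError):
    """Raised when a matrix, label table or gene-set file violates its contract."""


@dataclass
class GEM:
    """A labelled gene expression matrix, oriented samples x genes.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Expression values (FPKM-like, log2 or normalized scale depending on
        the pipeline stage).
    gene_ids : list of str
        Unique gene identifiers, one per column.
    sample_ids : list of str
        Unique sample identifiers, one per row.
    labels : ndarray of str, optional
        Per-sample phenotype label (e.g. ``"normal"`` / ``"tumor"``).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise GEMValidationError("values must be a 2-D samples x genes matrix")
        n_samples, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise GEMValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} columns"
            )
        if len(self.sample_ids) != n_samples:
            raise GEMValidationError(
                f"{len(self.sample_ids)} sample ids for {n_samples} rows"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise GEMValidationError(f"duplicate {name} ids: {sorted(dupes)}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (n_samples,):
                raise GEMValidationError("labels must have one entry per sample")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def label_vocabulary(self) -> list[str]:
        """Sorted distinct labels; empty when unlabeled."""
        if self.labels is None:
            return []
        return sorted({str(x) for x in self.labels})

    def require_two_labels(self) -> list[str]:
        vocab = self.label_vocabulary()
        if len(vocab) != 2:
            raise GEMValidationError(
                f"exactly two phenotype labels required, found {vocab!r}"
            )
        return vocab

    def subset_genes(self, genes: list[str]) -> "GEM":
        """Restrict to the given genes, in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise GEMValidationError(f"genes not in matrix: {missing}")
        cols = [index[g] for g in genes]
        return replace(self, values=self.values[:, cols], gene_ids=list(genes))

    def subset_samples(self, mask_or_indices) -> "GEM":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=None if self.labels is None else self.labels[idx],
        )

    def rows_with_label(self, label: str) -> "GEM":
        if self.labels is None:
            raise GEMValidationError("GEM is unlabeled")
        return self.subset_samples(self.labels == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


def _duplicates(ids) -> set:
    seen, dup = set(), set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# -- matrix I/O ----------------------------------------------------------------


def read_gem(path, orientation: str = "genes_as_rows") -> GEM:
    """Read a tab-separated expression matrix.

    ``"NA"`` and empty cells are replaced by 0 at read time, before any
    transform, so unexpressed genes survive the later log2(n+1) step as exact
    zeros.  Gzip input is accepted transparently.
    """
    if orientation not in ("genes_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    for name, ids in (("row", row_ids), ("column", col_ids)):
        dupes = _duplicates(ids)
        if dupes:
            raise GEMValidationError(
                f"duplicate {name} identifiers in {path}: {sorted(dupes)}"
            )
    raw = df.to_numpy(dtype=object)
    is_na = (raw == "NA") | (raw == "")
    filled = np.where(is_na, "0", raw)
    try:
        values = filled.astype(np.float64)
    except ValueError:
        for i in range(filled.shape[0]):
            for j in range(filled.shape[1]):
                try:
                    float(filled[i, j])
                except ValueError:
                    raise GEMValidationError(
                        f"non-numeric cell {filled[i, j]!r} at row "
                        f"{row_ids[i]!r}, column {col_ids[j]!r} in {path}"
                    ) from None
        raise  # pragma: no cover - unreachable
    if is_na.any():
        logger.info("replaced %d NA/empty cells with 0 in %s", int(is_na.sum()), path)
    if orientation == "genes_as_rows":
        return GEM(values=values.T, gene_ids=row_ids, sample_ids=col_ids)
    return GEM(values=values, gene_ids=col_ids, sample_ids=row_ids)


def write_gem(gem: GEM, path, orientation: str = "genes_as_rows") -> None:
    """Write the TSV dialect read by :func:`read_gem` (floats round-trip exactly)."""
    if orientation == "genes_as_rows":
        df = pd.DataFrame(gem.values.T, index=gem.gene_ids, columns=gem.sample_ids)
        df.index.name = "gene"
    elif orientation == "samples_as_rows":
        df = pd.DataFrame(gem.values, index=gem.sample_ids, columns=gem.gene_ids)
        df.index.name = "sample"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t", float_format=None)


def write_labels(gem: GEM, path) -> None:
    if gem.labels is None:
        raise GEMValidationError("GEM has no labels to write")
    with open(path, "w") as fh:
        for sid, lab in zip(gem.sample_ids, gem.labels):
            fh.write(f"{sid}\t{lab}\n")


def attach_labels(gem: GEM, labels_path) -> GEM:
    """Attach phenotype labels from a two-column ``sample_id<TAB>label`` table.

    Labels for samples absent from the matrix are ignored with a warning;
    matrix samples without a label are an error.
    """
    table: dict[str, str] = {}
    with open(labels_path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GEMValidationError(
                    f"{labels_path}: line {ln} has fewer than 2 fields"
                )
            table[parts[0]] = parts[1]
    missing = [s for s in gem.sample_ids if s not in table]
    if missing:
        raise GEMValidationError(f"label table missing samples: {missing}")
    extra = set(table) - set(gem.sample_ids)
    if extra:
        logger.warning(
            "label table has %d entries for unknown samples (ignored)", len(extra)
        )
    labels = np.array([table[s] for s in gem.sample_ids], dtype=object)
    return replace(gem, labels=labels)


def merge_gems(gems: list[GEM], label_per_gem: list[str]) -> GEM:
    """Concatenate source matrices on their shared genes, labelling by provenance.

    Gene order follows the first input filtered to the intersection.  Sample
    ids colliding across inputs are disambiguated with a ``.<k>`` suffix.
    """
    if len(gems) < 2:
        raise GEMValidationError("merge_gems needs at least two matrices")
    if len(label_per_gem) != len(gems):
        raise GEMValidationError("one label per input matrix required")
    shared = set(gems[0].gene_ids)
    for g in gems[1:]:
        shared &= set(g.gene_ids)
    if not shared:
        raise GEMValidationError("gene intersection of the inputs is empty")
    genes = [g for g in gems[0].gene_ids if g in shared]
    blocks, sample_ids, labels = [], [], []
    seen: dict[str, int] = {}
    for gem, lab in zip(gems, label_per_gem):
        blocks.append(gem.subset_genes(genes).values)
        for sid in gem.sample_ids:
            if sid in seen:
                seen[sid] += 1
                sample_ids.append(f"{sid}.{seen[sid]}")
            else:
                seen[sid] = 0
                sample_ids.append(sid)
        labels.extend([lab] * gem.n_samples)
    return GEM(
        values=np.vstack(blocks),
        gene_ids=genes,
        sample_ids=sample_ids,
        labels=np.array(labels, dtype=object),
    )


# -- GMT gene sets ---------------------------------------------------------------


def read_gmt(path) -> dict[str, list[str]]:
    """Read an MSigDB-dialect GMT file into an ordered name -> genes mapping.

    Duplicate genes within one line are dropped, keeping first occurrence.
    Genes absent from any particular matrix are *not* filtered here.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GEMValidationError(
                    f"{path}: line {ln} has {len(parts)} fields, expected >= 3"
                )
            name, _desc, genes = parts[0], parts[1], parts[2:]
            sets[name] = list(dict.fromkeys(g for g in genes if g))
    return sets


def write_gmt(collection: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
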