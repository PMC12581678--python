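"""Core data containers, Matrix Market / TSV readers and writers, and cell-level QC.

The central container is :class:`CellCountMatrix`, a sparse genes x cells UMI
count matrix with a per-cell metadata table.  Counts are raw (never normalised
here); downstream pseudo-bulk aggregation sums them unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Canonical per-cell metadata columns, one record per cell.
CELL_META_COLUMNS = [
    "cell_id",
    "sample_id",
    "study_id",
    "disease_state",
    "cell_type",
    "compartment",
    "chemistry",
    "seq_method",
]

#: Known disease-state labels; unknown labels are allowed but logged.
KNOWN_DISEASE_STATES = frozenset(
    {"control", "IPF", "ILD-not-IPF", "COPD", "COVID-19", "CLAD"}
)

COMPARTMENTS = frozenset({"epithelial", "endothelial", "stromal", "immune"})

STRUCTURAL_COMPARTMENTS = frozenset({"epithelial", "endothelial", "stromal"})


class FormatError(ValueError):
    """A file or table does not have the expected structure."""


class ValidationError(ValueError):
    """A container violates one of its declared invariants."""


@dataclass
class CellCountMatrix:
    """Sparse genes x cells integer UMI count matrix with per-cell metadata.

    Parameters
    ----------
    counts
        ``scipy.sparse`` matrix of shape ``(n_genes, n_cells)`` holding
        non-negative integer UMI counts.
    gene_ids
        Unique gene symbols (HGNC), length ``n_genes``.
    cell_meta
        One row per cell, in column order :data:`CELL_META_COLUMNS`.
    """

    counts: sp.spmatrix
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.shape[0] != len(self.gene_ids):
            raise ValidationError(
                f"counts has {self.counts.shape[0]} rows but {len(self.gene_ids)} gene ids"
            )
        if self.counts.shape[1] != len(self.cell_meta):
            raise ValidationError(
                f"counts has {self.counts.shape[1]} columns but "
                f"{len(self.cell_meta)} cell metadata records"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids are not unique")
        missing = [c for c in CELL_META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise ValidationError(f"cell_meta missing columns: {missing}")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValidationError("counts contain negative entries")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("counts contain non-integer entries")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)
        bad_comp = set(self.cell_meta["compartment"]) - COMPARTMENTS
        if bad_comp:
            raise ValidationError(f"unknown compartments: {sorted(bad_comp)}")
        unknown_disease = set(self.cell_meta["disease_state"]) - KNOWN_DISEASE_STATES
        if unknown_disease:
            logger.info(
                "cell_meta carries disease labels outside the canonical vocabulary: %s",
                sorted(unknown_disease),
            )
        self.cell_meta = self.cell_meta.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CellCountMatrix":
        """Return a new matrix restricted to cells where ``mask`` is True (order kept)."""
        mask = np.asarray(mask, dtype=bool)
        return CellCountMatrix(
            counts=self.counts[:, mask],
            gene_ids=self.gene_ids,
            cell_meta=self.cell_meta.loc[mask].reset_index(drop=True),
        )

    def subset_genes(self, mask: np.ndarray) -> "CellCountMatrix":
        mask = np.asarray(mask, dtype=bool)
        return CellCountMatrix(
            counts=self.counts[mask, :],
            gene_ids=self.gene_ids[mask],
            cell_meta=self.cell_meta,
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene biotype and housekeeping-class flags.

    ``biotype`` maps gene symbol -> "protein_coding" | "other"; genes absent
    from the table resolve to "other".  Ribosomal genes are recognised by the
    RPL/RPS symbol prefix and mitochondrial genes by the "MT-" prefix, the
    community convention for human HGNC symbols.
    """

    biotype: dict = field(default_factory=dict)

    @staticmethod
    def is_ribosomal(gene_id: str) -> bool:
        return gene_id.startswith("RPL") or gene_id.startswith("RPS")

    @staticmethod
    def is_mitochondrial(gene_id: str) -> bool:
        return gene_id.startswith("MT-")

    def get_biotype(self, gene_id: str) -> str:
        return self.biotype.get(gene_id, "other")

    @classmethod
    def protein_coding(cls, gene_ids) -> "GeneAnnotation":
        """Annotation declaring every listed gene protein-coding (synthetic cohorts)."""
        return cls(biotype={g: "protein_coding" for g in gene_ids})


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC cut-offs.

    Cells are removed when the number of detected features is below
    ``min_features`` or above ``max_features``, when the UMI total is below
    ``min_umi`` or above ``max_umi``, or when the mitochondrial fraction
    exceeds ``max_mito_fraction``.  All comparisons are strict, so boundary
    values survive (a cell with exactly 200 features, 400 UMIs and a 10%
    mitochondrial fraction is retained).
    """

    min_features: int = 200
    max_features: int = 7500
    min_umi: int = 400
    max_umi: int = 40000
    max_mito_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (self.min_features < self.max_features):
            raise ValidationError("min_features must be < max_features")
        if not (self.min_umi < self.max_umi):
            raise ValidationError("min_umi must be < max_umi")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValidationError("max_mito_fraction must lie in [0, 1]")


def read_cell_matrix(mtx_path, genes_path, cellmeta_path) -> CellCountMatrix:
    """Read a cohort from Matrix Market counts plus gene / cell annotation TSVs.

    Parameters
    ----------
    mtx_path
        Matrix Market coordinate file, genes x cells, integer entries.
    genes_path
        TSV with header; first column is the gene symbol.
    cellmeta_path
        TSV with header carrying :data:`CELL_META_COLUMNS`.
    """
    counts = scipy.io.mmread(str(mtx_path))
    if not np.allclose(counts.data, np.round(counts.data)):
        raise ValidationError(f"{mtx_path}: matrix entries are not integers")
    genes = pd.read_csv(genes_path, sep="\t")
    gene_ids = genes.iloc[:, 0].astype(str).to_numpy(dtype=object)
    cell_meta = pd.read_csv(cellmeta_path, sep="\t", dtype=str)
    if counts.shape[0] != len(gene_ids):
        raise FormatError(
            f"{genes_path}: lists {len(gene_ids)} genes but matrix has "
            f"{counts.shape[0]} rows"
        )
    if counts.shape[1] != len(cell_meta):
        raise FormatError(
            f"{cellmeta_path}: lists {len(cell_meta)} cells but matrix has "
            f"{counts.shape[1]} columns"
        )
    # Rows whose identifier is not a plausible HGNC symbol (e.g. bare Ensembl
    # ids) are dropped at read time.
    symbol_like = np.array(
        [not g.startswith("ENSG") for g in gene_ids], dtype=bool
    )
    if not symbol_like.all():
        logger.info("dropping %d non-symbol gene rows", int((~symbol_like).sum()))
        counts = sp.csr_matrix(counts)[symbol_like, :]
        gene_ids = gene_ids[symbol_like]
    return CellCountMatrix(counts=counts, gene_ids=gene_ids, cell_meta=cell_meta)


def write_cell_matrix(cells: CellCountMatrix, mtx_path, genes_path, cellmeta_path) -> None:
    """Write a cohort as MTX + TSV, the inverse of :func:`read_cell_matrix`."""
    scipy.io.mmwrite(str(mtx_path), cells.counts.tocoo(), field="integer")
    pd.DataFrame({"gene_id": cells.gene_ids}).to_csv(genes_path, sep="\t", index=False)
    cells.cell_meta.to_csv(cellmeta_path, sep="\t", index=False)


def qc_cells(cells: CellCountMatrix, thr: QCThresholds | None = None) -> CellCountMatrix:
    """Remove low-quality cells by feature count, UMI total and mitochondrial load.

    Retains exactly the cells with detected-feature count inside
    ``[min_features, max_features]``, UMI total inside ``[min_umi, max_umi]``
    and mitochondrial UMI fraction at most ``max_mito_fraction``; the stated
    extremes themselves survive.  Cell order is preserved and surviving cells'
    counts are untouched, so the operation is idempotent.
    """
    thr = thr or QCThresholds()
    csc = cells.counts.tocsc()
    n_features = np.asarray((csc > 0).sum(axis=0)).ravel()
    n_umi = np.asarray(csc.sum(axis=0)).ravel()
    mito_rows = np.array(
        [GeneAnnotation.is_mitochondrial(g) for g in cells.gene_ids], dtype=bool
    )
    mito_umi = (
        np.asarray(csc[mito_rows, :].sum(axis=0)).ravel()
        if mito_rows.any()
        else np.zeros_like(n_umi)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(n_umi > 0, mito_umi / np.maximum(n_umi, 1), 0.0)
    keep = (
        (n_features >= thr.min_features)
        & (n_features <= thr.max_features)
        & (n_umi >= thr.min_umi)
        & (n_umi <= thr.max_umi)
        & (mito_frac <= thr.max_mito_fraction)
    )
    if not keep.any():
        logger.warning("qc_cells removed every cell")
    return cells.subset_cells(keep)
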