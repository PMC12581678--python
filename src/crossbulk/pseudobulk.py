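"""Pseudo-bulk aggregation and the retention filters applied before modelling.

Cells are summed into one unit per (sample, cell type) pair — raw counts, no
per-cell normalisation — and units/genes are then filtered: units must carry
more than 25 contributing cells, genes must be protein-coding and neither
ribosomal nor mitochondrial, and genes must be detected (count > 0) in at
least one unit of every study present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_model import CellCountMatrix, GeneAnnotation, ValidationError

logger = logging.getLogger(__name__)

UNIT_META_COLUMNS = ["sample_id", "study_id", "disease_state", "cell_type", "n_cells"]


@dataclass
class PseudobulkMatrix:
    """Genes x units integer count matrix; units are (sample, cell type) pairs."""

    counts: np.ndarray                 # dense (n_genes, n_units) int64
    gene_ids: np.ndarray
    unit_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if sp.issparse(self.counts):  # pragma: no cover - defensive
            self.counts = self.counts.toarray()
        self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("pseudo-bulk counts must be non-negative")
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.shape[0] != len(self.gene_ids):
            raise ValidationError("gene_ids length mismatch")
        if self.counts.shape[1] != len(self.unit_meta):
            raise ValidationError("unit_meta length mismatch")
        keys = list(zip(self.unit_meta["sample_id"], self.unit_meta["cell_type"]))
        if len(set(keys)) != len(keys):
            raise ValidationError("(sample_id, cell_type) pairs must be unique")
        if (self.unit_meta["n_cells"] <= 0).any():
            raise ValidationError("units must have n_cells > 0")
        self.unit_meta = self.unit_meta.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    def subset_units(self, mask) -> "PseudobulkMatrix":
        mask = np.asarray(mask, dtype=bool)
        return PseudobulkMatrix(self.counts[:, mask], self.gene_ids,
                                self.unit_meta.loc[mask].reset_index(drop=True))

    def subset_genes(self, mask) -> "PseudobulkMatrix":
        mask = np.asarray(mask, dtype=bool)
        return PseudobulkMatrix(self.counts[mask, :], self.gene_ids[mask],
                                self.unit_meta)

    def to_tsv(self, counts_path, meta_path) -> None:
        pd.DataFrame(self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
                     columns=[f"{s}|{t}" for s, t in
                              zip(self.unit_meta["sample_id"],
                                  self.unit_meta["cell_type"])]) \
            .to_csv(counts_path, sep="\t")
        self.unit_meta.to_csv(meta_path, sep="\t", index=False)


def aggregate(cells: CellCountMatrix) -> PseudobulkMatrix:
    """Sum raw counts of all cells of each (sample, cell type) pair into one unit.

    Exact integer column sums; total count mass is conserved and the result
    is invariant to cell ordering.  Empty input yields an empty matrix.
    """
    meta = cells.cell_meta
    if len(meta) == 0:
        return PseudobulkMatrix(
            np.zeros((cells.n_genes, 0), dtype=np.int64), cells.gene_ids,
            pd.DataFrame(columns=UNIT_META_COLUMNS))
    keys = pd.MultiIndex.from_frame(meta[["sample_id", "cell_type"]])
    uniq, codes = np.unique(np.asarray(keys.to_numpy(), dtype=object),
                            return_inverse=True)
    # indicator matrix cells x units, then one sparse matmul
    n_units = len(uniq)
    ind = sp.csr_matrix(
        (np.ones(len(meta)), (np.arange(len(meta)), codes)),
        shape=(len(meta), n_units),
    )
    counts = np.asarray((cells.counts @ ind).todense()).astype(np.int64)
    rows = []
    for u, (sample_id, cell_type) in enumerate(uniq):
        members = meta.loc[codes == u]
        rows.append({
            "sample_id": sample_id,
            "study_id": members["study_id"].iloc[0],
            "disease_state": members["disease_state"].iloc[0],
            "cell_type": cell_type,
            "n_cells": int(len(members)),
        })
    return PseudobulkMatrix(counts, cells.gene_ids, pd.DataFrame(rows))


def filter_units(pb: PseudobulkMatrix, min_cells: int = 26) -> PseudobulkMatrix:
    """Retain units whose contributing-cell number is at least ``min_cells``.

    The default of 26 keeps exactly the units with more than 25 cells.
    """
    keep = (pb.unit_meta["n_cells"] >= min_cells).to_numpy()
    dropped = pb.unit_meta.loc[~keep]
    if len(dropped):
        logger.info("filter_units dropped %d unit(s): %s", len(dropped),
                    list(zip(dropped["sample_id"], dropped["cell_type"])))
    if not keep.any():
        logger.warning("filter_units removed every unit")
    return pb.subset_units(keep)


def filter_genes(pb: PseudobulkMatrix, ann: GeneAnnotation) -> PseudobulkMatrix:
    """Keep protein-coding genes, dropping ribosomal and mitochondrial ones."""
    keep = np.array([
        ann.get_biotype(g) == "protein_coding"
        and not GeneAnnotation.is_ribosomal(g)
        and not GeneAnnotation.is_mitochondrial(g)
        for g in pb.gene_ids
    ])
    return pb.subset_genes(keep)


def filter_by_study_presence(pb: PseudobulkMatrix) -> PseudobulkMatrix:
    """Keep genes detected (count > 0) in at least one unit of every study present."""
    studies = pb.unit_meta["study_id"].unique()
    if len(studies) <= 1:
        logger.info("filter_by_study_presence: single study, no-op")
        return pb.subset_genes(np.ones(pb.n_genes, dtype=bool))
    keep = np.ones(pb.n_genes, dtype=bool)
    for s in studies:
        cols = (pb.unit_meta["study_id"] == s).to_numpy()
        keep &= (pb.counts[:, cols] > 0).any(axis=1)
    return pb.subset_genes(keep)


def standard_filter_chain(
    pb: PseudobulkMatrix,
    ann: GeneAnnotation,
    min_cells: int = 26,
) -> PseudobulkMatrix:
    """Canonical pipeline order: units -> gene classes -> per-study presence."""
    return filter_by_study_presence(filter_genes(filter_units(pb, min_cells), ann))
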