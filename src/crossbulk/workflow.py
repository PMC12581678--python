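"""High-level composition of the comparative pipeline.

Wires together pseudo-bulk aggregation, filtering, the NB contrast fits and
the calling rules for the standard multi-disease analysis: every disease is
contrasted against control and against every other disease from one fitted
model per cell-type slice, and the common / disease-unique callers are
applied to the resulting tables.
"""

from __future__ import annotations

from dataclasses import dataclass

from .diffmodel import DesignSpec, DETable, fit_contrasts
from .io_model import CellCountMatrix, GeneAnnotation, ValidationError, qc_cells
from .pseudobulk import PseudobulkMatrix, aggregate, standard_filter_chain
from .signatures import CallCriteria, CallResult, call_common_genes, \
    call_disease_unique_genes, combine_calls


@dataclass
class ComparativeResult:
    """Differential tables plus the common / disease-unique calls."""

    de: DETable
    common: CallResult
    unique: CallResult
    combined: CallResult
    diseases: list


def prepare_pseudobulk(
    cells: CellCountMatrix,
    annotation: GeneAnnotation | None = None,
    min_cells: int = 26,
    run_qc: bool = True,
) -> PseudobulkMatrix:
    """QC cells, aggregate to pseudo-bulk and apply the retention filters."""
    if run_qc:
        cells = qc_cells(cells)
    if annotation is None:
        annotation = GeneAnnotation.protein_coding(cells.gene_ids)
    return standard_filter_chain(aggregate(cells), annotation, min_cells)


def comparative_calls(
    pb: PseudobulkMatrix,
    criteria: CallCriteria | None = None,
    strategy: str = "covariate",
    batch_col: str | None = "study_id",
) -> ComparativeResult:
    """Fit all disease-vs-control and pairwise contrasts; call common and
    disease-unique genes at the published criteria."""
    states = list(pb.unit_meta["disease_state"].unique())
    if "control" not in states:
        raise ValidationError("comparative calling requires control units")
    diseases = [s for s in states if s != "control"]
    if not diseases:
        raise ValidationError("no disease units present")
    contrasts = [(f"{d}_vs_control", d, "control") for d in diseases]
    contrasts += [(f"{a}_vs_{b}", a, b)
                  for i, a in enumerate(diseases) for b in diseases[i + 1:]]
    design = DesignSpec(batch_col=batch_col, contrasts=contrasts)
    de = fit_contrasts(pb, design, strategy=strategy)

    tables = {d: de.for_contrast(f"{d}_vs_control") for d in diseases}
    pct = {d: de.group_pct_expressed[d] for d in diseases}
    common = call_common_genes(tables, pct, criteria)
    if len(diseases) >= 2:
        pairwise = {(a, b): de.for_contrast(f"{a}_vs_{b}")
                    for i, a in enumerate(diseases) for b in diseases[i + 1:]}
        unique = call_disease_unique_genes(tables, pairwise,
                                           de.group_median_logcpm, pct,
                                           criteria)
    else:
        unique = CallResult()
    return ComparativeResult(de=de, common=common, unique=unique,
                             combined=combine_calls(common, unique),
                             diseases=diseases)
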