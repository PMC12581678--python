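"""Cell-level QC and pseudo-bulk aggregation with the retention filters.

Cells outside the feature/UMI/mitochondrial bounds are dropped, raw counts
are summed into one unit per (sample, cell type), and units with 25 or fewer
cells, non-protein-coding / ribosomal / mitochondrial genes, and genes not
detected in every study are removed.
"""

from crossbulk import (CohortConfig, GeneAnnotation, aggregate,
                       filter_by_study_presence, filter_genes, filter_units,
                       generate_cohort, qc_cells)

cells, _ = generate_cohort(CohortConfig(seed=2, n_genes=800,
                                        cells_per_sample=120))
kept = qc_cells(cells)
print(f"QC: {kept.n_cells} of {cells.n_cells} cells pass the "
      "feature (200-7,500), UMI (400-40,000) and mitochondrial (<=10%) bounds")

pb = aggregate(kept)
print(f"pseudo-bulk: {pb.n_units} (sample, cell type) units; "
      f"count mass conserved: {pb.counts.sum() == kept.counts.sum()}")

pb = filter_units(pb)                                  # > 25 cells per unit
ann = GeneAnnotation.protein_coding(pb.gene_ids)
pb = filter_by_study_presence(filter_genes(pb, ann))   # gene classes + presence
print(f"after filters: {pb.n_genes} genes x {pb.n_units} units")
print(pb.unit_meta.head(4).to_string(index=False))
print("each row is one pseudo-bulk unit: its sample, study, disease state "
      "and the number of cells summed into it")
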