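# crossbulk

Cross-disease pseudo-bulk comparison for lung single-cell transcriptomics.

Integrated single-cell compendia of fibrotic lung disease — idiopathic
pulmonary fibrosis (IPF), non-IPF interstitial lung disease, COPD, COVID-19
fibrosis and chronic lung allograft dysfunction (CLAD) — mix many studies,
chemistries and pipelines, so naive per-cell statistics confound technical
structure with biology. `crossbulk` implements the pseudo-bulk comparative
workflow for such compendia, for computational biologists analysing
multi-study cohorts:

* **Pseudo-bulk modelling.** Raw UMI counts are summed into one unit per
  (sample, cell type); units with ≤ 25 cells, non-protein-coding /
  ribosomal / mitochondrial genes, and genes not detected in every study
  are removed. Per gene *g* and unit *j* the model is
  `y_gj ~ NB(mu_gj, alpha_g)` with
  `log mu_gj = x_j' beta_g + log(N_j f_j)`, where `N_j f_j` is the
  TMM-scaled effective library size and the design contains disease state
  plus either study as a batch covariate or, alternatively, a
  ComBat-seq-style count-level quantile adjustment. Dispersions `alpha_g`
  are shrunk toward a mean–dispersion trend by empirical Bayes; contrasts
  are tested by moderated-t Wald statistics with an empirical-null scale
  calibration, and p-values are Benjamini–Hochberg adjusted per contrast.
* **Decision rules.** *Common genes*: adjusted p < 0.05, |fold change| ≥
  1.35 vs control, expressed-unit fraction > 0.1 (up) / 0.6 (down), the
  same direction and significance in **every** disease. *Disease-unique
  genes*: additionally ≥ 2-fold and significantly higher than **each**
  other disease, with the strictly highest group median logCPM.
  *Core cell-state signature* (e.g. the aberrant basaloid KRT17⁺KRT5⁻
  state): FDR < 0.05 against the average of the other cell types, ≥ 2-fold,
  and a strictly higher median logCPM than each other cell type.
  Over-representation of called sets is tested by one-sided hypergeometric
  with BH q-values.
* **Technical audits.** Chemistry-biased genes by Cook's distance (> 3× the
  mean) on the between-chemistry regression of per-gene mean expression;
  genome-build fingerprinting via the SEPP1 → SELENOP symbol rename;
  study clustering by Jaccard distance on gene-presence sets with complete
  linkage; classical MDS of pseudo-bulk logCPM profiles.
* **Donor–recipient chimerism.** From cell × variant allele counts:
  variant filtering (≥ 20 UMIs, ≥ 10% minor alleles, population AF > 5%),
  a two-genotype binomial-mixture EM with a doublet component, exclusion of
  cells assigned with probability < 0.9, donor assignment to the
  structurally dominant genotype group, and per-(patient, cell type)
  recipient proportions with totals < 20 reported as not applicable.
* **Synthetic cohorts with planted truth.** A generator emulates the
  statistical structure of such compendia — multi-study batch effects,
  NB counts, per-sample biological variability, chemistry biases, planted
  common/unique/signature gene sets, two-genotype mixtures with doublets —
  so every stage is testable without any download.

## Worked example

```python
from crossbulk import CohortConfig, generate_cohort, prepare_pseudobulk, \
    comparative_calls

cells, truth = generate_cohort(CohortConfig(seed=1))
pb = prepare_pseudobulk(cells)          # QC -> aggregate -> filters
res = comparative_calls(pb)             # all contrasts + calling rules
```

Running `python examples/common_and_unique_genes.py` (which adds scoring
against the planted truth and an enrichment test) prints:

```
common genes called: 27 (planted 30, recovered 27)
disease-unique genes called: 97 (planted 100, recovered 97)
  unique to CLAD: 20
  unique to COPD: 19
  unique to COVID-19: 18
  unique to ILD-not-IPF: 20
  unique to IPF: 20

over-representation of the called common set:
                overlap  set_size         p         q  significant
planted_common       27        30  0.000000  0.000000         True
random_set            1        30  0.336857  0.336857        False
```

27 of 30 planted common genes (fold change 2, six samples per arm) are
recovered with no false calls, 97 of 100 planted disease-unique genes are
assigned to the correct disease, and the called set is over-represented in
the planted set but not in an arbitrary one. The other scripts in
`examples/` demonstrate QC/aggregation, single-contrast differential
expression, the core-signature derivation, the technical audits and the
chimerism pipeline, each printing what it computes and what the numbers
mean.

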