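# Methods

This note records the statistical model, the choices made where the design
was open, and what the synthetic cohorts do and do not emulate. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Pseudo-bulk model

Cells passing QC (features in [200, 7,500], UMIs in [400, 40,000],
mitochondrial fraction ≤ 10%; all bounds inclusive, since the exclusion
rules are strict inequalities) are summed per (sample, cell type) into
integer pseudo-bulk units. Units with 25 or fewer cells are dropped, genes
are restricted to protein-coding symbols with ribosomal (RPL/RPS) and
mitochondrial (MT-) genes removed — prefix conventions for human HGNC
symbols, since no explicit gene list is part of the design — and a gene
must be detected (count > 0) in at least one unit of every study present.
"Detected" is the minimal zero/non-zero reading; no CPM threshold is
imposed. The presence rule is applied within the analysis slice (the cell
type under analysis); bookkeeping at whole-sample granularity is the noted
alternative.

Counts are modelled per gene as NB(mu, alpha) with Var = mu + alpha·mu²,
log link, and offset log(N_j·f_j) where f_j are TMM scaling factors
(30% trim on log-ratios, 5% on average abundance, precision weights,
largest-library unit as reference, factors normalised to geometric mean 1).
logCPM uses a prior count (default 0.5) scaled per unit in proportion to
its effective library size, so proportional count columns map to identical
logCPM columns.

### Fitting

All genes share a design matrix, so the IRLS updates are vectorised across
genes: each iteration reduces to a batched solve of p×p systems. Genewise
dispersion is estimated by Cox–Reid adjusted profile likelihood on a
log-spaced grid with quadratic refinement. The mean–dispersion trend is
fitted per expression bin by maximising the *summed* APL of the bin's genes
(a common-dispersion fit; the sum is far less skewed than the median of
genewise maximisers, which is biased low at moderate counts). Genewise
estimates are shrunk toward the trend on the log scale with an
empirically estimated weight: the sampling variance of each log-dispersion
is read off the APL curvature at its maximum, the robust excess spread of
the genewise estimates around the trend gives the prior variance, and the
weight is v_sampling / (v_sampling + v_prior). The implied prior degrees of
freedom (2 / prior variance) are added to the residual degrees of freedom
of the moderated-t reference used for Wald contrasts.

Two further calibration layers matter at pseudo-bulk sample sizes
(tens of units):

* the t reference with moderated degrees of freedom, rather than a normal
  reference, absorbs the variability of the plugged-in dispersions;
* an empirical-null scale calibration divides all Wald statistics of a fit
  by the scale of their central null component, estimated by two-quantile
  matching (50th/80th percentiles of |z| pooled across contrasts, with the
  null fraction treated as unknown so that true signals — which occupy only
  the extreme ranks — do not bias the scale). The calibration assumes most
  genes are null, is clipped to [0.95, 1.3], and is skipped for gene
  universes under 500. It corrects the few-percent understatement of
  plug-in standard errors that otherwise accumulates into visible
  non-uniformity over thousands of p-values.

Contrasts are linear combinations of coefficients: disease vs control,
disease vs disease, or a target level against the equally weighted average
of the other levels (used for the core signature). BH adjustment is applied
within each contrast. Fold-change thresholds are applied to the estimated
log2FC post hoc, not via a threshold-aware test. Non-convergent genes are
reported with missing p-values.

### Batch handling

Two strategies are exposed, because different analyses in this workflow
family use either: `covariate` includes study as a design factor;
`count_adjust` first maps counts through a ComBat-seq-style adjustment —
per gene, an NB GLM with group and batch effects is fitted, and each count
is carried through the midpoint quantile of its batch-specific NB to the
inverse CDF of the batch-free NB (batch coefficient replaced by the
size-weighted mean batch effect), rounded and clamped at zero. Single-batch
input is returned unchanged; a batch perfectly confounded with group raises
an error pointing to the covariate strategy. Group medians of logCPM are
reported after batch handling (fitted study effects, centred across
studies, are subtracted under the covariate strategy).

## Calling rules

The thresholds are the published ones: adjusted p < 0.05; fold change
≥ 1.35 vs control and ≥ 2 vs other diseases or other cell types;
expressed-unit fraction > 0.1 for upregulated and > 0.6 for downregulated
genes. Design choices where the rules were underspecified:

* "expressed" means a unit with count > 0; the cut-off is strict.
* The disease-unique clause "higher than other diseases" is evaluated
  pairwise against each other disease (adjusted p < 0.05 per pair), not
  against a pooled rest; pairwise is the default behaviour.
* "Median logCPM ranking highest" is a strict maximum; ties yield no call.
* Downregulated disease-unique genes are not called (only upregulated DUGs
  are part of the workflow); the 0.1 expressed-fraction cut-off applies.
* When both callers fire on the same gene, the common call wins: a gene
  consistently regulated in every disease is by definition not unique to
  one (`combine_calls`).
* For the core signature, the "average of other cell types" is an explicit
  contrast vector weighting the other cell-type levels equally, and the
  model includes sample identity as a covariate.

## Technical audits

The chemistry audit averages depth-normalised (counts per 10k, log1p)
expression per gene within each chemistry — the common single-cell
convention; raw-count means are available by flag — and regresses one
condition on the other by OLS with intercept. Cook's distance is computed
algebraically (r_i² h_i / (p s² (1−h_i)²)) and genes with D > 3× the mean D
are flagged; the algebraic form is verified against the leave-one-out refit
definition in the tests. A numerically exact fit (zero residual variance)
yields all-zero distances and no flags. Genome builds are dated by the
SEPP1 → SELENOP rename: SEPP1 present → outdated; SELENOP without SEPP1 →
current; neither → indeterminate. Study similarity uses Jaccard distance on
binary gene presence with complete-linkage clustering (lexicographic label
order fixes tie behaviour); the dendrogram is serialised as a merge list
with heights. MDS is classical (eigendecomposition of the doubly centred
squared-distance matrix), returning the top-2 principal coordinates.

## Chimerism

Variants are filtered on pooled UMIs (≥ 20), pooled minor-allele fraction
(≥ 0.10) and population allele frequency (> 0.05 when provided). The
demultiplexer is a two-cluster binomial mixture: per-variant alt dosages on
{0, 0.5, 1} per cluster, a doublet component with averaged dosages, a fixed
doublet prior (default 0.05), allele error rate 0.01, and EM whose discrete
M-step maximises the expected complete-data likelihood jointly over the
3×3 dosage pairs per variant — monotone in likelihood by construction.
Initialisation is k-means on per-cell alt-fraction profiles, 10 seeded
restarts, best likelihood kept; cluster labels are canonicalised by total
dosage so runs are reproducible, and carry no biological meaning until the
donor rule is applied. Collapsed clusters (identical dosage vectors) leave
all cells unassigned with a warning. Cells whose best singlet posterior is
below 0.9 are unassigned; doublet-called cells are excluded. The genotype
group with the higher fraction of members in structural compartments
(epithelial + endothelial + stromal, configurable) is the donor; an exact
tie raises rather than choosing silently. Proportions are
recipient/(donor+recipient) per (patient, cell type), with totals under 20
reported as not applicable.

## Synthetic cohorts

The generator draws per-cell counts NB(mu, phi) with mu =
baseline × cell-type factor × disease factor × study batch factor ×
chemistry factor × per-sample factor × cell size factor. Defaults define
the reference study conditions used throughout the tests: 2 studies, 5
disease states + control, 6 samples per arm (split across studies), 200
cells per sample of the analysed cell type, 2,000 genes with log-normal
baseline means (median 0.5 UMI/cell, log-sd 1.5 — per-cell libraries of a
few thousand UMIs over a reduced gene universe), log-normal cell-level
dispersions (median 0.1), per-sample biological variability of 0.3 on the
log2 scale (donor-to-donor variation; this, not counting noise, bounds the
attainable power), study batch effects of s.d. 0.5 log2 per gene, and
planted sets: 30 common genes (20 up, 10 down) at fold change 2, 20 unique
genes per disease at fold change 2 vs control.

Choices worth stating explicitly:

* **Planted genes are drawn from the expressed transcriptome** (baseline
  mean ≥ 0.5 UMI/cell by default). Planted effects emulate reported disease
  genes, which are well-expressed markers; a fold change planted on a gene
  with a handful of counts per unit is unrecoverable by any method at
  cohort-scale sample sizes and would measure the depth distribution rather
  than the callers.
* **Unique genes sit below baseline in the other diseases**
  (fold 2.0 vs control, 2.8 vs other diseases by default). The calling rule
  demands an *estimated* ≥ 2-fold difference from every other disease; truth
  exactly at the threshold would make the call a coin flip on estimation
  noise, so the planted pairwise ratio clears the threshold with margin
  while the vs-control ratio stays at the stated fold change 2.
* **Dual-signature genes** (for exercising the median-dominance exclusion)
  are elevated in the target cell type and 1.5× more strongly in one other
  cell type, so that significance and fold-change criteria pass and only
  dominance can exclude them — deterministically, not by a tie of noisy
  medians.
* Batch effects are multiplicative per study and gene; an optional
  fixed-magnitude shift with random sign per gene (used by the
  batch-adjustment checks) avoids planting a pure library-size change,
  which normalisation would absorb trivially.
* Allele mixtures: dosages uniform on {0, 0.5, 1}, a configured fraction of
  variants discordant between genotypes, Poisson depth per (cell, variant),
  binomial alt counts with error 0.01, doublets averaging the dosages.

What the generator does **not** emulate: gene–gene correlation, ambient
RNA, expression-level doublets, zero-inflation beyond NB, spliced/unspliced
structure, and realistic gene-symbol universes. Passing tests therefore
demonstrate that the statistical machinery and decision rules behave as
specified under an honest NB world with batch structure — not that any
particular biological result from real compendia is reproduced. The
published headline numbers (≈1.6M integrated cells, a 360-gene KRT17⁺KRT5⁻
signature, 274 chemistry-biased genes, 6 common CLAD AT2 genes) depend on
many external datasets and are out of scope.

## Problem sizes and numerics

The test suite and acceptance script run the reference cohorts described
above (36 pseudo-bulk units per comparative fit; 80 units for the
signature; 20 effect-free replicates for calibration; 1,000-cell genotype
mixtures), sizes at which the full pipeline completes in minutes on one
CPU. Numerical details: IRLS with ridge 1e-8 on the normal equations and
linear-predictor clipping at ±30; dispersion grid 1e-4–5 (22 points);
EM convergence at 1e-6 relative log-likelihood; BH implemented as the
standard step-up with NaN propagation for non-convergent genes. Library
sizes after count adjustment are preserved to within a few percent by
centring the removed batch effects.

## Known limitations

Wald-type inference with plug-in dispersions is approximate at very small
unit counts (< ~10 units); quasi-likelihood F-tests and mixed models are
deliberately out of scope. The demultiplexer handles exactly two genotypes
and ignores ambient-RNA contamination of allele counts. The count-level
batch adjustment assumes batch effects act on NB location per gene, not on
dispersion. Per-study QC overrides are supported through `QCThresholds`
but no override table ships with the package.
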