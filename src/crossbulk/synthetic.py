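"""Synthetic multi-study, multi-disease cohorts and genotype mixtures with planted truth.

The generator emulates the statistical structure of an integrated lung
single-cell compendium: several studies with study-level multiplicative batch
effects, five disease states plus controls, negative-binomial UMI counts with
gene-level dispersion, per-sample biological variability, chemistry-specific
gene biases, and two-genotype cell mixtures with doublets.  Every planted
effect (common genes, disease-unique genes, cell-state signature genes,
chemistry-biased genes, genotype labels) is recorded in a
:class:`SyntheticTruth` so downstream callers can be scored against ground
truth without any external data.

The negative binomial is parameterised by mean ``mu`` and dispersion ``phi``
with ``Var = mu + phi * mu**2``.  All effects act multiplicatively on the
mean, so the expected pseudo-bulk disease/control ratio of a planted gene
equals its configured fold change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_model import CellCountMatrix, ValidationError

DEFAULT_DISEASES = ("IPF", "ILD-not-IPF", "COPD", "COVID-19", "CLAD")


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults describe the reference study conditions used throughout the test
    suite: 2 studies, 5 diseases + control with 6 samples per arm, one
    analysed cell type, 2,000 genes, study batch s.d. of 0.5 on the log2
    scale, and planted common / disease-unique gene sets at fold change 2.
    """

    n_studies: int = 2
    diseases: tuple = DEFAULT_DISEASES
    samples_per_arm: int = 6
    cells_per_sample: int = 200
    n_genes: int = 2000
    cell_types: tuple = ("AT2",)
    cell_type_proportions: tuple | None = None
    compartment: str = "epithelial"

    # expression model
    baseline_log_mean: float = float(np.log(0.5))
    baseline_log_sd: float = 1.5
    dispersion_log_mean: float = float(np.log(0.1))
    dispersion_log_sd: float = 0.5
    cell_size_log_sd: float = 0.3          # natural-log s.d. of per-cell size factors
    sample_log2_sd: float = 0.3            # per-sample biological variability (log2)
    batch_log2_sd: float = 0.5             # per-study per-gene batch effect (log2)
    batch_log2_shift: float = 0.0          # fixed-magnitude per-gene shift, random sign

    # planted effects
    n_common_up: int = 20
    n_common_down: int = 10
    common_fc: float = 2.0
    n_unique_per_disease: int = 20
    unique_fc_vs_control: float = 2.0
    unique_fc_vs_others: float = 2.8
    n_signature: int = 0
    signature_fc: float = 4.0
    #: dual-signature genes are elevated in the target cell type and *more*
    #: strongly (by this multiplier on signature_fc) in one other cell type,
    #: so that only the median-dominance criterion can exclude them
    n_dual_signature: int = 0
    dual_signature_factor: float = 1.5
    target_cell_type: str | None = None
    n_chemistry_bias: int = 0
    chemistry_bias_multiplier: float = 4.0
    #: planted sets are drawn from genes whose baseline mean is at least this
    #: (UMI per cell): planted effects emulate reported disease genes, which
    #: are expressed, and a fold change on an unexpressed gene is not a
    #: recoverable signal at cohort-scale sample sizes
    planted_min_baseline: float = 0.5

    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_type_proportions is None:
            k = len(self.cell_types)
            self.cell_type_proportions = tuple([1.0 / k] * k)
        if len(self.cell_type_proportions) != len(self.cell_types):
            raise ValidationError("one proportion per cell type required")
        if abs(sum(self.cell_type_proportions) - 1.0) > 1e-8:
            raise ValidationError("cell_type_proportions must sum to 1")
        if self.cells_per_sample <= 0 or self.samples_per_arm <= 0:
            raise ValidationError("cohort must contain cells")
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        for fc in (self.common_fc, self.unique_fc_vs_control,
                   self.unique_fc_vs_others, self.signature_fc,
                   self.chemistry_bias_multiplier):
            if fc <= 0:
                raise ValidationError("fold changes must be positive")
        n_planted = (self.n_common_up + self.n_common_down
                     + self.n_unique_per_disease * len(self.diseases)
                     + self.n_signature + self.n_dual_signature
                     + self.n_chemistry_bias)
        if n_planted > self.n_genes:
            raise ValidationError("more planted genes than genes in the cohort")
        if self.target_cell_type is None:
            self.target_cell_type = self.cell_types[0]

    def to_json(self, path) -> None:
        d = asdict(self)
        for k in ("diseases", "cell_types", "cell_type_proportions"):
            d[k] = list(d[k])
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("diseases", "cell_types", "cell_type_proportions"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators, serialisable as JSON."""

    common_up: list = field(default_factory=list)
    common_down: list = field(default_factory=list)
    unique: dict = field(default_factory=dict)          # disease -> [gene]
    signature: list = field(default_factory=list)
    dual_signature: dict = field(default_factory=dict)  # gene -> second cell type
    chemistry_bias: list = field(default_factory=list)
    batch_log2: dict = field(default_factory=dict)      # study -> per-gene list
    genotype: list = field(default_factory=list)        # per cell: g1 | g2 | doublet
    dosage_g1: list = field(default_factory=list)
    dosage_g2: list = field(default_factory=list)
    donor_fraction: dict = field(default_factory=dict)  # (patient, cell_type) label -> fraction

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    @property
    def all_common(self) -> list:
        return list(self.common_up) + list(self.common_down)

    @property
    def all_unique(self) -> list:
        return [g for genes in self.unique.values() for g in genes]


def _study_chemistry(study_index: int) -> str:
    return "3'V2" if study_index % 2 == 0 else "5'"


def generate_cohort(cfg: CohortConfig) -> tuple[CellCountMatrix, SyntheticTruth]:
    """Draw a cohort of NB-distributed UMI counts with planted effects.

    Per-cell counts are NB with mean
    ``baseline x cell-type factor x disease factor x study batch factor x
    chemistry factor x sample factor x cell size factor`` and per-gene
    dispersion.  Identical config (including seed) yields identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(G)], dtype=object)

    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, G))
    phi = np.exp(rng.normal(cfg.dispersion_log_mean, cfg.dispersion_log_sd, G))

    # --- planted gene sets (disjoint, drawn from expressed genes) ---
    eligible = np.flatnonzero(baseline >= cfg.planted_min_baseline)
    order = rng.permutation(eligible)
    cursor = 0

    def take(n):
        nonlocal cursor
        if cursor + n > len(order):
            raise ValidationError(
                "not enough expressed genes to host the planted sets; "
                "lower planted_min_baseline or raise n_genes"
            )
        idx = order[cursor:cursor + n]
        cursor += n
        return idx

    idx_common_up = take(cfg.n_common_up)
    idx_common_down = take(cfg.n_common_down)
    idx_unique = {d: take(cfg.n_unique_per_disease) for d in cfg.diseases}
    idx_signature = take(cfg.n_signature)
    idx_dual = take(cfg.n_dual_signature)
    idx_chem = take(cfg.n_chemistry_bias)

    diseases = list(cfg.diseases)
    states = ["control"] + diseases

    # disease factor matrix: gene x state multiplier on the mean
    disease_factor = {s: np.ones(G) for s in states}
    for d in diseases:
        disease_factor[d][idx_common_up] = cfg.common_fc
        disease_factor[d][idx_common_down] = 1.0 / cfg.common_fc
    for d in diseases:
        disease_factor[d][idx_unique[d]] = cfg.unique_fc_vs_control
        for other in diseases:
            if other != d:
                # unique genes sit below baseline in the other diseases so the
                # pairwise ratio exceeds the vs-control ratio
                disease_factor[other][idx_unique[d]] = (
                    cfg.unique_fc_vs_control / cfg.unique_fc_vs_others
                )

    # cell-type factor: signature genes elevated in the target cell type
    ct_factor = {t: np.ones(G) for t in cfg.cell_types}
    ct_factor[cfg.target_cell_type][idx_signature] = cfg.signature_fc
    dual_partner = {}
    others = [t for t in cfg.cell_types if t != cfg.target_cell_type]
    for j, gi in enumerate(idx_dual):
        ct_factor[cfg.target_cell_type][gi] = cfg.signature_fc
        if others:
            partner = others[j % len(others)]
            ct_factor[partner][gi] = cfg.signature_fc * cfg.dual_signature_factor
            dual_partner[gene_ids[gi]] = partner

    # study batch factors (log2 scale): gaussian spread plus optional
    # fixed-magnitude shift with random sign per gene
    batch_log2 = {}
    for b in range(cfg.n_studies):
        shift = np.zeros(G)
        if b > 0:
            shift = rng.normal(0.0, cfg.batch_log2_sd, G)
            if cfg.batch_log2_shift:
                shift = shift + cfg.batch_log2_shift * rng.choice([-1.0, 1.0], G)
        batch_log2[f"study{b + 1}"] = shift

    chem_factor = np.ones(G)
    chem_factor[idx_chem] = cfg.chemistry_bias_multiplier  # applied to 3'V2 cells

    # --- samples ---
    blocks = []
    meta_rows = []
    n_ct = len(cfg.cell_types)
    for state in states:
        for i in range(cfg.samples_per_arm):
            b = i % cfg.n_studies
            study = f"study{b + 1}"
            chemistry = _study_chemistry(b)
            sample_id = f"{state}_s{i + 1}"
            sample_f = np.exp2(rng.normal(0.0, cfg.sample_log2_sd, G))
            base = (baseline * disease_factor[state] * sample_f
                    * np.exp2(batch_log2[study]))
            if chemistry == "3'V2":
                base = base * chem_factor
            ct_of_cell = rng.choice(n_ct, size=cfg.cells_per_sample,
                                    p=np.asarray(cfg.cell_type_proportions))
            size = np.exp(rng.normal(0.0, cfg.cell_size_log_sd, cfg.cells_per_sample))
            sample_counts = np.empty((G, cfg.cells_per_sample), dtype=np.int64)
            for t_idx, t in enumerate(cfg.cell_types):
                cols = np.flatnonzero(ct_of_cell == t_idx)
                if cols.size == 0:
                    continue
                mu = (base * ct_factor[t])[:, None] * size[cols][None, :]
                r = (1.0 / phi)[:, None]
                p = r / (r + mu)
                sample_counts[:, cols] = rng.negative_binomial(r, p)
            blocks.append(sp.csr_matrix(sample_counts))
            for c in range(cfg.cells_per_sample):
                meta_rows.append({
                    "cell_id": f"{sample_id}_c{c + 1}",
                    "sample_id": sample_id,
                    "study_id": study,
                    "disease_state": state,
                    "cell_type": cfg.cell_types[ct_of_cell[c]],
                    "compartment": cfg.compartment,
                    "chemistry": chemistry,
                    "seq_method": "scRNA",
                })
    counts = sp.hstack(blocks, format="csr")
    cells = CellCountMatrix(counts=counts, gene_ids=gene_ids,
                            cell_meta=pd.DataFrame(meta_rows))

    truth = SyntheticTruth(
        common_up=[str(g) for g in gene_ids[idx_common_up]],
        common_down=[str(g) for g in gene_ids[idx_common_down]],
        unique={d: [str(g) for g in gene_ids[idx_unique[d]]] for d in diseases},
        signature=[str(g) for g in gene_ids[idx_signature]],
        dual_signature=dual_partner,
        chemistry_bias=[str(g) for g in gene_ids[idx_chem]],
        batch_log2={k: v.tolist() for k, v in batch_log2.items()},
    )
    return cells, truth


@dataclass
class AlleleCountMatrix:
    """Cells x variants reference/alternate UMI counts for demultiplexing."""

    ref_umis: np.ndarray      # (n_cells, n_variants) int
    alt_umis: np.ndarray
    variant_ids: np.ndarray
    cell_ids: np.ndarray
    pop_af: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ref_umis = np.asarray(self.ref_umis, dtype=np.int64)
        self.alt_umis = np.asarray(self.alt_umis, dtype=np.int64)
        if self.ref_umis.shape != self.alt_umis.shape:
            raise ValidationError("ref and alt matrices differ in shape")
        if np.any(self.ref_umis < 0) or np.any(self.alt_umis < 0):
            raise ValidationError("allele counts must be non-negative")
        if self.ref_umis.shape[0] != len(self.cell_ids):
            raise ValidationError("one cell id per row required")
        if self.ref_umis.shape[1] != len(self.variant_ids):
            raise ValidationError("one variant id per column required")

    @property
    def n_cells(self) -> int:
        return self.ref_umis.shape[0]

    @property
    def n_variants(self) -> int:
        return self.ref_umis.shape[1]

    def total_umis(self) -> np.ndarray:
        return self.ref_umis + self.alt_umis

    def subset_variants(self, mask) -> "AlleleCountMatrix":
        mask = np.asarray(mask, dtype=bool)
        return AlleleCountMatrix(
            ref_umis=self.ref_umis[:, mask],
            alt_umis=self.alt_umis[:, mask],
            variant_ids=np.asarray(self.variant_ids)[mask],
            cell_ids=self.cell_ids,
            pop_af=None if self.pop_af is None else np.asarray(self.pop_af)[mask],
        )

    def to_tsv(self, path) -> None:
        rows = []
        for i, cid in enumerate(self.cell_ids):
            for j, vid in enumerate(self.variant_ids):
                r, a = self.ref_umis[i, j], self.alt_umis[i, j]
                if r or a:
                    rows.append((cid, vid, r, a))
        pd.DataFrame(rows, columns=["cell_id", "variant_id", "ref_umis", "alt_umis"]) \
            .to_csv(path, sep="\t", index=False)


def read_allele_counts(path, pop_af: dict | None = None) -> AlleleCountMatrix:
    """Read a long-format cell x variant allele table (cell_id, variant_id, ref_umis, alt_umis)."""
    df = pd.read_csv(path, sep="\t")
    cells = pd.Index(sorted(df["cell_id"].unique()))
    variants = pd.Index(sorted(df["variant_id"].unique()))
    ref = np.zeros((len(cells), len(variants)), dtype=np.int64)
    alt = np.zeros_like(ref)
    ci = cells.get_indexer(df["cell_id"])
    vi = variants.get_indexer(df["variant_id"])
    ref[ci, vi] = df["ref_umis"].to_numpy()
    alt[ci, vi] = df["alt_umis"].to_numpy()
    af = None
    if pop_af is not None:
        af = np.array([pop_af.get(v, np.nan) for v in variants])
    return AlleleCountMatrix(ref_umis=ref, alt_umis=alt,
                             variant_ids=variants.to_numpy(dtype=object),
                             cell_ids=cells.to_numpy(dtype=object), pop_af=af)


def generate_allele_counts(
    n_cells: int,
    n_variants: int,
    depth: float,
    doublet_rate: float,
    genotype_divergence: float,
    seed: int,
    g2_fraction: float = 0.5,
    error_rate: float = 0.01,
) -> tuple[AlleleCountMatrix, SyntheticTruth]:
    """Simulate a two-genotype cell mixture with doublets.

    Each genotype carries a per-variant alt-allele dosage in {0, 0.5, 1};
    ``genotype_divergence`` is the fraction of variants at which the two
    genotypes differ.  Per (cell, variant) sequencing depth is Poisson(depth)
    and alt UMIs are Binomial(depth, dosage adjusted by ``error_rate``).
    Doublets mix the two dosages equally.
    """
    if n_variants <= 0 or n_cells <= 0:
        raise ValidationError("n_cells and n_variants must be positive")
    if depth <= 0:
        raise ValidationError("depth must be positive")
    if not (0.0 <= doublet_rate < 1.0):
        raise ValidationError("doublet_rate must lie in [0, 1)")
    if genotype_divergence <= 0.0:
        raise ValidationError(
            "two genotype clusters with zero divergence are unidentifiable"
        )
    rng = np.random.default_rng(seed)
    dos_levels = np.array([0.0, 0.5, 1.0])
    d1 = rng.choice(dos_levels, n_variants)
    d2 = d1.copy()
    discordant = rng.random(n_variants) < genotype_divergence
    for j in np.flatnonzero(discordant):
        choices = dos_levels[dos_levels != d1[j]]
        d2[j] = rng.choice(choices)

    u = rng.random(n_cells)
    labels = np.where(u < doublet_rate, "doublet",
                      np.where(rng.random(n_cells) < g2_fraction, "g2", "g1"))
    dosage = np.empty((n_cells, n_variants))
    dosage[labels == "g1"] = d1
    dosage[labels == "g2"] = d2
    dosage[labels == "doublet"] = 0.5 * (d1 + d2)

    dp = rng.poisson(depth, size=(n_cells, n_variants))
    p_alt = dosage * (1 - 2 * error_rate) + error_rate
    alt = rng.binomial(dp, p_alt)
    ref = dp - alt
    ac = AlleleCountMatrix(
        ref_umis=ref, alt_umis=alt,
        variant_ids=np.array([f"V{j:04d}" for j in range(n_variants)], dtype=object),
        cell_ids=np.array([f"cell{i:05d}" for i in range(n_cells)], dtype=object),
        pop_af=rng.uniform(0.05, 0.5, n_variants),
    )
    truth = SyntheticTruth(genotype=labels.tolist(),
                           dosage_g1=d1.tolist(), dosage_g2=d2.tolist())
    return ac, truth


def assign_chimeric_cell_types(
    genotype_labels,
    type_plan: list,
    seed: int,
    patient: str = "P1",
) -> pd.DataFrame:
    """Attach cell-type / compartment metadata consistent with genotype labels.

    ``type_plan`` is a list of ``(cell_type, compartment, n_cells,
    recipient_fraction)`` tuples; recipient cells are drawn from the ``g2``
    pool and donor cells from ``g1``, so each planned cell type carries
    exactly its planted recipient fraction (up to rounding).  Cells not used
    by the plan (including doublets) are omitted from the returned metadata.
    Raises if the plan demands more singlets of either genotype than
    available.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(genotype_labels)
    pool = {"g1": list(rng.permutation(np.flatnonzero(labels == "g1"))),
            "g2": list(rng.permutation(np.flatnonzero(labels == "g2")))}
    rows = {}
    for cell_type, compartment, n, rec_frac in type_plan:
        n_rec = int(round(n * rec_frac))
        for _ in range(n_rec):
            if not pool["g2"]:
                raise ValidationError("plan exhausts recipient (g2) singlets")
            rows[pool["g2"].pop()] = (cell_type, compartment)
        for _ in range(n - n_rec):
            if not pool["g1"]:
                raise ValidationError("plan exhausts donor (g1) singlets")
            rows[pool["g1"].pop()] = (cell_type, compartment)
    meta = pd.DataFrame(
        [(int(i), rows[i][0], rows[i][1], patient) for i in sorted(rows)],
        columns=["cell_index", "cell_type", "compartment", "patient"],
    )
    return meta
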