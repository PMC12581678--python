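"""Donor-recipient deconvolution from cell-level variant allele counts.

Pipeline: filter variants on coverage / minor-allele content / population
allele frequency, demultiplex cells into two genotype clusters with a
binomial-mixture EM (doublet component included), drop low-confidence cells
and doublets, assign the structurally dominant genotype group as donor, and
report per-(patient, cell type) recipient proportions, marking totals below
20 cells as not applicable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.vq

from .io_model import STRUCTURAL_COMPARTMENTS, ValidationError
from .synthetic import AlleleCountMatrix

logger = logging.getLogger(__name__)

_DOSAGE_LEVELS = np.array([0.0, 0.5, 1.0])


def filter_variants(
    ac: AlleleCountMatrix,
    min_umis: int = 20,
    min_minor_frac: float = 0.10,
    min_pop_af: float = 0.05,
) -> AlleleCountMatrix:
    """Keep variants with >= ``min_umis`` total UMIs, pooled minor-allele
    fraction >= ``min_minor_frac`` and (when provided) population allele
    frequency > ``min_pop_af``."""
    total = ac.total_umis().sum(axis=0)
    alt = ac.alt_umis.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    minor = np.minimum(af, 1.0 - af)
    keep = (total >= min_umis) & (minor >= min_minor_frac)
    if ac.pop_af is not None:
        pa = np.asarray(ac.pop_af, dtype=float)
        keep &= np.where(np.isnan(pa), True, pa > min_pop_af)
    if not keep.any():
        raise ValidationError(
            "all variants removed by filtering; relax min_umis/min_minor_frac"
        )
    return ac.subset_variants(keep)


@dataclass
class DemuxAssignment:
    """Per-cell genotype assignment with posterior probabilities.

    ``assignment`` columns: cell_id, group (g1 | g2 | doublet | unassigned),
    posterior (probability of the assigned group), p_g1, p_g2, p_doublet.
    """

    assignment: pd.DataFrame
    dosage_g1: np.ndarray | None = None
    dosage_g2: np.ndarray | None = None
    log_likelihood: float = float("nan")
    ll_trace: list | None = None


def _component_loglik(alt, ref, dosage_row, error_rate):
    p = dosage_row * (1.0 - 2.0 * error_rate) + error_rate
    return alt @ np.log(p) + ref @ np.log(1.0 - p)


def demux_two_genotypes(
    ac: AlleleCountMatrix,
    seed: int,
    doublet_prior: float = 0.05,
    error_rate: float = 0.01,
    n_restarts: int = 10,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> DemuxAssignment:
    """EM over a two-genotype binomial mixture with a doublet component.

    Cluster-specific alt dosages live on {0, 0.5, 1} per variant; the doublet
    component averages the two cluster dosages.  The EM is initialised by
    k-means on per-cell alt-fraction profiles (seeded; ``n_restarts``
    restarts, best likelihood kept) and its log-likelihood is non-decreasing
    across iterations.  Cluster labels are canonicalised (g1 has the smaller
    total dosage, ties broken lexicographically), so they carry no donor/
    recipient meaning by themselves.
    """
    if ac.n_cells < 2:
        raise ValidationError("need at least 2 cells")
    rng = np.random.default_rng(seed)
    alt = ac.alt_umis.astype(float)
    ref = ac.ref_umis.astype(float)
    dp = alt + ref
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(dp > 0, alt / np.maximum(dp, 1.0), 0.5)

    best = None
    for _ in range(n_restarts):
        _, labels = scipy.cluster.vq.kmeans2(
            frac, 2, minit="++", seed=rng, missing="warn")
        if len(np.unique(labels)) < 2:
            labels = rng.integers(0, 2, ac.n_cells)
        d = np.empty((2, ac.n_variants))
        for c in (0, 1):
            members = labels == c
            pooled = alt[members].sum(axis=0) / np.maximum(dp[members].sum(axis=0), 1.0)
            d[c] = _DOSAGE_LEVELS[np.argmin(
                np.abs(pooled[:, None] - _DOSAGE_LEVELS[None, :]), axis=1)]
        res = _run_em(alt, ref, d[0], d[1], doublet_prior, error_rate,
                      max_iter, tol)
        if best is None or res["ll"] > best["ll"]:
            best = res

    d1, d2 = best["d1"], best["d2"]
    if np.array_equal(d1, d2):
        logger.warning("genotype clusters collapsed; all cells unassigned")
        n = ac.n_cells
        df = pd.DataFrame({
            "cell_id": ac.cell_ids, "group": "unassigned",
            "posterior": np.nan, "p_g1": np.nan, "p_g2": np.nan,
            "p_doublet": np.nan,
        })
        return DemuxAssignment(assignment=df, dosage_g1=d1, dosage_g2=d2,
                               log_likelihood=best["ll"], ll_trace=best["trace"])

    # canonical order: g1 = smaller total dosage (lexicographic tie-break)
    if (d1.sum(), tuple(d1)) > (d2.sum(), tuple(d2)):
        d1, d2 = d2, d1
        best["resp"] = best["resp"][:, [1, 0, 2]]

    resp = best["resp"]
    groups = np.array(["g1", "g2", "doublet"])[np.argmax(resp, axis=1)]
    df = pd.DataFrame({
        "cell_id": ac.cell_ids,
        "group": groups,
        "posterior": resp.max(axis=1),
        "p_g1": resp[:, 0],
        "p_g2": resp[:, 1],
        "p_doublet": resp[:, 2],
    })
    return DemuxAssignment(assignment=df, dosage_g1=d1, dosage_g2=d2,
                           log_likelihood=best["ll"], ll_trace=best["trace"])


def _run_em(alt, ref, d1, d2, doublet_prior, error_rate, max_iter, tol):
    n_cells, n_var = alt.shape
    pi = np.array([(1 - doublet_prior) / 2, (1 - doublet_prior) / 2, doublet_prior])
    trace = []
    ll_prev = -np.inf
    resp = None
    for _ in range(max_iter):
        comp_ll = np.column_stack([
            _component_loglik(alt, ref, d1, error_rate),
            _component_loglik(alt, ref, d2, error_rate),
            _component_loglik(alt, ref, 0.5 * (d1 + d2), error_rate),
        ]) + np.log(pi)[None, :]
        mx = comp_ll.max(axis=1, keepdims=True)
        lse = mx.ravel() + np.log(np.exp(comp_ll - mx).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(comp_ll - lse[:, None])
        trace.append(ll)
        if ll - ll_prev < tol and len(trace) > 1:
            break
        ll_prev = ll

        # M-step: singlet mixing weights (doublet prior stays fixed)
        singlet_mass = resp[:, 0].sum() + resp[:, 1].sum()
        if singlet_mass > 0:
            pi = np.array([
                (1 - doublet_prior) * resp[:, 0].sum() / singlet_mass,
                (1 - doublet_prior) * resp[:, 1].sum() / singlet_mass,
                doublet_prior,
            ])
            pi = np.maximum(pi, 1e-12)

        # M-step: per-variant joint choice of (d1, d2) over the 3x3 grid
        levels = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        S = np.empty((3, len(levels), n_var))
        for li, lv in enumerate(levels):
            p = lv * (1 - 2 * error_rate) + error_rate
            LL = alt * np.log(p) + ref * np.log(1 - p)
            for c in range(3):
                S[c, li] = resp[:, c] @ LL
        lvl_idx = {v: i for i, v in enumerate(levels)}
        combo_scores = np.full((3, 3, n_var), -np.inf)
        for i1, v1 in enumerate(_DOSAGE_LEVELS):
            for i2, v2 in enumerate(_DOSAGE_LEVELS):
                mid = 0.5 * (v1 + v2)
                combo_scores[i1, i2] = (S[0, lvl_idx[v1]] + S[1, lvl_idx[v2]]
                                        + S[2, lvl_idx[mid]])
        flat = combo_scores.reshape(9, n_var)
        bestc = np.argmax(flat, axis=0)
        d1 = _DOSAGE_LEVELS[bestc // 3]
        d2 = _DOSAGE_LEVELS[bestc % 3]
    return {"ll": ll_prev if not trace else trace[-1], "d1": d1, "d2": d2,
            "resp": resp, "trace": trace}


def apply_probability_filter(
    d: DemuxAssignment, threshold: float = 0.9
) -> DemuxAssignment:
    """Mark cells with max singlet posterior below ``threshold`` unassigned.

    Doublet-called cells keep the ``doublet`` label and are excluded from
    downstream proportion counts, as are unassigned cells.
    """
    df = d.assignment.copy()
    singlet = df["group"].isin(["g1", "g2"])
    low = singlet & (df[["p_g1", "p_g2"]].max(axis=1) < threshold)
    df.loc[low, "group"] = "unassigned"
    df.loc[low, "posterior"] = df.loc[low, ["p_g1", "p_g2"]].max(axis=1)
    return DemuxAssignment(assignment=df, dosage_g1=d.dosage_g1,
                           dosage_g2=d.dosage_g2,
                           log_likelihood=d.log_likelihood, ll_trace=d.ll_trace)


def label_donor_recipient(
    d: DemuxAssignment,
    cell_meta: pd.DataFrame,
    structural_compartments=STRUCTURAL_COMPARTMENTS,
) -> tuple[dict, dict]:
    """Assign donor/recipient identities to the two genotype groups.

    The group with the higher fraction of member cells in structural
    compartments (epithelial + endothelial + stromal, vs immune) is the
    donor.  Returns ``(mapping, structural_fractions)`` where mapping is
    {"g1": "donor"|"recipient", "g2": ...}.  An exact tie raises, requiring
    manual assignment.
    """
    df = d.assignment.merge(cell_meta, on="cell_id", how="inner")
    fracs = {}
    for g in ("g1", "g2"):
        members = df[df["group"] == g]
        if len(members) == 0:
            raise ValidationError(f"group {g} is empty after filtering")
        fracs[g] = float(
            members["compartment"].isin(structural_compartments).mean())
    if fracs["g1"] == fracs["g2"]:
        raise ValidationError(
            "structural fractions tie exactly; manual donor assignment required"
        )
    donor = "g1" if fracs["g1"] > fracs["g2"] else "g2"
    mapping = {donor: "donor", ("g2" if donor == "g1" else "g1"): "recipient"}
    return mapping, fracs


def chimerism_proportions(
    d: DemuxAssignment,
    cell_meta: pd.DataFrame,
    mapping: dict,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Per-(patient, cell type) recipient proportions.

    Unassigned and doublet cells are excluded from numerator and
    denominator; totals below ``min_cells`` yield a not-applicable (NaN)
    proportion with ``applicable = False``.
    """
    df = d.assignment.merge(cell_meta, on="cell_id", how="inner")
    df = df[df["group"].isin(["g1", "g2"])].copy()
    df["origin"] = df["group"].map(mapping)
    rows = []
    for (patient, cell_type), grp in df.groupby(["patient", "cell_type"]):
        n_total = len(grp)
        n_rec = int((grp["origin"] == "recipient").sum())
        applicable = n_total >= min_cells
        rows.append({
            "patient": patient,
            "cell_type": cell_type,
            "n_total": n_total,
            "n_recipient": n_rec,
            "proportion": (n_rec / n_total) if applicable else np.nan,
            "applicable": applicable,
        })
    return pd.DataFrame(rows)
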