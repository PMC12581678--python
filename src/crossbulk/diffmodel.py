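"""Normalisation, batch handling and NB differential expression for pseudo-bulk counts.

The modelling conventions follow the standard pseudo-bulk workflow for
multi-study count data:

* trimmed-mean-of-M-values (TMM) scaling factors with the usual 30% trim on
  log-ratios and 5% on average log-abundance;
* log2 counts-per-million with a small prior count;
* per-gene NB log-linear models with log effective library size as offset,
  batch handled either as a design covariate or by count-level quantile
  adjustment (ComBat-seq style);
* Wald tests on linear contrasts with Benjamini-Hochberg adjustment within
  each contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from scipy.stats import rankdata

from .glm import fit_nb_glm, estimate_dispersion
from .io_model import ValidationError
from .pseudobulk import PseudobulkMatrix

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def norm_factors(
    pb: PseudobulkMatrix | np.ndarray,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> np.ndarray:
    """TMM scaling factors, normalised to geometric mean 1.

    The unit with the largest library is the reference; per unit the factor
    is the doubly trimmed, precision-weighted mean of the gene-wise log2
    ratios against the reference.  A pure depth difference between units
    (every gene scaled by the same constant) yields factors of 1.
    """
    counts = pb.counts if isinstance(pb, PseudobulkMatrix) else np.asarray(pb)
    counts = counts.astype(float)
    G, n = counts.shape
    if n < 2:
        raise ValidationError("norm_factors needs at least 2 units")
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        bad = np.flatnonzero(lib == 0)
        raise ValidationError(f"unit(s) {bad.tolist()} have all-zero counts")
    ref = int(np.argmax(lib))
    factors = np.ones(n)
    pr = counts[:, ref] / lib[ref]
    for k in range(n):
        if k == ref:
            continue
        pk = counts[:, k] / lib[k]
        use = (counts[:, k] > 0) & (counts[:, ref] > 0)
        if use.sum() < 10:
            continue
        M = np.log2(pk[use] / pr[use])
        A = 0.5 * np.log2(pk[use] * pr[use])
        # asymptotic delta-method variance of M
        w = ((lib[k] - counts[use, k]) / (lib[k] * counts[use, k])
             + (lib[ref] - counts[use, ref]) / (lib[ref] * counts[use, ref]))
        m = use.sum()
        rM = rankdata(M)
        rA = rankdata(A)
        loM = np.floor(m * logratio_trim) + 1
        hiM = m + 1 - loM
        loA = np.floor(m * abundance_trim) + 1
        hiA = m + 1 - loA
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if keep.sum() == 0 or np.abs(M[keep]).max() < 1e-6:
            factors[k] = 1.0
        else:
            factors[k] = 2.0 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def logcpm(
    pb: PseudobulkMatrix | np.ndarray,
    factors: np.ndarray | None = None,
    prior_count: float = 0.5,
) -> np.ndarray:
    """log2 counts-per-million: log2((y + c_j) / (L_eff_j + 2 c_j) * 1e6).

    The prior count is scaled per unit in proportion to its effective
    library size (``c_j = prior_count * L_eff_j / mean(L_eff)``), so units
    with proportional counts get identical logCPM columns.
    """
    counts = pb.counts if isinstance(pb, PseudobulkMatrix) else np.asarray(pb)
    counts = counts.astype(float)
    lib = counts.sum(axis=0)
    if factors is None:
        factors = np.ones(counts.shape[1])
    eff = lib * factors
    prior = prior_count * eff / eff.mean()
    return np.log2((counts + prior[None, :])
                   / (eff + 2.0 * prior)[None, :] * 1e6)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs propagate)."""
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    pv = p[finite]
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        res = np.empty(m)
        res[order] = np.minimum(adj, 1.0)
        out[finite] = res
    return out


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Factors and contrasts of a pseudo-bulk differential-expression model.

    ``contrasts`` entries are either ``(name, level_a, level_b)`` —
    level_a vs level_b on ``group_col``, positive log2FC meaning higher in
    level_a — or ``(name, "__avg__", target)`` for target vs the equally
    weighted average of the other ``group_col`` levels.
    """

    group_col: str = "disease_state"
    reference: str = "control"
    batch_col: str | None = "study_id"
    covariate_cols: tuple = ()
    contrasts: list = field(default_factory=list)

    @staticmethod
    def disease_vs_control(diseases, batch_col="study_id") -> "DesignSpec":
        return DesignSpec(
            batch_col=batch_col,
            contrasts=[(f"{d}_vs_control", d, "control") for d in diseases],
        )

    @staticmethod
    def pairwise(diseases, batch_col="study_id") -> "DesignSpec":
        ds = list(diseases)
        contrasts = [(f"{a}_vs_{b}", a, b)
                     for i, a in enumerate(ds) for b in ds[i + 1:]]
        return DesignSpec(batch_col=batch_col, contrasts=contrasts)


def _dummies(series: pd.Series, ref: str | None, prefix: str):
    levels = list(pd.unique(series))
    if ref is not None:
        if ref not in levels:
            raise ValidationError(f"reference level {ref!r} absent from {prefix}")
        levels = [ref] + sorted(l for l in levels if l != ref)
    else:
        levels = sorted(levels)
    cols, names = [], []
    for l in levels[1:]:
        cols.append((series == l).to_numpy(float))
        names.append(f"{prefix}[{l}]")
    return cols, names, levels


def build_design(
    unit_meta: pd.DataFrame, design: DesignSpec, include_batch: bool
) -> tuple[np.ndarray, list, list]:
    """Intercept + treatment-coded factor columns; returns (X, names, group levels)."""
    cols = [np.ones(len(unit_meta))]
    names = ["intercept"]
    gcols, gnames, glevels = _dummies(unit_meta[design.group_col],
                                      design.reference
                                      if design.reference in set(unit_meta[design.group_col])
                                      else None,
                                      design.group_col)
    cols += gcols
    names += gnames
    if include_batch and design.batch_col is not None:
        bcols, bnames, _ = _dummies(unit_meta[design.batch_col], None, design.batch_col)
        cols += bcols
        names += bnames
    for cov in design.covariate_cols:
        ccols, cnames, _ = _dummies(unit_meta[cov], None, cov)
        cols += ccols
        names += cnames
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValidationError(
            f"design matrix is rank deficient ({rank} < {X.shape[1]}); "
            "check for confounded factors"
        )
    return X, names, glevels


def _contrast_vector(names: list, glevels: list, group_col: str, spec) -> np.ndarray:
    name_idx = {nm: i for i, nm in enumerate(names)}
    c = np.zeros(len(names))

    def coef(level):
        key = f"{group_col}[{level}]"
        return name_idx.get(key)  # None for the reference level (coefficient 0)

    _, a, b = spec
    if a == "__avg__":
        target = b
        others = [l for l in glevels if l != target]
        if not others:
            raise ValidationError("average contrast needs at least 2 levels")
        i = coef(target)
        if i is not None:
            c[i] = 1.0
        for o in others:
            j = coef(o)
            if j is not None:
                c[j] -= 1.0 / len(others)
        return c
    for level, sign in ((a, 1.0), (b, -1.0)):
        if level not in glevels:
            raise ValidationError(f"contrast level {level!r} absent from design")
        i = coef(level)
        if i is not None:
            c[i] += sign
    return c


# ---------------------------------------------------------------------------
# batch adjustment (count level)
# ---------------------------------------------------------------------------

def adjust_counts_for_batch(
    pb: PseudobulkMatrix,
    batch_col: str = "study_id",
    group_col: str = "disease_state",
) -> PseudobulkMatrix:
    """ComBat-seq-style count adjustment: NB quantile mapping to a batch-free model.

    Per gene, an NB GLM with group and batch effects is fitted; each count is
    mapped through the midpoint-quantile of its batch-specific NB to the
    inverse CDF of the batch-free NB (batch coefficient replaced by the
    size-weighted average batch effect), preserving group differences while
    removing batch-specific location shifts.  Single-batch input is returned
    unchanged.  A batch perfectly confounded with group raises, directing the
    caller to the covariate strategy.
    """
    meta = pb.unit_meta
    batches = list(pd.unique(meta[batch_col]))
    if len(batches) <= 1:
        return pb
    counts_per_batch = meta[batch_col].value_counts()
    if (counts_per_batch < 2).any():
        raise ValidationError("every batch needs at least 2 units")
    design = DesignSpec(group_col=group_col, reference=None, batch_col=batch_col)
    design.reference = (meta[group_col].iloc[0]
                        if "control" not in set(meta[group_col]) else "control")
    try:
        X, names, _ = build_design(meta, design, include_batch=True)
    except ValidationError as exc:
        raise ValidationError(
            "batch is confounded with group; use the covariate strategy instead"
        ) from exc
    Y = pb.counts.astype(float)
    lib = Y.sum(axis=0)
    offset = np.log(lib)
    alpha = estimate_dispersion(Y, X, offset).alpha
    fit = fit_nb_glm(Y, X, offset, alpha)

    batch_cols = [i for i, nm in enumerate(names) if nm.startswith(f"{batch_col}[")]
    batch_levels = [nm[len(batch_col) + 1:-1] for nm in (names[i] for i in batch_cols)]
    # per-unit batch term (natural log) and its size-weighted mean
    unit_batch_term = np.zeros((Y.shape[0], Y.shape[1]))
    size = meta[batch_col].value_counts()
    mean_term = np.zeros(Y.shape[0])
    for lvl, i in zip(batch_levels, batch_cols):
        in_lvl = (meta[batch_col] == lvl).to_numpy()
        unit_batch_term[:, in_lvl] = fit.beta[:, [i]]
        mean_term += fit.beta[:, i] * (size[lvl] / len(meta))
    mu_bf = fit.mu * np.exp(mean_term[:, None] - unit_batch_term)

    r = (1.0 / np.maximum(fit.alpha, 1e-8))[:, None]
    p_with = r / (r + np.maximum(fit.mu, 1e-10))
    p_bf = r / (r + np.maximum(mu_bf, 1e-10))
    y = pb.counts
    cdf_hi = scipy.stats.nbinom.cdf(y, r, p_with)
    cdf_lo = scipy.stats.nbinom.cdf(y - 1, r, p_with)
    q = np.clip(0.5 * (cdf_lo + cdf_hi), 1e-12, 1.0 - 1e-12)
    adj = scipy.stats.nbinom.ppf(q, r, p_bf)
    adj = np.maximum(np.round(adj), 0).astype(np.int64)
    return PseudobulkMatrix(adj, pb.gene_ids, pb.unit_meta.copy())


def _empirical_null_scale(abs_z: np.ndarray, df: float) -> float:
    """Scale of the central null component of |z| by two-quantile matching.

    Assumes z ~ scale x t(df) for the (majority) null genes while
    alternatives live far in the tails, so moderate quantiles of |z| carry
    no signal mass — alternatives only compress the null ranks, which the
    unknown null fraction absorbs.  The scale is identified from the ratio
    of the 50th and 80th percentiles (the curved region of the null CDF):
    q1/q2 = F0(x1/c) / F0(x2/c), solved for c by bisection.
    """
    q1, q2 = 0.5, 0.8
    q_ratio = q1 / q2
    x1, x2 = np.quantile(abs_z, [q1, q2])
    if not (0 < x1 < x2):
        return 1.0

    def f0(t):
        return 2.0 * scipy.stats.t.cdf(t, df) - 1.0

    def g(c):
        return f0(x1 / c) / f0(x2 / c) - q_ratio

    try:
        lo, hi = 0.3, 3.0
        if g(lo) * g(hi) > 0:
            return 1.0
        scale = scipy.optimize.brentq(g, lo, hi, xtol=1e-4)
    except (ValueError, ZeroDivisionError):  # pragma: no cover - degenerate z
        return 1.0
    return float(np.clip(scale, 0.95, 1.3))


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass
class DETable:
    """Per-gene, per-contrast statistics plus group-level summaries.

    ``table`` columns: gene, contrast, log2FC, avg_logCPM, p_value, adj_p.
    ``group_median_logcpm`` / ``group_pct_expressed`` are genes x group-level
    frames (medians computed after batch handling).
    """

    table: pd.DataFrame
    group_median_logcpm: pd.DataFrame
    group_pct_expressed: pd.DataFrame
    gene_ids: np.ndarray

    def for_contrast(self, name: str) -> pd.DataFrame:
        sub = self.table[self.table["contrast"] == name]
        if sub.empty:
            raise ValidationError(f"no contrast named {name!r}")
        return sub.set_index("gene")

    def to_tsv(self, path) -> None:
        med = self.group_median_logcpm.add_prefix("median_logCPM_")
        pct = self.group_pct_expressed.add_prefix("pct_expressed_")
        wide = self.table.join(med, on="gene").join(pct, on="gene")
        wide.to_csv(path, sep="\t", index=False)


def fit_contrasts(
    pb: PseudobulkMatrix,
    design: DesignSpec,
    strategy: str = "covariate",
    prior_count: float = 0.5,
    dispersion_prior_weight: float | None = None,
    empirical_null: bool = True,
) -> DETable:
    """Genewise NB GLM with library-size offsets; Wald tests per contrast.

    ``strategy="covariate"`` includes batch as a design factor;
    ``strategy="count_adjust"`` first maps counts through
    :func:`adjust_counts_for_batch` and then fits the batch-free design.
    BH adjustment is applied within each contrast.

    With ``empirical_null=True`` (default) each contrast's Wald statistics
    are rescaled so their genome-wide median |z| matches the reference
    null median, absorbing the small residual understatement of plug-in
    standard errors; the calibration assumes most genes are null and is
    skipped for small gene universes.
    """
    if strategy not in ("covariate", "count_adjust"):
        raise ValidationError(f"unknown strategy {strategy!r}")
    meta = pb.unit_meta
    groups = meta[design.group_col]
    level_sizes = groups.value_counts()
    compared = set()
    for spec in design.contrasts:
        _, a, b = spec
        compared.update([b] if a == "__avg__" else [a, b])
    for lvl in compared:
        if lvl not in level_sizes.index:
            raise ValidationError(f"contrast references absent level {lvl!r}")
        if level_sizes[lvl] < 2:
            raise ValidationError(f"level {lvl!r} has fewer than 2 units")

    if strategy == "count_adjust" and design.batch_col is not None \
            and meta[design.batch_col].nunique() > 1:
        pb = adjust_counts_for_batch(pb, design.batch_col, design.group_col)
        meta = pb.unit_meta
    include_batch = strategy == "covariate"
    X, names, glevels = build_design(meta, design, include_batch=include_batch)

    factors = norm_factors(pb)
    lib = pb.counts.sum(axis=0).astype(float)
    offset = np.log(lib * factors)
    Y = pb.counts.astype(float)
    disp = estimate_dispersion(Y, X, offset,
                               prior_weight=dispersion_prior_weight)
    fit = fit_nb_glm(Y, X, offset, disp.alpha)
    n_bad = int((~fit.converged).sum())
    if n_bad:
        logger.warning("%d gene model(s) did not converge; p set to NaN", n_bad)

    lcpm = logcpm(pb, factors, prior_count)
    # remove fitted batch effects (centred across batches) from logCPM before
    # computing group medians
    lcpm_adj = lcpm.copy()
    if include_batch and design.batch_col is not None:
        bcols = [i for i, nm in enumerate(names)
                 if nm.startswith(f"{design.batch_col}[")]
        if bcols:
            blevels = [names[i][len(design.batch_col) + 1:-1] for i in bcols]
            term = np.zeros_like(lcpm)
            sizes = meta[design.batch_col].value_counts()
            mean_term = np.zeros(pb.n_genes)
            for lvl, i in zip(blevels, bcols):
                in_lvl = (meta[design.batch_col] == lvl).to_numpy()
                term[:, in_lvl] = fit.beta[:, [i]] / LN2
                mean_term += fit.beta[:, i] / LN2 * (sizes[lvl] / len(meta))
            lcpm_adj = lcpm - term + mean_term[:, None]

    group_levels = list(pd.unique(groups))
    med = {}
    pct = {}
    for lvl in group_levels:
        in_lvl = (groups == lvl).to_numpy()
        med[lvl] = np.median(lcpm_adj[:, in_lvl], axis=1)
        pct[lvl] = (pb.counts[:, in_lvl] > 0).mean(axis=1)
    group_median_logcpm = pd.DataFrame(med, index=pb.gene_ids)
    group_pct_expressed = pd.DataFrame(pct, index=pb.gene_ids)
    avg_lcpm = lcpm.mean(axis=1)

    # Wald statistics are referred to a moderated t: residual df plus the
    # prior df earned by dispersion shrinkage (the more informative the
    # trend, the closer the reference is to normal)
    df_resid = max(X.shape[0] - X.shape[1], 1)
    df_total = min(df_resid + disp.df_prior, 1e6)
    ests = {}
    zs = {}
    pooled = []
    for spec in design.contrasts:
        cname = spec[0]
        c = _contrast_vector(names, glevels, design.group_col, spec)
        est, se = fit.contrast(c)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = est / se
        ests[cname] = est
        zs[cname] = z
        pooled.append(z[np.isfinite(z) & fit.converged])
    pooled = np.concatenate(pooled) if pooled else np.array([])
    scale = (_empirical_null_scale(np.abs(pooled), df_total)
             if empirical_null and pooled.size >= 500 else 1.0)

    frames = []
    for spec in design.contrasts:
        cname = spec[0]
        z = zs[cname] / scale
        pvals = 2.0 * scipy.stats.t.sf(np.abs(z), df=df_total)
        pvals[~fit.converged] = np.nan
        frames.append(pd.DataFrame({
            "gene": pb.gene_ids,
            "contrast": cname,
            "log2FC": ests[cname] / LN2,
            "avg_logCPM": avg_lcpm,
            "p_value": pvals,
            "adj_p": bh_adjust(pvals),
        }))
    table = pd.concat(frames, ignore_index=True)
    return DETable(table=table, group_median_logcpm=group_median_logcpm,
                   group_pct_expressed=group_pct_expressed, gene_ids=pb.gene_ids)
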