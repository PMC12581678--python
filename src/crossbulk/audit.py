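"""Technical-bias diagnostics: chemistry-influential genes, genome-build
fingerprinting, Jaccard clustering of gene-presence sets, and classical MDS.

These audits flag the non-biological structure an integrated multi-study
compendium carries: per-chemistry expression biases (via Cook's distance on
a between-condition regression of per-gene mean expression), outdated
reference genome builds (via symbol renames such as SEPP1 -> SELENOP), and
study- or pipeline-level separation in low-dimensional embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance

from .io_model import CellCountMatrix, ValidationError


@dataclass
class InfluenceResult:
    """OLS influence audit of condition-B on condition-A mean expression."""

    gene_ids: np.ndarray
    cooks_d: np.ndarray
    influential: np.ndarray       # bool, D_i > 3 * mean(D)
    slope: float
    intercept: float

    @property
    def influential_genes(self) -> list:
        return [str(g) for g in np.asarray(self.gene_ids)[self.influential]]


def mean_expression_per_condition(
    cells: CellCountMatrix,
    condition_col: str = "chemistry",
    normalized: bool = True,
) -> pd.DataFrame:
    """Per-gene mean expression per condition.

    With ``normalized=True`` (default) each cell is depth-normalised to
    counts per 10k and log1p-transformed before averaging, the common
    single-cell convention; otherwise raw-count means are returned.
    """
    csc = cells.counts.tocsc().astype(float)
    out = {}
    for cond in pd.unique(cells.cell_meta[condition_col]):
        mask = (cells.cell_meta[condition_col] == cond).to_numpy()
        sub = csc[:, mask]
        if normalized:
            depth = np.asarray(sub.sum(axis=0)).ravel()
            depth = np.maximum(depth, 1.0)
            sub = sub.multiply(1e4 / depth[None, :]).tocsc()
            sub.data = np.log1p(sub.data)
        out[cond] = np.asarray(sub.mean(axis=1)).ravel()
    return pd.DataFrame(out, index=cells.gene_ids)


def cooks_distance(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cook's distance of each observation in the OLS fit of y on x (with intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in predictor; slope undefined")
    X = np.column_stack([np.ones(n), x])
    XtX_inv = np.linalg.inv(X.T @ X)
    H = X @ XtX_inv @ X.T
    h = np.diag(H)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    p = 2
    s2 = resid @ resid / (n - p)
    if s2 <= np.finfo(float).eps * max(float(np.var(y)), 1.0):
        # numerically exact fit: no influence to measure
        return np.zeros(n)
    return (resid ** 2 / (p * s2)) * (h / (1.0 - h) ** 2)


def detect_influential_genes(
    mean_a: pd.Series | np.ndarray,
    mean_b: pd.Series | np.ndarray,
    gene_ids=None,
    mean_multiple: float = 3.0,
) -> InfluenceResult:
    """Flag genes whose (A, B) mean-expression pair is influential in the OLS fit.

    B is regressed on A with an intercept, one observation per gene; a gene
    is influential iff its Cook's distance strictly exceeds ``mean_multiple``
    times the mean Cook's distance.
    """
    if isinstance(mean_a, pd.Series) and gene_ids is None:
        gene_ids = mean_a.index.to_numpy()
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("condition vectors must share the gene universe")
    if gene_ids is None:
        gene_ids = np.arange(len(a))
    d = cooks_distance(a, b)
    flag = d > mean_multiple * d.mean()
    X = np.column_stack([np.ones(len(a)), a])
    beta = np.linalg.lstsq(X, b, rcond=None)[0]
    return InfluenceResult(gene_ids=np.asarray(gene_ids), cooks_d=d,
                           influential=flag, slope=float(beta[1]),
                           intercept=float(beta[0]))


def flag_genome_build(gene_lists: dict) -> dict:
    """Classify each study's reference build from symbol usage.

    "SEPP1" present -> "outdated"; "SELENOP" present without "SEPP1" ->
    "current"; neither -> "indeterminate".
    """
    out = {}
    for study, genes in gene_lists.items():
        if not len(genes):
            raise ValidationError(f"study {study!r} has an empty gene list")
        s = set(genes)
        if "SEPP1" in s:
            out[study] = "outdated"
        elif "SELENOP" in s:
            out[study] = "current"
        else:
            out[study] = "indeterminate"
    return out


@dataclass
class JaccardClustering:
    """Pairwise Jaccard distances between studies plus a complete-linkage dendrogram."""

    studies: list
    distance: pd.DataFrame
    merges: list                  # [(member_set_a, member_set_b, height), ...]
    linkage: np.ndarray


def jaccard_cluster(presence: pd.DataFrame) -> JaccardClustering:
    """Cluster studies by Jaccard distance between their gene-presence sets.

    ``presence`` is studies x genes boolean/0-1.  Distances are
    1 - |A∩B| / |A∪B|; clustering is agglomerative with complete linkage.
    Studies are processed in lexicographic label order, which fixes the merge
    order under ties.
    """
    if presence.shape[0] < 2:
        raise ValidationError("need at least 2 studies")
    presence = presence.sort_index()
    mat = presence.to_numpy(dtype=bool)
    empty = ~mat.any(axis=1)
    if empty.any():
        raise ValidationError(
            f"study(ies) with empty gene set: {list(presence.index[empty])}")
    dvec = scipy.spatial.distance.pdist(mat, metric="jaccard")
    dmat = scipy.spatial.distance.squareform(dvec)
    Z = scipy.cluster.hierarchy.linkage(dvec, method="complete")
    labels = list(presence.index)
    members = {i: [labels[i]] for i in range(len(labels))}
    merges = []
    for k, (i, j, h, _) in enumerate(Z):
        i, j = int(i), int(j)
        merges.append((sorted(members[i]), sorted(members[j]), float(h)))
        members[len(labels) + k] = members[i] + members[j]
    return JaccardClustering(
        studies=labels,
        distance=pd.DataFrame(dmat, index=labels, columns=labels),
        merges=merges,
        linkage=Z,
    )


def mds_embed(profiles: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (metric) MDS on Euclidean distances between unit profiles.

    ``profiles`` is features x units (e.g. a logCPM matrix); returns units x
    ``n_components`` principal coordinates from the eigendecomposition of the
    doubly centred squared-distance matrix, giving the optimal rank-k
    approximation of the input distances.
    """
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[1]
    if n < 3:
        raise ValidationError("need at least 3 units to embed")
    sq = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(profiles.T, metric="euclidean")) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ sq @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_components]
    w_top = np.maximum(w[order], 0.0)
    return v[:, order] * np.sqrt(w_top)[None, :]
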