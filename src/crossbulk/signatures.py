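"""Multi-criteria gene calling: common genes, disease-unique genes, core
cell-state signatures, and hypergeometric over-representation.

All callers are pure functions of differential-expression tables: the same
tables always yield the same calls, and relaxing any threshold can only grow
a call set.

Calling rules
-------------
* **Common genes** are significantly and *consistently* regulated vs control
  in every disease: adjusted p below the cut-off, |log2FC| at least
  log2(1.35), the same sign everywhere, and the expressed-sample fraction of
  each disease group above 0.1 (up) or 0.6 (down).
* **Disease-unique genes (DUGs)** are up vs control in exactly one disease
  (same significance/fold/pct rules), at least 2-fold and significantly
  higher than *each* other disease, and have the strictly highest group
  median logCPM (after batch handling) in that disease.
* The **core signature** of a target cell state collects genes with FDR <
  0.05 against the equally weighted average of the other cell types, at
  least 2-fold change, and a strictly higher median logCPM than each other
  cell type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .diffmodel import DesignSpec, DETable, bh_adjust, fit_contrasts
from .io_model import ValidationError
from .pseudobulk import PseudobulkMatrix


@dataclass(frozen=True)
class CallCriteria:
    """Thresholds of the calling rules; defaults are the published cut-offs."""

    adj_p_max: float = 0.05
    fc_primary: float = 1.35     # vs control
    fc_secondary: float = 2.0    # vs other diseases / other cell types
    pct_min_up: float = 0.1
    pct_min_down: float = 0.6

    def __post_init__(self) -> None:
        if min(self.adj_p_max, self.fc_primary, self.fc_secondary,
               self.pct_min_up, self.pct_min_down) <= 0:
            raise ValidationError("criteria must be positive")
        if self.fc_secondary < self.fc_primary:
            raise ValidationError("fc_secondary must be >= fc_primary")


@dataclass
class CallResult:
    """Outcome of a common/unique calling run.

    ``calls`` maps gene -> "common_up" | "common_down" | "unique:<disease>";
    genes with no call are absent.  ``evidence`` is the long-format table of
    per-disease statistics the decision was made from.
    """

    calls: dict = field(default_factory=dict)
    evidence: pd.DataFrame | None = None

    def genes(self, call_prefix: str = "") -> list:
        return sorted(g for g, c in self.calls.items() if c.startswith(call_prefix))


def _aligned_universe(tables: dict) -> np.ndarray:
    universes = {d: frozenset(t.index) for d, t in tables.items()}
    ref = next(iter(universes.values()))
    for d, u in universes.items():
        if u != ref:
            diff = sorted(ref.symmetric_difference(u))
            raise ValidationError(
                f"gene universes differ (e.g. table {d!r}); symmetric difference: "
                f"{diff[:10]}{'...' if len(diff) > 10 else ''}"
            )
    some = next(iter(tables.values()))
    return some.index.to_numpy()


def call_common_genes(
    de_tables: dict,
    pct_expressed: dict,
    criteria: CallCriteria | None = None,
) -> CallResult:
    """Call genes consistently regulated vs control across *all* diseases.

    Parameters
    ----------
    de_tables
        disease -> per-gene frame with columns ``log2FC`` and ``adj_p``
        (one disease-vs-control table per disease, identical gene universe).
    pct_expressed
        disease -> per-gene expressed-unit fraction of that disease group.
    """
    crit = criteria or CallCriteria()
    genes = _aligned_universe(de_tables)
    diseases = list(de_tables)
    lfc = np.column_stack([de_tables[d]["log2FC"].to_numpy() for d in diseases])
    adj = np.column_stack([de_tables[d]["adj_p"].to_numpy() for d in diseases])
    pct = np.column_stack([np.asarray(pct_expressed[d].loc[genes])
                           for d in diseases])
    thr = np.log2(crit.fc_primary)
    sig = adj < crit.adj_p_max
    up = sig & (lfc >= thr) & (pct > crit.pct_min_up)
    down = sig & (lfc <= -thr) & (pct > crit.pct_min_down)
    common_up = up.all(axis=1)
    common_down = down.all(axis=1)
    calls = {}
    for g in genes[common_up]:
        calls[g] = "common_up"
    for g in genes[common_down]:
        calls[g] = "common_down"
    evidence = pd.concat(
        [de_tables[d].assign(disease=d, pct=pct[:, i])
         for i, d in enumerate(diseases)]
    )
    return CallResult(calls=calls, evidence=evidence)


def call_disease_unique_genes(
    de_vs_control: dict,
    de_pairwise: dict,
    group_median_logcpm: pd.DataFrame,
    pct_expressed: dict,
    criteria: CallCriteria | None = None,
) -> CallResult:
    """Call genes upregulated in exactly one disease and dominant over the rest.

    Parameters
    ----------
    de_vs_control
        disease -> disease-vs-control frame (``log2FC``, ``adj_p``).
    de_pairwise
        (a, b) -> frame for the a-vs-b contrast (either orientation may be
        supplied; the reverse is derived by sign flip).
    group_median_logcpm
        genes x disease medians after batch handling.
    """
    crit = criteria or CallCriteria()
    diseases = list(de_vs_control)
    if len(diseases) < 2:
        raise ValidationError("disease-unique calling needs at least 2 diseases")
    genes = _aligned_universe(de_vs_control)

    def pair(a, b):
        if (a, b) in de_pairwise:
            t = de_pairwise[(a, b)]
            return t["log2FC"].to_numpy(), t["adj_p"].to_numpy()
        if (b, a) in de_pairwise:
            t = de_pairwise[(b, a)]
            return -t["log2FC"].to_numpy(), t["adj_p"].to_numpy()
        raise ValidationError(f"missing pairwise contrast for {(a, b)}")

    thr1 = np.log2(crit.fc_primary)
    thr2 = np.log2(crit.fc_secondary)
    calls = {}
    for d in diseases:
        t = de_vs_control[d]
        ok = ((t["adj_p"].to_numpy() < crit.adj_p_max)
              & (t["log2FC"].to_numpy() >= thr1)
              & (np.asarray(pct_expressed[d].loc[genes]) > crit.pct_min_up))
        for other in diseases:
            if other == d:
                continue
            lfc_po, adj_po = pair(d, other)
            ok &= (adj_po < crit.adj_p_max) & (lfc_po >= thr2)
        med = group_median_logcpm.loc[genes, diseases].to_numpy()
        d_idx = diseases.index(d)
        others_max = np.max(np.delete(med, d_idx, axis=1), axis=1)
        ok &= med[:, d_idx] > others_max  # strict maximum; ties yield no call
        for g in genes[ok]:
            calls[g] = f"unique:{d}"
    evidence = pd.concat([de_vs_control[d].assign(disease=d) for d in diseases])
    return CallResult(calls=calls, evidence=evidence)


def combine_calls(common: CallResult, unique: CallResult) -> CallResult:
    """Merge common and disease-unique calls into one call per gene.

    A gene consistently regulated across every disease is by definition not
    unique to one, so a common call takes precedence when both callers fire
    on the same gene.
    """
    calls = dict(unique.calls)
    calls.update(common.calls)
    return CallResult(calls=calls, evidence=common.evidence)


@dataclass
class SignatureResult:
    """Core signature of a target cell state."""

    genes: list
    table: pd.DataFrame              # per-gene log2FC, p, adj_p for target vs average
    median_logcpm: pd.DataFrame      # genes x cell-type medians
    de: DETable | None = None


def derive_core_signature(
    pb: PseudobulkMatrix,
    target_cell_type: str,
    criteria: CallCriteria | None = None,
    sample_col: str = "sample_id",
) -> SignatureResult:
    """Derive the core gene signature of one cell type against its peers.

    Fits a linear additive NB model over cell types with sample identity as a
    covariate (absorbing technical and disease-etiology differences between
    samples), contrasts the target against the equally weighted average of
    the other cell types, and keeps genes with FDR < ``adj_p_max``, fold
    change at least ``fc_secondary`` and a strictly higher median logCPM in
    the target than in each other cell type.
    """
    crit = criteria or CallCriteria()
    cell_types = list(pd.unique(pb.unit_meta["cell_type"]))
    if target_cell_type not in cell_types:
        raise ValidationError(f"target cell type {target_cell_type!r} absent")
    design = DesignSpec(
        group_col="cell_type",
        reference=sorted(cell_types)[0],
        batch_col=None,
        covariate_cols=(sample_col,),
        contrasts=[("target_vs_avg", "__avg__", target_cell_type)],
    )
    de = fit_contrasts(pb, design, strategy="covariate")
    t = de.for_contrast("target_vs_avg")
    med = de.group_median_logcpm
    others = [c for c in cell_types if c != target_cell_type]
    dominance = np.ones(len(t), dtype=bool)
    for o in others:
        dominance &= (med[target_cell_type] > med[o]).to_numpy()
    keep = ((t["adj_p"].to_numpy() < crit.adj_p_max)
            & (t["log2FC"].to_numpy() >= np.log2(crit.fc_secondary))
            & dominance)
    genes = sorted(t.index[keep])
    return SignatureResult(genes=genes, table=t, median_logcpm=med, de=de)


def read_gmt(path) -> dict:
    """Read gene sets from GMT (name, description, members...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets


def ora_enrichment(
    query_genes,
    universe,
    gene_sets: dict,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH q-values.

    Returns a frame indexed by set name with columns overlap, set_size,
    query_size, p, q, significant (q < ``q_max``).  Gene sets are intersected
    with the universe; the query must be a subset of the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    query = set(query_genes)
    if not query <= universe:
        raise ValidationError("query genes must be a subset of the universe")
    M = len(universe)
    N = len(query)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        n = len(members)
        k = len(members & query)
        # P[X >= k], X ~ Hypergeom(M, n, N)
        p = float(scipy.stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append((name, k, n, N, p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size",
                                      "query_size", "p"]).set_index("set")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < q_max
    return out
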