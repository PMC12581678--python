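"""Normalisation, logCPM, BH, batch adjustment and the NB contrast fits."""

import subprocess

import numpy as np
import pytest
import statsmodels.stats.multitest

from crossbulk import (
    CohortConfig,
    DesignSpec,
    GeneAnnotation,
    ValidationError,
    adjust_counts_for_batch,
    aggregate,
    bh_adjust,
    fit_contrasts,
    generate_cohort,
    logcpm,
    norm_factors,
    standard_filter_chain,
)

from conftest import make_pb


class TestTMM:
    def test_identical_units(self):
        Y = np.tile(np.arange(1, 21)[:, None], (1, 2))
        assert np.allclose(norm_factors(Y), [1.0, 1.0])

    def test_pure_depth_difference_absorbed(self, rng):
        a = rng.integers(1, 50, 200)
        Y = np.column_stack([a, 2 * a])
        assert np.allclose(norm_factors(Y), [1.0, 1.0])

    def test_geometric_mean_is_one(self, rng):
        Y = rng.poisson(20, size=(300, 6)) + 1
        Y[:, 2] *= 3
        f = norm_factors(Y)
        assert np.isclose(np.exp(np.mean(np.log(f))), 1.0)
        assert np.all(f > 0)

    def test_matches_edger_reference(self, tmp_path, rng):
        """Independent oracle: edgeR's calcNormFactors on the same matrix."""
        G, n = 400, 6
        mu = np.exp(rng.normal(3, 1.5, G))
        depth = rng.uniform(0.5, 2.0, n)
        Y = rng.poisson(mu[:, None] * depth[None, :])
        path = tmp_path / "counts.tsv"
        np.savetxt(path, Y, fmt="%d", delimiter="\t")
        r = subprocess.run(
            ["Rscript", "-e",
             f'suppressMessages(library(edgeR)); '
             f'y<-as.matrix(read.table("{path}")); '
             'f<-calcNormFactors(y, method="TMM"); '
             'cat(f/exp(mean(log(f))))'],
            capture_output=True, text=True, check=True)
        f_r = np.array([float(x) for x in r.stdout.split()])
        assert np.max(np.abs(norm_factors(Y) / f_r - 1)) < 0.03

    def test_all_zero_unit_rejected(self):
        Y = np.ones((10, 2), dtype=int)
        Y[:, 1] = 0
        with pytest.raises(ValidationError, match="all-zero"):
            norm_factors(Y)


class TestLogCPM:
    def test_closed_form(self):
        Y = np.zeros((2, 1))
        Y[1, 0] = 1e6
        out = logcpm(Y, np.array([1.0]), prior_count=0.5)
        assert np.isclose(out[0, 0], np.log2(0.5 / (1e6 + 1) * 1e6), atol=1e-9)

    def test_monotone_in_counts(self, rng):
        Y = rng.integers(0, 100, size=(50, 3)).astype(float) + 1
        out = logcpm(Y)
        Y2 = Y.copy()
        Y2[10, 1] = 2 * Y[10, 1]
        assert logcpm(Y2)[10, 1] > out[10, 1]

    def test_proportional_units_identical_columns(self):
        a = np.arange(1.0, 31.0)
        Y = np.column_stack([a, 5 * a])
        out = logcpm(Y, np.ones(2))
        assert np.allclose(out[:, 0], out[:, 1], atol=1e-6)


class TestBH:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_properties_hold_on_arbitrary_pvalues(self, p):
        adj = bh_adjust(p)
        assert np.all((adj >= 0) & (adj <= 1))
        assert np.all(adj >= np.asarray(p) - 1e-12)
        # monotone in the input ranks
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        ref = statsmodels.stats.multitest.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adj, ref)

    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_identities(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([0.4, 0.4, 0.4]), [0.4, 0.4, 0.4])

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(0, 1, 200)
        ref = statsmodels.stats.multitest.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref)

    def test_invalid_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_nan_propagates(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and not np.isnan(out[0])


def _two_batch_pb(seed=11, shift=1.0):
    cfg = CohortConfig(seed=seed, diseases=("disease",), samples_per_arm=6,
                       n_studies=2, n_genes=800, n_common_up=20,
                       n_common_down=0, n_unique_per_disease=0, common_fc=2.0,
                       batch_log2_sd=0.0, batch_log2_shift=shift)
    cells, truth = generate_cohort(cfg)
    pb = standard_filter_chain(aggregate(cells),
                               GeneAnnotation.protein_coding(cells.gene_ids))
    return pb, truth


class TestBatchAdjust:
    def test_single_batch_identity(self):
        pb, _ = _two_batch_pb()
        pb1 = pb.subset_units((pb.unit_meta["study_id"] == "study1").to_numpy())
        adj = adjust_counts_for_batch(pb1)
        assert np.array_equal(adj.counts, pb1.counts)

    def test_confounded_batch_rejected(self):
        pb, _ = _two_batch_pb()
        meta = pb.unit_meta.copy()
        # make batch coincide with group
        meta["study_id"] = np.where(meta["disease_state"] == "disease", "A", "B")
        pb2 = type(pb)(pb.counts, pb.gene_ids, meta)
        with pytest.raises(ValidationError, match="covariate"):
            adjust_counts_for_batch(pb2)

    def test_counts_stay_nonnegative_integers_and_libraries_close(self):
        pb, _ = _two_batch_pb()
        adj = adjust_counts_for_batch(pb)
        assert adj.counts.dtype == np.int64
        assert (adj.counts >= 0).all()
        ratio = adj.counts.sum(axis=0) / pb.counts.sum(axis=0)
        assert np.all((ratio > 0.9) & (ratio < 1.1))

    def test_batch_effect_removed_group_effect_kept(self):
        from crossbulk.diffmodel import build_design
        from crossbulk.glm import estimate_dispersion, fit_nb_glm

        pb, truth = _two_batch_pb()
        adj = adjust_counts_for_batch(pb)
        design = DesignSpec(contrasts=[("d", "disease", "control")])
        X, names, _ = build_design(adj.unit_meta, design, include_batch=True)
        Y = adj.counts.astype(float)
        off = np.log(Y.sum(axis=0))
        disp = estimate_dispersion(Y, X, off)
        fit = fit_nb_glm(Y, X, off, disp.alpha)
        b_batch = fit.beta[:, names.index("study_id[study2]")] / np.log(2)
        b_grp = fit.beta[:, names.index("disease_state[disease]")] / np.log(2)
        assert np.mean(np.abs(b_batch)) < 0.2
        planted = np.isin(adj.gene_ids, truth.common_up)
        assert abs(b_grp[planted].mean() - 1.0) < 0.25


@pytest.fixture(scope="module")
def one_disease_de():
    cfg = CohortConfig(seed=21, diseases=("IPF",), samples_per_arm=6,
                       n_genes=1000, n_common_up=25, n_common_down=0,
                       n_unique_per_disease=0, common_fc=2.0)
    cells, truth = generate_cohort(cfg)
    pb = standard_filter_chain(aggregate(cells),
                               GeneAnnotation.protein_coding(cells.gene_ids))
    design = DesignSpec(contrasts=[("IPF_vs_control", "IPF", "control"),
                                   ("control_vs_IPF", "control", "IPF")])
    return pb, truth, fit_contrasts(pb, design)


class TestFitContrasts:
    def test_planted_log2fc_recovered(self, one_disease_de):
        pb, truth, de = one_disease_de
        t = de.for_contrast("IPF_vs_control")
        lfc = t.loc[truth.common_up, "log2FC"]
        assert abs(lfc.mean() - 1.0) < 0.15
        assert (np.abs(lfc - 1.0) < 0.3).mean() >= 0.9

    def test_contrast_antisymmetry(self, one_disease_de):
        _, _, de = one_disease_de
        a = de.for_contrast("IPF_vs_control")
        b = de.for_contrast("control_vs_IPF")
        assert np.allclose(a["log2FC"], -b["log2FC"], atol=1e-8)
        assert np.allclose(a["p_value"].dropna(), b["p_value"].dropna())

    def test_discoveries_control_fdp(self, one_disease_de):
        pb, truth, de = one_disease_de
        t = de.for_contrast("IPF_vs_control")
        hits = set(t.index[t["adj_p"] < 0.05])
        false = hits - set(truth.common_up)
        assert len(false) <= 0.1 * max(len(hits), 1)
        assert len(hits & set(truth.common_up)) >= 0.9 * len(truth.common_up)

    def test_adj_p_at_least_p(self, one_disease_de):
        _, _, de = one_disease_de
        t = de.table.dropna(subset=["p_value"])
        assert (t["adj_p"] >= t["p_value"] - 1e-12).all()

    def test_pct_expressed_in_unit_fractions(self, one_disease_de):
        pb, _, de = one_disease_de
        pct = de.group_pct_expressed
        assert ((pct >= 0) & (pct <= 1)).all().all()
        grp = (pb.unit_meta["disease_state"] == "IPF").to_numpy()
        manual = (pb.counts[:, grp] > 0).mean(axis=1)
        assert np.allclose(pct["IPF"].to_numpy(), manual)

    def test_constant_gene_gives_null_result(self):
        Y = np.tile(np.arange(5, 55)[:, None], (1, 8))
        pb = make_pb(Y, disease_states=["control"] * 4 + ["IPF"] * 4)
        design = DesignSpec(batch_col=None,
                            contrasts=[("c", "IPF", "control")])
        de = fit_contrasts(pb, design)
        t = de.for_contrast("c")
        assert np.allclose(t["log2FC"], 0.0, atol=1e-6)
        assert (t["p_value"].dropna() > 0.99).all()

    def test_absent_level_rejected(self, one_disease_de):
        pb, _, _ = one_disease_de
        design = DesignSpec(contrasts=[("x", "COPD", "control")])
        with pytest.raises(ValidationError, match="absent"):
            fit_contrasts(pb, design)

    def test_strategies_agree_in_sign_on_planted_effects(self):
        pb, truth = _two_batch_pb(seed=31)
        design = DesignSpec(contrasts=[("d", "disease", "control")])
        cov = fit_contrasts(pb, design, strategy="covariate")
        adj = fit_contrasts(pb, design, strategy="count_adjust")
        planted = list(truth.common_up)
        s1 = np.sign(cov.for_contrast("d").loc[planted, "log2FC"])
        s2 = np.sign(adj.for_contrast("d").loc[planted, "log2FC"])
        assert (s1 == s2).all()
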