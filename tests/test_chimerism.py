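"""Variant filtering, two-genotype EM demultiplexing and the donor/recipient
classification rules."""

import numpy as np
import pandas as pd
import pytest

from crossbulk import (
    AlleleCountMatrix,
    ValidationError,
    apply_probability_filter,
    assign_chimeric_cell_types,
    chimerism_proportions,
    demux_two_genotypes,
    filter_variants,
    generate_allele_counts,
    label_donor_recipient,
)
from crossbulk.chimerism import DemuxAssignment
from crossbulk.synthetic import read_allele_counts


def make_ac(ref, alt, pop_af=None):
    ref = np.atleast_2d(ref)
    return AlleleCountMatrix(
        ref_umis=ref, alt_umis=np.atleast_2d(alt),
        variant_ids=np.array([f"V{j}" for j in range(ref.shape[1])], dtype=object),
        cell_ids=np.array([f"c{i}" for i in range(ref.shape[0])], dtype=object),
        pop_af=pop_af)


class TestFilterVariants:
    def test_threshold_rules(self):
        # V0: 19 UMIs -> removed; V1: 100 UMIs, 9% minor -> removed;
        # V2: 100 UMIs, 50 alt -> kept
        ref = np.array([[10, 91, 50]])
        alt = np.array([[9, 9, 50]])
        kept = filter_variants(make_ac(ref, alt))
        assert list(kept.variant_ids) == ["V2"]

    def test_population_af_rule(self):
        ref = np.array([[50, 50]])
        alt = np.array([[50, 50]])
        kept = filter_variants(make_ac(ref, alt, pop_af=np.array([0.04, 0.3])))
        assert list(kept.variant_ids) == ["V1"]

    def test_all_removed_raises(self):
        with pytest.raises(ValidationError, match="relax"):
            filter_variants(make_ac([[1]], [[1]]))


class TestDemux:
    def test_recovery_on_synthetic_mixture(self):
        ac, truth = generate_allele_counts(400, 60, depth=3.0, doublet_rate=0.0,
                                           genotype_divergence=0.5, seed=8)
        d = demux_two_genotypes(filter_variants(ac), seed=8)
        a = d.assignment.copy()
        a["truth"] = truth.genotype
        conf = a[a["group"].isin(["g1", "g2"])]
        acc = (conf["group"] == conf["truth"]).mean()
        assert max(acc, 1 - acc) >= 0.98

    def test_identical_profiles_identical_posteriors(self):
        ac, _ = generate_allele_counts(100, 30, depth=4.0, doublet_rate=0.0,
                                       genotype_divergence=0.8, seed=2)
        ref = np.vstack([ac.ref_umis, ac.ref_umis[:1]])
        alt = np.vstack([ac.alt_umis, ac.alt_umis[:1]])
        d = demux_two_genotypes(make_ac(ref, alt), seed=2)
        a = d.assignment
        assert np.allclose(
            a.loc[a.index[-1], ["p_g1", "p_g2", "p_doublet"]].astype(float),
            a.loc[0, ["p_g1", "p_g2", "p_doublet"]].astype(float))

    def test_loglik_monotone(self):
        ac, _ = generate_allele_counts(300, 40, depth=2.0, doublet_rate=0.05,
                                       genotype_divergence=0.4, seed=5)
        d = demux_two_genotypes(filter_variants(ac), seed=5)
        assert np.all(np.diff(d.ll_trace) >= -1e-6)

    def test_collapsed_clusters_leave_cells_unassigned(self):
        # all cells share one genotype profile: nothing to separate
        rng = np.random.default_rng(0)
        dp = rng.poisson(4.0, size=(80, 20))
        alt = rng.binomial(dp, 0.5)
        d = demux_two_genotypes(make_ac(dp - alt, alt), seed=0)
        assert (d.assignment["group"] == "unassigned").all()

    def test_accuracy_monotone_in_depth_and_divergence(self):
        accs = {}
        for div in (0.2, 0.5, 1.0):
            for depth in (1.0, 3.0, 5.0):
                ac, truth = generate_allele_counts(
                    300, 60, depth=depth, doublet_rate=0.0,
                    genotype_divergence=div, seed=17)
                d = demux_two_genotypes(filter_variants(ac), seed=17)
                a = d.assignment.copy()
                a["truth"] = truth.genotype
                conf = a[a["group"].isin(["g1", "g2"])]
                raw = (conf["group"] == conf["truth"]).mean()
                accs[(div, depth)] = max(raw, 1 - raw)
        for div in (0.2, 0.5, 1.0):
            assert accs[(div, 1.0)] <= accs[(div, 3.0)] + 1e-9
            assert accs[(div, 3.0)] <= accs[(div, 5.0)] + 1e-9
        for depth in (1.0, 3.0, 5.0):
            assert accs[(0.2, depth)] <= accs[(0.5, depth)] + 1e-9
            assert accs[(0.5, depth)] <= accs[(1.0, depth)] + 1e-9


def fake_assignment(groups, p_max):
    n = len(groups)
    df = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "group": groups,
        "posterior": p_max,
        "p_g1": [p if g == "g1" else (1 - p) * 0.9 for g, p in zip(groups, p_max)],
        "p_g2": [p if g == "g2" else (1 - p) * 0.9 for g, p in zip(groups, p_max)],
        "p_doublet": [p if g == "doublet" else (1 - p) * 0.1
                      for g, p in zip(groups, p_max)],
    })
    return DemuxAssignment(assignment=df)


class TestProbabilityFilter:
    def test_low_confidence_unassigned(self):
        d = fake_assignment(["g1", "g1", "g2", "doublet"],
                            [0.85, 0.95, 0.91, 0.99])
        out = apply_probability_filter(d).assignment
        assert list(out["group"]) == ["unassigned", "g1", "g2", "doublet"]


def chimera_meta(groups):
    comp = {"g1": "epithelial", "g2": "immune"}
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(len(groups))],
        "cell_type": ["AT2"] * len(groups),
        "compartment": [comp[g] if g in comp else "immune" for g in groups],
        "patient": ["P1"] * len(groups),
    })


class TestDonorRecipient:
    def test_structural_dominance_rule(self):
        groups = ["g1"] * 10 + ["g2"] * 10
        d = fake_assignment(groups, [0.99] * 20)
        meta = chimera_meta(groups)
        mapping, fracs = label_donor_recipient(d, meta)
        assert mapping == {"g1": "donor", "g2": "recipient"}
        assert fracs["g1"] == 1.0 and fracs["g2"] == 0.0

    def test_label_switch_invariance(self):
        groups = ["g1"] * 10 + ["g2"] * 10
        d = fake_assignment(groups, [0.99] * 20)
        meta = chimera_meta(groups)
        swapped = fake_assignment(
            ["g2" if g == "g1" else "g1" for g in groups], [0.99] * 20)
        m1, _ = label_donor_recipient(d, meta)
        m2, _ = label_donor_recipient(swapped, meta)
        origins1 = [m1[g] for g in d.assignment["group"]]
        origins2 = [m2[g] for g in swapped.assignment["group"]]
        assert origins1 == origins2

    def test_exact_tie_raises(self):
        groups = ["g1", "g1", "g2", "g2"]
        d = fake_assignment(groups, [0.99] * 4)
        meta = chimera_meta(groups)
        meta["compartment"] = ["epithelial", "immune", "epithelial", "immune"]
        with pytest.raises(ValidationError, match="tie"):
            label_donor_recipient(d, meta)


class TestProportions:
    def test_ratio_and_small_group_rule(self):
        groups = ["g1"] * 21 + ["g2"] * 9 + ["g1"] * 19 + ["doublet"] * 3
        d = fake_assignment(groups, [0.99] * len(groups))
        meta = chimera_meta(groups)
        meta.loc[30:48, "cell_type"] = "Rare"
        meta.loc[49:, "cell_type"] = "AT2"
        mapping = {"g1": "donor", "g2": "recipient"}
        rep = chimerism_proportions(d, meta, mapping)
        at2 = rep[rep.cell_type == "AT2"].iloc[0]
        rare = rep[rep.cell_type == "Rare"].iloc[0]
        assert at2.n_total == 30 and at2.n_recipient == 9
        assert at2.proportion == pytest.approx(0.30)
        assert rare.n_total == 19 and not rare.applicable
        assert np.isnan(rare.proportion)


def test_allele_tsv_round_trip(tmp_path):
    ac, _ = generate_allele_counts(20, 8, depth=3.0, doublet_rate=0.0,
                                   genotype_divergence=0.9, seed=4)
    path = tmp_path / "alleles.tsv"
    ac.to_tsv(path)
    back = read_allele_counts(path)
    # cells/variants with no coverage at all may drop out of the long format
    keep_c = np.isin(ac.cell_ids, back.cell_ids)
    keep_v = np.isin(ac.variant_ids, back.variant_ids)
    assert np.array_equal(back.ref_umis, ac.ref_umis[np.ix_(keep_c, keep_v)])
    assert np.array_equal(back.alt_umis, ac.alt_umis[np.ix_(keep_c, keep_v)])


def test_chimeric_type_plan_fractions():
    _, truth = generate_allele_counts(500, 30, depth=3.0, doublet_rate=0.05,
                                      genotype_divergence=0.6, seed=6,
                                      g2_fraction=0.5)
    plan = [("AT2", "epithelial", 100, 0.25), ("AM", "immune", 50, 0.8)]
    meta = assign_chimeric_cell_types(truth.genotype, plan, seed=6)
    labels = np.array(truth.genotype)
    at2 = meta[meta.cell_type == "AT2"]
    assert len(at2) == 100
    assert (labels[at2.cell_index] == "g2").sum() == 25
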