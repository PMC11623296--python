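import numpy as np
import pandas as pd
import pytest
import yaml

from tdratio import (build_references, cohort_td_ratios, read_expression_matrix,
                     read_gene_sets_gmt, read_sample_annotation)
from tdratio.simulate import CohortSimulator, SimulationConfig


def _cfg(**kw):
    base = dict(n_genes=300, n_patients=6, n_normal_per_tissue=5, seed=42)
    base.update(kw)
    return SimulationConfig(**base)


class TestDeterminism:
    def test_fixed_seed_bitwise_identical(self):
        a = CohortSimulator(_cfg()).generate_reference_cohort()[0]
        b = CohortSimulator(_cfg()).generate_reference_cohort()[0]
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_tumor_cohort_identical_too(self):
        a = CohortSimulator(_cfg()).generate_tumor_cohort("colon", "liver")[0]
        b = CohortSimulator(_cfg()).generate_tumor_cohort("colon", "liver")[0]
        pd.testing.assert_frame_equal(a.data, b.data)


class TestReferenceCohort:
    def test_one_sample_per_tissue_reference_equals_sample(self):
        sim = CohortSimulator(_cfg(n_normal_per_tissue=1))
        normals, ann = sim.generate_reference_cohort()
        refs = build_references(normals, ann)
        for tissue, ref in refs.items():
            sid = ann.loc[ann["origin_tissue"] == tissue, "sample_id"].iloc[0]
            np.testing.assert_allclose(ref.values, normals.data[sid])

    def test_zero_separation_tissues_closer_than_separated(self):
        cfg = _cfg(n_genes=2000, tissues=("a", "b", "c"), separation=1.0)
        sim = CohortSimulator(cfg)
        # collapse b onto a: zero-separation pair
        sim.tissue_log_means["b"] = sim.tissue_log_means["a"].copy()
        normals, ann = sim.generate_reference_cohort()
        refs = build_references(normals, ann)
        from tdratio import transcriptomic_distance
        d_ab = transcriptomic_distance(refs["a"].values.to_numpy(), refs["b"])
        d_ac = transcriptomic_distance(refs["a"].values.to_numpy(), refs["c"])
        assert d_ab < d_ac


class TestTumorCohort:
    def test_alpha_zero_zero_noise_collapses_to_ot(self):
        cfg = _cfg(noise_sd=0.0, tumor_offset_sd=0.0,
                   alpha_primary=0.0, alpha_met=0.0)
        sim = CohortSimulator(cfg)
        normals, nann = sim.generate_reference_cohort()
        tumors, tann = sim.generate_tumor_cohort("colon", "liver")
        refs = build_references(normals, nann)
        td = cohort_td_ratios(tumors, tann, refs)
        assert (td["ratio"] == 0).all()

    def test_median_ratio_increases_with_alpha(self):
        medians = []
        for alpha in (0.0, 0.25, 0.5, 0.75, 1.0):
            sim = CohortSimulator(_cfg(n_genes=800, n_patients=15, paired=False,
                                       alpha_primary=alpha, seed=9))
            normals, nann = sim.generate_reference_cohort()
            tumors, tann = sim.generate_tumor_cohort("colon", "liver")
            refs = build_references(normals, nann)
            td = cohort_td_ratios(tumors, tann, refs)
            medians.append(td["ratio"].median())
        assert all(np.diff(medians) > 0)

    def test_paired_patients_have_both_roles(self):
        _, ann = CohortSimulator(_cfg()).generate_tumor_cohort("colon", "liver")
        by_pt = ann.groupby("patient_id")["role"].apply(set)
        assert all(s == {"primary", "metastatic"} for s in by_pt)

    def test_unpaired_cohort_has_no_metastases(self):
        _, ann = CohortSimulator(_cfg(paired=False)).generate_tumor_cohort("colon", "liver")
        assert set(ann["role"]) == {"primary"}

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            CohortSimulator(_cfg()).generate_tumor_cohort("colon", "liver",
                                                          alpha_met=-0.2)

    def test_purity_recorded_and_confounding(self):
        # with purity mixing on, lower purity drags samples toward the OT,
        # inducing a positive ratio-purity association
        hits = 0
        for seed in range(10):
            sim = CohortSimulator(_cfg(n_genes=500, n_patients=25, paired=False,
                                       purity_mixing=True, alpha_primary=0.5,
                                       seed=seed))
            normals, nann = sim.generate_reference_cohort()
            tumors, tann = sim.generate_tumor_cohort("colon", "liver")
            assert tann["purity"].between(0, 1).all()
            refs = build_references(normals, nann)
            td = cohort_td_ratios(tumors, tann, refs)
            from scipy.stats import spearmanr
            rho, p = spearmanr(td["ratio"], td["purity"])
            hits += (rho > 0) and (p < 0.05)
        assert hits >= 9


class TestPlantPathwayShift:
    def test_only_set_genes_change(self):
        sim = CohortSimulator(_cfg())
        tumors, tann = sim.generate_tumor_cohort("colon", "liver")
        gset = sim.genes[:10]
        shifted = sim.plant_pathway_shift(tumors, tann, gset, 0.9, "colon", "liver")
        untouched = [g for g in sim.genes if g not in gset]
        pd.testing.assert_frame_equal(shifted.data.loc[untouched],
                                      tumors.data.loc[untouched])
        assert not np.allclose(shifted.data.loc[gset], tumors.data.loc[gset])

    def test_unknown_gene_error(self):
        sim = CohortSimulator(_cfg())
        tumors, tann = sim.generate_tumor_cohort("colon", "liver")
        with pytest.raises(KeyError):
            sim.plant_pathway_shift(tumors, tann, ["NOPE"], 0.9, "colon", "liver")

    def test_matched_alpha_statistically_unchanged(self):
        # replanting with the cohort's own mixture weight only resamples noise:
        # group medians of the pathway TD ratio stay near the originals
        from tdratio import score_pathways, GeneSetCollection
        sim = CohortSimulator(_cfg(n_genes=500, n_patients=10, seed=3))
        normals, nann = sim.generate_reference_cohort()
        tumors, tann = sim.generate_tumor_cohort("colon", "liver")
        gset = sim.genes[:40]
        shifted = sim.plant_pathway_shift(tumors, tann, gset, sim.cfg.alpha_primary,
                                          "colon", "liver")
        refs = build_references(normals, nann)
        gs = GeneSetCollection({"S": gset})
        from tdratio import pathway_value_table
        t0 = pathway_value_table(tumors, tann, refs, gs)
        t1 = pathway_value_table(shifted, tann, refs, gs)
        pri0 = t0.set_index("class").loc["primary", "delta"]
        pri1 = t1.set_index("class").loc["primary", "delta"]
        assert pri1 == pytest.approx(pri0, rel=0.35)


class TestGenerateGeneSets:
    def test_reproducible_sizes_and_uniqueness(self):
        sim = CohortSimulator(_cfg())
        a = sim.generate_gene_sets(10, (5, 15), seed=2)
        b = sim.generate_gene_sets(10, (5, 15), seed=2)
        assert a.sets == b.sets
        for genes in a.sets.values():
            assert 5 <= len(genes) <= 15
            assert len(set(genes)) == len(genes)

    def test_invalid_size_range(self):
        with pytest.raises(ValueError):
            CohortSimulator(_cfg()).generate_gene_sets(3, (10, 5000))


@pytest.fixture(scope="module")
def bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    sim = CohortSimulator(_cfg(purity_mixing=True))
    truth = sim.write_fixture_bundle(out, planted={"SET_0001": 0.9})
    return out, truth


class TestFixtureBundle:
    def test_round_trip_to_1e12(self, bundle):
        out, _ = bundle
        sim = CohortSimulator(_cfg(purity_mixing=True))
        normals, _ = sim.generate_reference_cohort()
        back = read_expression_matrix(out / "normals.tsv", "cpm")
        np.testing.assert_allclose(back.data.to_numpy(),
                                   normals.data.to_numpy(), rtol=1e-12)

    def test_ground_truth_lists_planted_pathways(self, bundle):
        out, truth = bundle
        on_disk = yaml.safe_load((out / "ground_truth.yaml").read_text())
        assert on_disk["planted_pathways"] == {"SET_0001": 0.9}
        assert truth["planted_pathways"] == {"SET_0001": 0.9}

    def test_bundle_files_parse(self, bundle):
        out, _ = bundle
        ann = read_sample_annotation(out / "tumors_annotation.tsv")
        assert set(ann["role"]) == {"primary", "metastatic"}
        assert ann["purity"].notna().all()
        gs = read_gene_sets_gmt(out / "gene_sets.gmt")
        assert len(gs) == 20

    def test_same_seed_identical_bundles(self, tmp_path):
        d1, d2 = tmp_path / "b1", tmp_path / "b2"
        CohortSimulator(_cfg()).write_fixture_bundle(d1)
        CohortSimulator(_cfg()).write_fixture_bundle(d2)
        assert (d1 / "tumors.tsv").read_text() == (d2 / "tumors.tsv").read_text()
        assert (d1 / "gene_sets.gmt").read_text() == (d2 / "gene_sets.gmt").read_text()
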