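"""Generator contracts: Mendelian consistency, ascertainment, injection rates,
annotation structure, and the reference-cohort emission model."""

import numpy as np
import pandas as pd
import pytest

from sle_trio import trio
from sle_trio.cohort import simulate_cohort, simulate_reference
from sle_trio.config import SimulationConfig, preset
from sle_trio.refine import assemble_trio_genotypes
from sle_trio.workflow import enrichment_from_cohort


def _trio_gt_arrays(cohort):
    fams = cohort.families
    child = cohort.common_gt.loc[fams["patient"]].to_numpy()
    mother = cohort.common_gt.loc[fams["mother"]].to_numpy()
    father = cohort.common_gt.loc[fams["father"]].to_numpy()
    return child, mother, father


def _mendelian_fraction(cohort):
    child, mother, father = _trio_gt_arrays(cohort)
    ok = 0
    total = child.size
    for c, m, f in zip(child.ravel(), mother.ravel(), father.ravel()):
        ok += trio.mendelian_consistent(int(c), int(m), int(f))
    # rare variants: every recorded trio is checked too
    wide = assemble_trio_genotypes(cohort.rare_gt, cohort.families)
    for row in wide.itertuples(index=False):
        total += 1
        ok += trio.mendelian_consistent(int(row.child), int(row.mother), int(row.father))
    return ok / total


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        {"n_families": 0},
        {"n_reference": -1},
        {"panel_enrichment_factor": 0.5},
        {"rare_maf_max": 0.2},          # not below min common MAF
        {"one_parent_fraction": 1.5},
        {"reference_singleton_call_rate": 0.0},
        {"n_causal_markers": 500},
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            SimulationConfig(**bad)

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            preset("nope")


def test_error_free_cohort_is_fully_mendelian_consistent(tiny_cohort):
    assert _mendelian_fraction(tiny_cohort) == 1.0


def test_genotype_errors_create_mendelian_inconsistencies():
    cfg = preset("tiny", seed=7).replace(genotype_error_rate=0.05)
    noisy = simulate_cohort(cfg)
    assert _mendelian_fraction(noisy) < 1.0
    # truth matrix remains clean
    assert (noisy.common_gt_true.to_numpy() != noisy.common_gt.to_numpy()).any()


def test_affected_offspring_exceed_liability_threshold(tiny_cohort):
    thr = tiny_cohort.config.liability_threshold
    for patient in tiny_cohort.patients:
        assert tiny_cohort.truth.liabilities[patient] > thr


def test_injected_variants_are_carried_by_their_transmitting_parent(tiny_cohort):
    gt = tiny_cohort.rare_gt.set_index(["variant_id", "sample_id"])["gt"]
    for row in tiny_cohort.truth.injected_panel_variants.itertuples(index=False):
        patient_gt = gt[(row.variant_id, f"{row.family}_P")]
        if row.zygosity == "hom":
            assert patient_gt == 2
            assert gt[(row.variant_id, f"{row.family}_M")] >= 1
            assert gt[(row.variant_id, f"{row.family}_F")] >= 1
        else:
            assert patient_gt == 1
            assert gt[(row.variant_id, row.transmitting_parent)] >= 1


def test_panel_injection_rate_matches_enrichment_target(recovery_run):
    """Mean injected panel variants per patient = background x enrichment."""
    cohort = recovery_run.cohort
    cfg = cohort.config
    injected = cohort.truth.injected_panel_variants
    het = injected[injected["zygosity"] == "het"]
    rate = len(het) / cfg.n_families
    target = cfg.panel_rare_rate_background * cfg.panel_enrichment_factor
    se = np.sqrt(target / cfg.n_families)
    assert abs(rate - target) < 3 * se


def test_common_marker_maf_converges_in_unascertained_parents():
    """Parent allele frequencies match generating MAFs without selection."""
    cfg = preset("paper_like", seed=5).replace(
        n_families=500, one_parent_fraction=0.0, liability_threshold=-10.0,
        n_controls=2, n_training_cases=2, genomewide_rare_rate=0.5,
        n_pool_rare=10, n_reference=50)
    cohort = simulate_cohort(cfg)
    parents = cohort.samples.loc[
        cohort.samples["role"].isin(["mother", "father"]), "sample_id"]
    dosage = cohort.common_gt.loc[parents].to_numpy()
    emp = dosage.mean(axis=0) / 2.0
    gen = cohort.common_markers["maf"].to_numpy()
    se = np.sqrt(gen * (1 - gen) / (2 * len(parents)))
    z = np.abs(emp - gen) / se
    assert (z > 3).sum() <= 2          # ~0.3 expected by chance over 120 markers
    assert z.mean() < 1.2


def test_reference_allele_number_is_diploid(tiny_cohort):
    an = tiny_cohort.reference_counts["an"]
    assert (an == 2 * tiny_cohort.config.n_reference).all()
    assert (tiny_cohort.reference_counts["ac"] >= 0).all()


def test_reference_reproducible_without_trio_simulation(tiny_cohort):
    ref = simulate_reference(tiny_cohort.config)
    pd.testing.assert_frame_equal(ref, tiny_cohort.reference_counts)


def test_reference_deflation_recovered_by_normalization_factor():
    """A 0.8 singleton call rate shows up as a ~1.25 correction factor."""
    cfg = preset("null", seed=4).replace(
        n_families=200, reference_singleton_call_rate=0.8)
    results = enrichment_from_cohort(simulate_cohort(cfg))
    ultra = next(r for r in results
                 if r.stratum.annotation_class == "non_silent_coding"
                 and r.stratum.maf_bin[0] == 0.0)
    assert ultra.normalization_factor == pytest.approx(1.25, abs=0.07)


class TestAnnotations:
    def test_deleterious_injections_have_damaging_scores(self, tiny_cohort):
        rv = tiny_cohort.rare_variants
        deleterious = rv[rv["deleterious"] & (rv["vclass"] == "missense")]
        assert (deleterious["dann"] >= 0.9).all()
        assert (deleterious["sift"] < 0.05).all()

    def test_promoter_variants_sit_in_promoter_intervals(self, tiny_cohort):
        rv = tiny_cohort.rare_variants
        prom = rv[(rv["origin"] == "panel_promoter")]
        for row in prom.itertuples(index=False):
            hit = tiny_cohort.panel.locate(row.chrom, row.pos)
            assert hit is not None and hit[1] == "promoter"

    def test_missing_class_filled_from_panel_location(self, tiny_cohort):
        from sle_trio.cohort import emit_annotations
        gene = tiny_cohort.panel.genes[0]
        variants = pd.DataFrame({
            "variant_id": ["x1", "x2", "x3"],
            "chrom": [gene.chrom, gene.chrom, "chrS9"],
            "pos": [gene.promoter[0] + 1, gene.coding[0][0] + 1, 5],
            "ref": "A", "alt": "G", "vclass": [None, None, None],
            "ref_maf": 0.0, "dann": np.nan, "sift": np.nan, "polyphen": np.nan,
        })
        ann = emit_annotations(variants, tiny_cohort.panel)
        assert list(ann["class"]) == ["promoter", "missense", "other"]

    def test_case_private_variants_absent_from_reference(self, tiny_cohort):
        rv = tiny_cohort.rare_variants
        private = rv[rv["origin"].str.startswith(("panel_injected", "background",
                                                  "panel_silent", "panel_promoter"))]
        assert (private["ref_maf"] == 0.0).all()
        assert not set(private["variant_id"]) & set(
            tiny_cohort.reference_counts["variant_id"])


def test_acr_phenotypes_fulfil_minimum_criteria(paper_analysis):
    cohort = paper_analysis.cohort
    crit = cohort.phenotypes.drop(columns=["sample_id"])
    assert (crit.sum(axis=1) >= cohort.config.min_acr_criteria).all()
    carriers = {
        f"{row.family}_P"
        for row in cohort.truth.injected_panel_variants.itertuples(index=False)
        if row.deleterious and row.zygosity == "het"}
    pheno = cohort.phenotypes.set_index("sample_id")
    assert (pheno.loc[sorted(carriers), "renal"] == 0).all()


def test_designated_parent_present_in_every_family(tiny_cohort):
    assert set(tiny_cohort.truth.high_burden_parent.values()) <= {"mother", "father"}
    assert len(tiny_cohort.truth.high_burden_parent) == tiny_cohort.config.n_families
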