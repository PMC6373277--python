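"""End-to-end in-memory analysis of a synthetic trio cohort.

Chains the stages — simulate, refine, score, enrich, prioritize, clinical
— over in-memory objects.  The file-based pipeline (:mod:`sle_trio.pipeline`)
drives the same library functions over emitted artifacts; this module is
what the analysis drivers, recovery studies and acceptance checks use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import clinical, enrichment, prioritize, refine, risk
from .cohort import TrioCohort, simulate_cohort
from .config import SimulationConfig


@dataclass
class AnalysisResult:
    cohort: TrioCohort
    trio_calls: pd.DataFrame
    flagged: set
    model: risk.RiskModel
    scores: pd.DataFrame
    partition: pd.DataFrame
    correlations: dict
    strata: list = field(default_factory=list)
    enrichment: list = field(default_factory=list)
    candidates: pd.DataFrame | None = None
    zygosity: prioritize.ZygositySummary | None = None
    carrier_correlations: dict | None = None
    acr: pd.DataFrame | None = None

    def ultra_rare_coding(self) -> enrichment.EnrichmentResult:
        """The headline stratum: ultra-rare non-silent coding panel variants."""
        for r in self.enrichment:
            if (r.stratum.annotation_class == "non_silent_coding"
                    and r.stratum.maf_bin[0] == 0.0):
                return r
        raise LookupError("no ultra-rare coding stratum present")


def enrichment_from_cohort(
    cohort: TrioCohort,
    flagged=(),
    bin_edges=enrichment.DEFAULT_BIN_EDGES,
    count_mode: str = "carrier",
) -> list[enrichment.EnrichmentResult]:
    """Stratified, normalized, Bonferroni-corrected enrichment for a cohort."""
    strata = enrichment.count_strata(
        annotations=cohort.annotations(),
        case_gt=cohort.rare_gt,
        case_sample_ids=cohort.patients,
        ref_counts=cohort.reference_counts,
        panel=cohort.panel,
        n_ref_genomes=cohort.config.n_reference,
        bin_edges=bin_edges,
        flagged=flagged,
        count_mode=count_mode,
    )
    return enrichment.correct_multiple_testing(
        [enrichment.enrichment_test(s) for s in strata])


def run_analysis(
    config: SimulationConfig,
    n_trees: int = risk.DEFAULT_N_TREES,
    count_mode: str = "carrier",
    cohort: TrioCohort | None = None,
) -> AnalysisResult:
    """Simulate (unless given a cohort) and run every analysis stage."""
    if cohort is None:
        cohort = simulate_cohort(config)

    # trio refinement; sites with a low-quality patient call are excluded
    trios = refine.assemble_trio_genotypes(cohort.rare_gt, cohort.families)
    calls = refine.refine_trio_calls(trios, pl_gap=config.pl_gap)
    flagged = refine.flagged_variants(calls)

    # risk scoring on the case/control training panel
    train_ids = cohort.samples_by_role("case_training") + cohort.samples_by_role("control")
    labels = [1] * len(cohort.samples_by_role("case_training")) + \
             [0] * len(cohort.samples_by_role("control"))
    model = risk.train_model(cohort.genotype_matrix(train_ids), labels,
                             n_trees=n_trees, seed=config.seed)
    scores = risk.score_table(model, cohort)
    partition = risk.partition_parents(scores, cohort.families)
    correlations = risk.correlation_report(scores, cohort.families, partition)

    results = enrichment_from_cohort(cohort, flagged=flagged, count_mode=count_mode)
    strata = [r.stratum for r in results]

    # prioritization with parent-of-origin annotations
    ann = cohort.annotations()
    poo = dict(zip(calls["variant_id"], calls["parent_of_origin"]))
    candidates = prioritize.filter_candidates(
        ann, cohort.rare_gt, cohort.patients, cohort.panel,
        flagged=flagged, scores=scores, parent_of_origin=poo)
    head = prioritize.headline(candidates)
    zygosity = prioritize.zygosity_summary(head)

    # mode of inheritance for heterozygous candidate families
    het_head = head[head["zygosity"] == "het"]
    carrier_map = refine.carrier_parent_map(
        cohort.rare_gt, cohort.families, het_head["variant_id"])
    carrier_by_family = {fam: parent for fam, parent in carrier_map.values()}
    carrier_corr = risk.carrier_correlation_report(
        scores, cohort.families, carrier_by_family)

    # ACR sub-phenotype comparison: het candidate carriers vs non-carriers
    carriers = set(het_head["carrier"])
    acr_table = cohort.phenotypes.copy()
    acr_table["carrier"] = acr_table["sample_id"].isin(carriers)
    acr = (clinical.acr_comparison(acr_table)
           if 0 < len(carriers) < len(acr_table) else None)

    return AnalysisResult(
        cohort=cohort, trio_calls=calls, flagged=flagged, model=model,
        scores=scores, partition=partition, correlations=correlations,
        strata=strata, enrichment=results, candidates=candidates,
        zygosity=zygosity, carrier_correlations=carrier_corr, acr=acr,
    )
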