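"""File-based pipeline stages over the emitted artifacts.

Each stage reads the artifacts of its predecessors from the output
directory, runs the corresponding library functions, and writes its own
artifacts with provenance headers.  Stages are idempotent given identical
inputs and seeds; a missing prerequisite raises with the artifact name.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import clinical, enrichment, io, plots, prioritize, refine, risk
from .cohort import simulate_cohort
from .config import SimulationConfig

log = logging.getLogger(__name__)

ARTIFACTS = {
    "vcf": "cohort.vcf",
    "ped": "trios.ped",
    "bed": "panel.bed",
    "annotations": "annotations.tsv",
    "reference": "reference_counts.tsv",
    "phenotypes": "phenotypes.tsv",
    "truth": "truth.json",
    "training_dosages": "training_dosages.tsv",
    "trio_dosages": "trio_dosages.tsv",
    "trio_calls": "trio_calls.tsv",
    "refined_vcf": "cohort.refined.vcf",
    "model": "risk_model.joblib",
    "scores": "scores.tsv",
    "partition": "parent_partition.tsv",
    "correlations": "correlations.json",
    "enrichment": "enrichment.tsv",
    "candidates": "candidates.tsv",
    "prioritization": "prioritization_summary.json",
    "acr": "acr_comparison.tsv",
    "summary": "summary.json",
}


def _path(out_dir, key: str, must_exist: bool = False) -> Path:
    p = Path(out_dir) / ARTIFACTS[key]
    if must_exist and not p.exists():
        raise FileNotFoundError(
            f"missing artifact {p.name!r}; run the stage that produces it first")
    return p


def stage_simulate(cfg: SimulationConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(cfg)
    h, s = cfg.digest(), cfg.seed
    io.write_vcf(cohort, _path(out, "vcf"))
    io.write_ped(cohort, _path(out, "ped"))
    io.write_bed(cohort.panel, _path(out, "bed"))
    io.write_tsv(cohort.annotations(), _path(out, "annotations"), h, s)
    io.write_tsv(cohort.reference_counts, _path(out, "reference"), h, s)
    io.write_tsv(cohort.phenotypes, _path(out, "phenotypes"), h, s)
    io.write_truth(cohort.truth, _path(out, "truth"))
    io.write_dosage_tsv(cohort, ("case_training", "control"),
                        _path(out, "training_dosages"), h, s)
    io.write_dosage_tsv(cohort, ("patient", "mother", "father"),
                        _path(out, "trio_dosages"), h, s)
    log.info("simulate: %d families, %d rare variants, %d reference records",
             len(cohort.families), len(cohort.rare_variants),
             len(cohort.reference_counts))


def stage_refine(cfg: SimulationConfig, out_dir) -> None:
    families = io.read_ped(_path(out_dir, "ped", must_exist=True))
    _, gts = io.read_vcf(_path(out_dir, "vcf", must_exist=True))
    rare = gts[~gts["variant_id"].str.startswith("cm")]
    trios = refine.assemble_trio_genotypes(rare, families)
    calls = refine.refine_trio_calls(trios, pl_gap=cfg.pl_gap)
    io.write_tsv(calls, _path(out_dir, "trio_calls"), cfg.digest(), cfg.seed)
    _annotate_vcf(_path(out_dir, "vcf"), _path(out_dir, "refined_vcf"), calls, families)
    log.info("refine: %d trio calls, %d flagged low quality",
             len(calls), int(calls["low_quality"].sum()))


def _annotate_vcf(src, dst, calls: pd.DataFrame, families: pd.DataFrame) -> None:
    """Copy a VCF, adding per-child GPP and the LOWGP site filter."""
    child_of = dict(zip(families["family"], families["patient"]))
    gpp = {(r.variant_id, child_of[r.family]): float(r.gpp)
           for r in calls.itertuples(index=False) if r.family in child_of}
    low = {r.variant_id for r in calls.itertuples(index=False) if r.low_quality}
    with pysam.VariantFile(str(src)) as vin:
        header = vin.header.copy()
        if "GPP" not in header.formats:
            header.formats.add("GPP", 1, "Float",
                               "Phred-scaled trio-refined genotype posterior")
        if "LOWGP" not in header.filters:
            header.filters.add("LOWGP", None, None,
                               "Refined genotype posterior below Q20 in a patient")
        with pysam.VariantFile(str(dst), "w", header=header) as vout:
            for rec in vin:
                rec.translate(header)
                if rec.id in low:
                    rec.filter.add("LOWGP")
                for sid in rec.samples:
                    if (rec.id, sid) in gpp:
                        rec.samples[sid]["GPP"] = gpp[(rec.id, sid)]
                vout.write(rec)


def _read_dosages(path) -> tuple[pd.DataFrame, pd.Series]:
    df = io.read_tsv(path)
    roles = df.set_index("sample_id")["role"]
    return df.drop(columns=["role"]).set_index("sample_id"), roles


def stage_score(cfg: SimulationConfig, out_dir, n_trees: int = risk.DEFAULT_N_TREES) -> None:
    train_x, train_roles = _read_dosages(_path(out_dir, "training_dosages", must_exist=True))
    trio_x, trio_roles = _read_dosages(_path(out_dir, "trio_dosages", must_exist=True))
    families = io.read_ped(_path(out_dir, "ped", must_exist=True))
    model = risk.train_model(train_x, (train_roles == "case_training").astype(int),
                             n_trees=n_trees, seed=cfg.seed)
    model.save(_path(out_dir, "model"))
    everyone = pd.concat([trio_x, train_x])
    scored = risk.score_samples(model, everyone)
    fam_of = {}
    for fam in families.itertuples(index=False):
        for sid in (fam.patient, fam.mother, fam.father):
            fam_of[sid] = fam.family
    roles = pd.concat([trio_roles, train_roles])
    scores = pd.DataFrame({
        "sample_id": scored.index,
        "family": [fam_of.get(s, "") for s in scored.index],
        "role": roles.reindex(scored.index).to_numpy(),
        "score": scored.to_numpy(),
    })
    partition = risk.partition_parents(scores, families)
    report = risk.correlation_report(scores, families, partition)
    io.write_tsv(scores, _path(out_dir, "scores"), cfg.digest(), cfg.seed)
    io.write_tsv(partition, _path(out_dir, "partition"), cfg.digest(), cfg.seed)
    _path(out_dir, "correlations").write_text(json.dumps(report, indent=1, sort_keys=True))
    log.info("score: %d samples scored; patient/higher-parent r=%.3f",
             len(scores), report["patient_vs_higher"]["r"])


def _case_inputs(out_dir):
    ann = io.read_tsv(_path(out_dir, "annotations", must_exist=True))
    families = io.read_ped(_path(out_dir, "ped", must_exist=True))
    variants, gts = io.read_vcf(_path(out_dir, "refined_vcf", must_exist=True))
    panel = io.read_bed(_path(out_dir, "bed", must_exist=True))
    flagged = set(variants.loc[variants["lowgp"], "variant_id"])
    rare = gts[~gts["variant_id"].str.startswith("cm")][["variant_id", "sample_id", "gt"]]
    return ann, families, rare, panel, flagged


def stage_enrich(cfg: SimulationConfig, out_dir, count_mode: str = "carrier") -> None:
    ann, families, rare, panel, flagged = _case_inputs(out_dir)
    ref = io.read_tsv(_path(out_dir, "reference", must_exist=True))
    n_ref = int(ref["an"].max() // 2)
    strata = enrichment.count_strata(
        ann, rare, list(families["patient"]), ref, panel, n_ref,
        flagged=flagged, count_mode=count_mode)
    results = enrichment.correct_multiple_testing(
        [enrichment.enrichment_test(s) for s in strata])
    table = enrichment.results_table(results)
    io.write_tsv(table, _path(out_dir, "enrichment"), cfg.digest(), cfg.seed)
    for r in results:
        log.info("enrich: %s OR=%.3g p=%.3g%s", r.label, r.odds_ratio, r.p_value,
                 " *" if r.significant else "")


def stage_prioritize(cfg: SimulationConfig, out_dir) -> None:
    ann, families, rare, panel, flagged = _case_inputs(out_dir)
    scores = io.read_tsv(_path(out_dir, "scores", must_exist=True))
    calls = io.read_tsv(_path(out_dir, "trio_calls", must_exist=True))
    poo = dict(zip(calls["variant_id"], calls["parent_of_origin"]))
    candidates = prioritize.filter_candidates(
        ann, rare, list(families["patient"]), panel,
        flagged=flagged, scores=scores, parent_of_origin=poo)
    io.write_tsv(candidates, _path(out_dir, "candidates"), cfg.digest(), cfg.seed)
    head = prioritize.headline(candidates)
    z = prioritize.zygosity_summary(head)
    summary = {
        "n_retained": int(len(candidates)),
        "n_headline": int(len(head)),
        **z._asdict(),
        "rounded_patients_per_carrier": (
            prioritize.rounded_patients_per_carrier(len(families), z.n_patients)
            if z.n_patients else None),
    }
    _path(out_dir, "prioritization").write_text(json.dumps(summary, indent=1))
    log.info("prioritize: %d candidates (%d headline) in %d patients",
             len(candidates), len(head), z.n_patients)


def stage_clinical(cfg: SimulationConfig, out_dir) -> None:
    pheno = io.read_tsv(_path(out_dir, "phenotypes", must_exist=True))
    candidates = io.read_tsv(_path(out_dir, "candidates", must_exist=True))
    head = prioritize.headline(candidates)
    carriers = set(head.loc[head["zygosity"] == "het", "carrier"])
    pheno = pheno.copy()
    pheno["carrier"] = pheno["sample_id"].isin(carriers)
    if pheno["carrier"].any() and not pheno["carrier"].all():
        acr = clinical.acr_comparison(pheno)
    else:
        acr = pd.DataFrame()
        log.warning("clinical: no carrier/non-carrier split available")
    io.write_tsv(acr, _path(out_dir, "acr"), cfg.digest(), cfg.seed)


def stage_report(cfg: SimulationConfig, out_dir, make_plots: bool = True) -> dict:
    scores = io.read_tsv(_path(out_dir, "scores", must_exist=True))
    partition = io.read_tsv(_path(out_dir, "partition", must_exist=True))
    families = io.read_ped(_path(out_dir, "ped", must_exist=True))
    correlations = json.loads(_path(out_dir, "correlations", must_exist=True).read_text())
    enr = io.read_tsv(_path(out_dir, "enrichment", must_exist=True))
    candidates = io.read_tsv(_path(out_dir, "candidates", must_exist=True))
    summary = {
        "seed": cfg.seed,
        "config_hash": cfg.digest(),
        "n_families": int(len(families)),
        "correlations": correlations,
        "enrichment": enr.to_dict("records"),
        "prioritization": json.loads(_path(out_dir, "prioritization").read_text()),
    }
    acr_path = _path(out_dir, "acr")
    if acr_path.exists():
        acr = io.read_tsv(acr_path)
        if len(acr):
            summary["acr"] = acr.to_dict("records")
    _path(out_dir, "summary").write_text(json.dumps(summary, indent=1, sort_keys=True))
    if make_plots:
        out = Path(out_dir)
        plots.score_distributions(scores, partition, out / "score_distributions.png")
        plots.enrichment_profile(enr, out / "enrichment_profile.png")
        head = prioritize.headline(candidates)
        carrier_by_family = {}
        sample_fam = dict(zip(scores["sample_id"], scores["family"]))
        for row in head.itertuples(index=False):
            fam = sample_fam.get(row.carrier, "")
            if fam and row.parent_of_origin in ("maternal", "paternal"):
                frow = families.set_index("family").loc[fam]
                carrier_by_family[fam] = (frow.mother if row.parent_of_origin == "maternal"
                                          else frow.father)
        if carrier_by_family:
            plots.carrier_scatter(scores, families, carrier_by_family,
                                  out / "carrier_correlation.png")
    return summary


STAGES = {
    "simulate": stage_simulate,
    "refine": stage_refine,
    "score": stage_score,
    "enrich": stage_enrich,
    "prioritize": stage_prioritize,
    "clinical": stage_clinical,
    "report": stage_report,
}
STAGE_ORDER = ["simulate", "refine", "score", "enrich", "prioritize", "clinical", "report"]


def run(subcommand: str, cfg: SimulationConfig, out_dir, **kwargs) -> None:
    """Run one stage, or all of them in order."""
    if subcommand == "all":
        for name in STAGE_ORDER:
            STAGES[name](cfg, out_dir)
        return
    if subcommand not in STAGES:
        raise ValueError(f"unknown stage {subcommand!r}")
    STAGES[subcommand](cfg, out_dir, **kwargs)
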