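"""File interfaces: VCF (via pysam), PED, BED, and provenance-headed TSVs.

Conventions: VCF coordinates are 1-based; BED intervals 0-based half-open.
Every emitted text table starts with ``##`` provenance lines (tool
version, configuration hash, master seed) so outputs are self-describing
and byte-identical across reruns with the same seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import __version__
from .cohort import TrioCohort
from .panel import GenePanel

CONTIG_LENGTH = 300_000_000
_GT_TUPLES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def provenance_lines(config_hash: str, seed: int) -> list[str]:
    return [
        f"## sle-trio version={__version__}",
        f"## config_hash={config_hash}",
        f"## master_seed={seed}",
    ]


def write_tsv(df: pd.DataFrame, path, config_hash: str = "", seed: int = 0) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in provenance_lines(config_hash, seed):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(cohort: TrioCohort, refined: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##sle_trio_version={__version__}")
    header.add_line(f"##sle_trio_config_hash={cohort.config.digest()}")
    header.add_line(f"##sle_trio_master_seed={cohort.config.seed}")
    contigs = sorted(set(cohort.common_markers["chrom"]) |
                     set(cohort.rare_variants["chrom"]))
    for contig in contigs:
        header.contigs.add(contig, length=CONTIG_LENGTH)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PL", "G", "Integer", "Phred-scaled genotype likelihoods")
    if refined:
        header.formats.add("GPP", 1, "Float",
                           "Phred-scaled trio-refined genotype posterior")
        header.filters.add("LOWGP", None, None,
                           "Refined genotype posterior below Q20 in a patient")
    for sid in cohort.samples.loc[
            cohort.samples["role"].isin(["patient", "mother", "father"]), "sample_id"]:
        header.add_sample(sid)
    return header


def write_vcf(cohort: TrioCohort, path, refined_calls: pd.DataFrame | None = None) -> None:
    """Multi-sample VCF of the trio cohort (common markers + rare variants).

    Children carry PL fields reconstructed from the emission model; when
    ``refined_calls`` is given, per-child GPP values are written and sites
    whose refined patient call is low quality get the LOWGP filter.
    """
    refined = refined_calls is not None
    header = _vcf_header(cohort, refined)
    trio_samples = list(header.samples)
    children = set(cohort.families["patient"])
    child_of = {fam.family: fam.patient for fam in cohort.families.itertuples(index=False)}

    gpp_by_site: dict[tuple[str, str], float] = {}
    low_sites: set[str] = set()
    if refined:
        for row in refined_calls.itertuples(index=False):
            child = child_of.get(row.family)
            if child is not None:
                gpp_by_site[(row.variant_id, child)] = float(row.gpp)
                if row.low_quality and child in children:
                    low_sites.add(row.variant_id)

    pl_gap = int(cohort.config.pl_gap)
    records = []

    common = cohort.common_gt.loc[[s for s in trio_samples]]
    for j, mk in enumerate(cohort.common_markers.itertuples(index=False)):
        gts = dict(zip(common.index, common[mk.variant_id]))
        records.append((mk.chrom, mk.pos, mk.variant_id, mk.ref, mk.alt, gts))

    rare_in_trios = cohort.rare_gt[cohort.rare_gt["sample_id"].isin(set(trio_samples))]
    gt_map: dict[str, dict[str, int]] = {}
    for row in rare_in_trios.itertuples(index=False):
        gt_map.setdefault(row.variant_id, {})[row.sample_id] = int(row.gt)
    for mk in cohort.rare_variants.itertuples(index=False):
        if mk.origin == "reference_private":
            continue
        records.append((mk.chrom, mk.pos, mk.variant_id, mk.ref, mk.alt,
                        gt_map.get(mk.variant_id, {})))

    records.sort(key=lambda r: (r[0], r[1], r[2]))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for chrom, pos, vid, ref, alt, gts in records:
            rec = vcf.new_record(contig=chrom, start=pos - 1, stop=pos,
                                 alleles=(ref, alt), id=vid)
            if vid in low_sites:
                rec.filter.add("LOWGP")
            for sid in trio_samples:
                g = gts.get(sid, 0)
                rec.samples[sid]["GT"] = _GT_TUPLES[g]
                if sid in children:
                    rec.samples[sid]["PL"] = [0 if k == g else pl_gap for k in range(3)]
                    if refined and (vid, sid) in gpp_by_site:
                        rec.samples[sid]["GPP"] = gpp_by_site[(vid, sid)]
            vcf.write(rec)


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a package-written VCF back into (variants, long genotypes).

    Carrier-only long format: hom-ref sample genotypes are not emitted as
    rows.  Child PL triples are attached to the genotype rows that have
    them; the variants table records the LOWGP filter state.
    """
    var_rows, gt_rows = [], []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            flagged = "LOWGP" in rec.filter
            var_rows.append((rec.id, rec.contig, rec.pos, rec.ref, rec.alts[0], flagged))
            for sid, call in rec.samples.items():
                alleles = call.get("GT")
                if alleles is None or all(a is None for a in alleles):
                    continue
                g = sum(a or 0 for a in alleles)
                if g == 0:
                    continue
                pl = call.get("PL")
                gt_rows.append((rec.id, sid, g, tuple(pl) if pl is not None else None))
    variants = pd.DataFrame(var_rows, columns=["variant_id", "chrom", "pos",
                                               "ref", "alt", "lowgp"])
    gts = pd.DataFrame(gt_rows, columns=["variant_id", "sample_id", "gt", "pl"])
    return variants, gts


# ---------------------------------------------------------------------------
# PED / BED / truth


def write_ped(cohort: TrioCohort, path) -> None:
    rows = []
    sex_code = {"M": 1, "F": 2}
    sex_of = dict(zip(cohort.samples["sample_id"], cohort.samples["sex"]))
    for fam in cohort.families.itertuples(index=False):
        rows.append((fam.family, fam.patient, fam.father, fam.mother,
                     sex_code[sex_of[fam.patient]], 2))
        rows.append((fam.family, fam.mother, 0, 0, 2, 1))
        rows.append((fam.family, fam.father, 0, 0, 1, 1))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False,
                              lineterminator="\n")


def read_ped(path) -> pd.DataFrame:
    """Trio family table (family, patient, mother, father) from a PED file."""
    ped = pd.read_csv(path, sep="\t", header=None,
                      names=["family", "individual", "father", "mother", "sex", "phenotype"])
    probands = ped[(ped["father"] != "0") & (ped["mother"] != "0")]
    return probands.rename(columns={"individual": "patient"})[
        ["family", "patient", "mother", "father"]].reset_index(drop=True)


def write_bed(panel: GenePanel, path) -> None:
    panel.to_bed().to_csv(path, sep="\t", header=False, index=False,
                          lineterminator="\n")


def read_bed(path, panel_label: str = "panel") -> GenePanel:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name"])
    return GenePanel.from_bed(bed, panel_label=panel_label)


def write_truth(truth, path) -> None:
    payload = {
        "causal_weights": truth.causal_weights,
        "high_burden_parent": truth.high_burden_parent,
        "injected_panel_variants": truth.injected_panel_variants.to_dict("records"),
        "liabilities": truth.liabilities,
        "parent_genetic": truth.parent_genetic,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_dosage_tsv(cohort: TrioCohort, roles, path, config_hash: str = "",
                     seed: int = 0) -> None:
    """Samples x markers dosage table for the given roles, with role column."""
    samples = cohort.samples[cohort.samples["role"].isin(roles)]
    mat = cohort.common_gt.loc[samples["sample_id"]].reset_index(names="sample_id")
    mat.insert(1, "role", samples["role"].to_numpy())
    write_tsv(mat, path, config_hash, seed)
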