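"""Cohort-level trio genotype refinement and call bookkeeping.

Applies the per-site Bayesian refinement of :mod:`sle_trio.trio` across
every (variant, family) pair in which any trio member carries the variant,
and derives the per-variant quality flags the enrichment stage consumes:
a site is flagged when a patient's refined call falls below Q20.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import trio


def assemble_trio_genotypes(gt_long: pd.DataFrame, families: pd.DataFrame) -> pd.DataFrame:
    """Wide (variant, family) trio genotype table from long-format genotypes.

    Samples outside trio families are ignored; absent genotype records are
    homozygous reference (the generator and VCF reader emit carriers only
    for rare variants).
    """
    role_of = {}
    for fam in families.itertuples(index=False):
        role_of[fam.patient] = (fam.family, "child")
        role_of[fam.mother] = (fam.family, "mother")
        role_of[fam.father] = (fam.family, "father")
    gt = gt_long[gt_long["sample_id"].isin(role_of)].copy()
    if gt.empty:
        return pd.DataFrame(columns=["variant_id", "family", "child", "mother", "father"])
    fam_role = gt["sample_id"].map(role_of)
    gt["family"] = [fr[0] for fr in fam_role]
    gt["role"] = [fr[1] for fr in fam_role]
    wide = gt.pivot_table(index=["variant_id", "family"], columns="role",
                          values="gt", aggfunc="first", fill_value=0)
    wide = wide.reindex(columns=["child", "mother", "father"], fill_value=0)
    return wide.reset_index().astype({"child": int, "mother": int, "father": int})


def _pl_from_genotype(gt: int, pl_gap: float) -> tuple[float, float, float]:
    return tuple(0.0 if g == gt else pl_gap for g in trio.GENOTYPES)


def refine_trio_calls(
    trios: pd.DataFrame,
    pl_gap: float = 40.0,
    leak: float = trio.DEFAULT_DENOVO_LEAK,
    af_by_variant: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Refine every (variant, family) child call and annotate trio status.

    Child likelihoods are reconstructed from the emitted genotype with a
    phred gap of ``pl_gap`` (the generator's emission model).  Adds the
    refined genotype, its phred-scaled posterior quality (``gpp``), the
    low-quality flag, the Mendelian status of the emitted trio and the
    parent-of-origin call of the emitted child genotype.
    """
    af_by_variant = af_by_variant or {}
    out = trios.copy()
    refined, gpp, low, mendel, origin = [], [], [], [], []
    for row in trios.itertuples(index=False):
        pl = _pl_from_genotype(int(row.child), pl_gap)
        call = trio.refine_genotype(
            pl, int(row.mother), int(row.father), leak=leak,
            population_af=af_by_variant.get(row.variant_id))
        refined.append(call.genotype)
        gpp.append(call.posterior_phred)
        low.append(call.low_quality)
        mendel.append(trio.mendelian_status(int(row.child), int(row.mother),
                                            int(row.father)).value)
        origin.append(trio.parent_of_origin(int(row.child), int(row.mother),
                                            int(row.father)).value)
    out["refined_gt"] = refined
    out["gpp"] = np.round(gpp, 4)
    out["low_quality"] = low
    out["mendelian"] = mendel
    out["parent_of_origin"] = origin
    return out


def flagged_variants(calls: pd.DataFrame) -> set[str]:
    """Variant ids with any low-quality refined child call."""
    return set(calls.loc[calls["low_quality"], "variant_id"])


def carrier_parent_map(gt_long: pd.DataFrame, families: pd.DataFrame,
                       variant_ids) -> dict[str, tuple[str, str]]:
    """For each private variant, the carrier family and carrier parent.

    Returns ``{variant_id: (family, parent_sample_id)}`` for variants with
    exactly one carrier parent in the carrier family; variants carried by
    both parents (or none) are omitted.
    """
    wide = assemble_trio_genotypes(
        gt_long[gt_long["variant_id"].isin(set(variant_ids))], families)
    parents = families.set_index("family")
    out = {}
    for row in wide.itertuples(index=False):
        m, f = int(row.mother) > 0, int(row.father) > 0
        if m == f:
            continue
        fam = parents.loc[row.family]
        out[row.variant_id] = (row.family, fam.mother if m else fam.father)
    return out
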