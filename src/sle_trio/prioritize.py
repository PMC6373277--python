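"""Candidate-variant prioritization from refined, annotated panel variants.

Filters panel variants to a candidate report by functional class, rarity
in the reference population, and deleteriousness predictions:

* in-panel non-silent coding variants only (class filter precedes scores);
* reference MAF at or below the rarity threshold (default 0.1%);
* damaging call from the predictor triple — SIFT "damaging" below 0.05,
  PolyPhen2 "damaging" at or above 0.85, or DANN at or above 0.96;
  nonsense variants are always score-damaging;
* variants failing all predictors are retained only when a human-supplied
  evidence note exists (structural or literature evidence is a judgment,
  never auto-assigned) and are excluded from the headline count otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .panel import GenePanel

log = logging.getLogger(__name__)

SCORE_DAMAGING = "score_damaging"
OTHER_EVIDENCE = "other_evidence"
NOT_DAMAGING = "not_damaging"


@dataclass(frozen=True)
class Thresholds:
    """Predictor cutoffs behind the damaging call; all three configurable."""

    sift_damaging: float = 0.05      # strict less-than ("D")
    polyphen_damaging: float = 0.85  # at or above ("D")
    dann_damaging: float = 0.96
    max_ref_maf: float = 0.001


def damaging_call(vclass: str, dann, sift, polyphen,
                  thresholds: Thresholds = Thresholds(),
                  evidence_note: str | None = None) -> str:
    """Classify one variant's deleteriousness evidence.

    A missing predictor score counts as non-damaging for that predictor.
    """
    if vclass == "nonsense":
        return SCORE_DAMAGING
    hits = []
    if not pd.isna(sift):
        hits.append(sift < thresholds.sift_damaging)
    if not pd.isna(polyphen):
        hits.append(polyphen >= thresholds.polyphen_damaging)
    if not pd.isna(dann):
        hits.append(dann >= thresholds.dann_damaging)
    if len(hits) < 3:
        log.info("variant with missing predictor score treated as non-damaging there")
    if any(hits):
        return SCORE_DAMAGING
    return OTHER_EVIDENCE if evidence_note else NOT_DAMAGING


def filter_candidates(
    annotations: pd.DataFrame,
    case_gt: pd.DataFrame,
    patient_ids,
    panel: GenePanel,
    thresholds: Thresholds = Thresholds(),
    flagged=(),
    evidence_notes: dict[str, str] | None = None,
    scores: pd.DataFrame | None = None,
    parent_of_origin: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Candidate-variant table: one row per (variant, carrier patient).

    ``annotations`` is the per-variant annotation table; ``case_gt`` the
    long genotype table; ``scores`` optionally a RiskScoreTable to attach
    the carrier's risk score; ``parent_of_origin`` optionally maps
    variant_id to an origin call.  The private-variant contract (one
    carrier family per candidate) is checked and violations logged, not
    fatal.
    """
    evidence_notes = evidence_notes or {}
    ann = annotations.set_index("variant_id")
    located = {
        vid: panel.locate(row.chrom, row.pos)
        for vid, row in ann.iterrows()
    }
    patient_ids = set(patient_ids)
    carriers = case_gt[(case_gt["sample_id"].isin(patient_ids)) & (case_gt["gt"] > 0)]
    score_by_id = (scores.set_index("sample_id")["score"] if scores is not None else None)

    rows = []
    for rec in carriers.itertuples(index=False):
        vid = rec.variant_id
        if vid not in ann.index or vid in set(flagged):
            continue
        a = ann.loc[vid]
        hit = located.get(vid)
        if hit is None or hit[1] != "coding":
            continue
        if a["class"] not in ("missense", "nonsense"):
            continue
        if a["ref_maf"] > thresholds.max_ref_maf:
            continue
        note = evidence_notes.get(vid)
        call = damaging_call(a["class"], a["dann"], a["sift"], a["polyphen"],
                             thresholds, evidence_note=note)
        rows.append({
            "variant_id": vid,
            "gene": hit[0],
            "vclass": a["class"],
            "carrier": rec.sample_id,
            "zygosity": "hom" if rec.gt == 2 else "het",
            "ref_maf": a["ref_maf"],
            "dann": a["dann"], "sift": a["sift"], "polyphen": a["polyphen"],
            "damaging_call": call,
            "evidence_note": note or "",
            "carrier_risk_score": (float(score_by_id.get(rec.sample_id, np.nan))
                                   if score_by_id is not None else np.nan),
            "parent_of_origin": (parent_of_origin or {}).get(vid, ""),
        })
    out = pd.DataFrame(rows, columns=[
        "variant_id", "gene", "vclass", "carrier", "zygosity", "ref_maf",
        "dann", "sift", "polyphen", "damaging_call", "evidence_note",
        "carrier_risk_score", "parent_of_origin"])
    shared = out.groupby("variant_id")["carrier"].nunique()
    for vid in shared[shared > 1].index:
        log.warning("variant %s violates the private-variant contract "
                    "(multiple carrier patients)", vid)
    return out


def headline(candidates: pd.DataFrame) -> pd.DataFrame:
    """Candidates contributing to the headline count (damaging or vouched)."""
    return candidates[candidates["damaging_call"] != NOT_DAMAGING]


class ZygositySummary(NamedTuple):
    n_het: int
    n_hom: int
    n_patients: int
    n_variants: int


def zygosity_summary(candidates: pd.DataFrame) -> ZygositySummary:
    """Counts of het/hom candidate observations, distinct carriers and variants."""
    if candidates.empty:
        return ZygositySummary(0, 0, 0, 0)
    return ZygositySummary(
        n_het=int((candidates["zygosity"] == "het").sum()),
        n_hom=int((candidates["zygosity"] == "hom").sum()),
        n_patients=int(candidates["carrier"].nunique()),
        n_variants=int(candidates["variant_id"].nunique()),
    )


def rounded_patients_per_carrier(n_patients: int, n_carriers: int) -> int:
    """'One out of N patients' carries a candidate: round(n_patients / n_carriers)."""
    if n_carriers <= 0:
        raise ValueError("need at least one carrier")
    return round(n_patients / n_carriers)
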