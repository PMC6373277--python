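"""Gene-panel rare-variant enrichment, stratified by MAF and annotation.

The statistic: count variant observations (variant x carrier occurrences)
inside a gene panel in the patient cohort and in a reference cohort, per
stratum of functional class (non-silent coding, promoter) and reference
minor-allele-frequency bin.  Because the two cohorts were called by
different pipelines, the reference panel expectation is first rescaled by
a normalization factor estimated from the genome-wide (non-panel) counts
of the same stratum — a calling-sensitivity correction that matters most
for private variants.  The enrichment odds ratio is the per-genome rate
ratio of the patient panel count to the normalized reference expectation;
the p value is a two-sided Fisher exact test on the genome-count 2x2
table, and significance is Bonferroni-corrected across all tested strata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenePanel
from .stats import fisher_exact_two_sided, odds_ratio_haldane

log = logging.getLogger(__name__)

#: default reference-MAF bin edges; binning is (lo, hi] with MAF 0 (absent
#: from the reference) assigned to the lowest, ultra-rare bin
DEFAULT_BIN_EDGES = (0.0, 0.001, 0.01, 0.05, 0.5)

NON_SILENT_CLASSES = ("missense", "nonsense")
STRATUM_CLASSES = ("non_silent_coding", "promoter")


def classify_maf_bin(ref_maf: float, bin_edges=DEFAULT_BIN_EDGES) -> int:
    """Index of the half-open MAF bin ``(lo, hi]`` containing ``ref_maf``.

    MAF 0 — a variant absent from the reference cohort — falls in the
    lowest (ultra-rare) bin.  Frequencies above the last edge are an
    error rather than being folded silently.
    """
    if ref_maf < 0:
        raise ValueError("MAF must be non-negative")
    if ref_maf > bin_edges[-1]:
        raise ValueError(f"MAF {ref_maf} exceeds the last bin edge {bin_edges[-1]}")
    if ref_maf == 0:
        return 0
    for i in range(len(bin_edges) - 1):
        if bin_edges[i] < ref_maf <= bin_edges[i + 1]:
            return i
    raise AssertionError("unreachable")


@dataclass
class StratumCounts:
    """2x2-table ingredients for one (class x MAF bin) stratum."""

    annotation_class: str
    maf_bin: tuple[float, float]
    case_panel: int
    case_background: int
    ref_panel: int
    ref_background: int
    n_case_genomes: int
    n_ref_genomes: int

    def __post_init__(self) -> None:
        for name in ("case_panel", "case_background", "ref_panel", "ref_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class EnrichmentResult:
    stratum: StratumCounts
    normalization_factor: float | None
    odds_ratio: float          # normalized per-genome rate ratio; inf on zero reference
    odds_ratio_haldane: float  # 2x2 cross-product OR with 0.5 correction (display)
    p_value: float
    signed_log_p: float
    untestable: bool = False
    corrected_alpha: float | None = None
    significant: bool | None = None

    @property
    def label(self) -> str:
        lo, hi = self.stratum.maf_bin
        return f"{self.stratum.annotation_class}:({lo},{hi}]"


def _observations(gt: pd.Series, mode: str) -> pd.Series:
    """Observation weight per carrier genotype row.

    ``carrier`` counts each carrier once regardless of zygosity (the
    convention matching 'variants identified in patients' tallies);
    ``allele`` counts homozygotes twice.
    """
    if mode == "carrier":
        return (gt > 0).astype(int)
    if mode == "allele":
        return gt.astype(int)
    raise ValueError(f"unknown count mode {mode!r}")


def count_strata(
    annotations: pd.DataFrame,
    case_gt: pd.DataFrame,
    case_sample_ids,
    ref_counts: pd.DataFrame,
    panel: GenePanel,
    n_ref_genomes: int,
    bin_edges=DEFAULT_BIN_EDGES,
    flagged=(),
    count_mode: str = "carrier",
) -> list[StratumCounts]:
    """Stratified observation counts for the case and reference cohorts.

    ``annotations`` carries one row per variant (class, ref_maf);
    ``case_gt`` is long-format genotypes; ``ref_counts`` per-variant allele
    counts.  Panel membership is decided by interval lookup; variants at
    sites in ``flagged`` (low-quality refined genotypes) are excluded.
    LOW-frequency bins are half-open ``(lo, hi]`` with MAF 0 in the lowest.
    """
    ann = annotations.copy()
    missing_class = ann["class"].isna()
    if missing_class.any():
        log.warning("%d variants lack a class annotation; excluded from all strata",
                    int(missing_class.sum()))
        ann = ann[~missing_class]
    ann = ann[~ann["variant_id"].isin(set(flagged))]

    located = [panel.locate(c, p) for c, p in zip(ann["chrom"], ann["pos"])]
    region = pd.Series([h[1] if h else "" for h in located], index=ann.index)
    ann["maf_bin"] = [classify_maf_bin(m, bin_edges) for m in ann["ref_maf"]]
    ann["group"] = np.select(
        [ann["class"].isin(NON_SILENT_CLASSES), ann["class"] == "promoter"],
        ["non_silent_coding", "promoter"], default="",
    )
    # a panel observation must lie in the matching interval type
    ann["in_panel"] = np.where(
        ann["group"] == "non_silent_coding", region == "coding",
        np.where(ann["group"] == "promoter", region == "promoter", False),
    )

    case_ids = set(case_sample_ids)
    case = case_gt[case_gt["sample_id"].isin(case_ids)].merge(
        ann[["variant_id", "group", "maf_bin", "in_panel"]], on="variant_id")
    case["obs"] = _observations(case["gt"], count_mode)

    ref = ref_counts.merge(ann[["variant_id", "group", "maf_bin", "in_panel"]],
                           on="variant_id")
    # for rare variants the allele count approximates the carrier count
    ref["obs"] = ref["ac"].astype(int)

    out = []
    for group in STRATUM_CLASSES:
        for b in range(len(bin_edges) - 1):
            def total(df, in_panel):
                sel = (df["group"] == group) & (df["maf_bin"] == b) & (df["in_panel"] == in_panel)
                return int(df.loc[sel, "obs"].sum())
            out.append(StratumCounts(
                annotation_class=group,
                maf_bin=(bin_edges[b], bin_edges[b + 1]),
                case_panel=total(case, True),
                case_background=total(case, False),
                ref_panel=total(ref, True),
                ref_background=total(ref, False),
                n_case_genomes=len(case_ids),
                n_ref_genomes=n_ref_genomes,
            ))
    return out


def normalization_factor(stratum: StratumCounts) -> float | None:
    """Cross-cohort calling-sensitivity correction for one stratum.

    The ratio of the per-genome genome-wide (non-panel) variant rate in the
    case cohort to that in the reference cohort, within the stratum's class
    and frequency bin.  The reference panel expectation is multiplied by
    this factor before testing.  Returns None (untestable) when the
    reference background is empty.
    """
    if stratum.ref_background == 0:
        return None
    case_rate = stratum.case_background / stratum.n_case_genomes
    ref_rate = stratum.ref_background / stratum.n_ref_genomes
    return case_rate / ref_rate


def enrichment_test(stratum: StratumCounts, factor: float | None = None) -> EnrichmentResult:
    """Normalized enrichment odds ratio and two-sided Fisher exact p.

    The odds ratio is the per-genome rate ratio
    ``(case_panel / n_case) / (factor * ref_panel / n_ref)`` — the scale on
    which the expected count under no enrichment is ``observed / OR``.  The
    p value comes from the 2x2 table of panel observations versus genome
    counts, with the reference cell rescaled (and rounded, since the exact
    test needs integers).
    """
    if factor is None:
        factor = normalization_factor(stratum)
    if factor is None or (stratum.case_panel == 0 and stratum.ref_panel == 0):
        return EnrichmentResult(
            stratum=stratum, normalization_factor=factor, odds_ratio=math.nan,
            odds_ratio_haldane=math.nan, p_value=1.0, signed_log_p=0.0, untestable=True)

    case_rate = stratum.case_panel / stratum.n_case_genomes
    ref_expected = factor * stratum.ref_panel
    ref_rate = ref_expected / stratum.n_ref_genomes
    odds_ratio = math.inf if ref_rate == 0 else case_rate / ref_rate

    a = stratum.case_panel
    b = max(stratum.n_case_genomes - a, 0)
    c = int(round(ref_expected))
    d = max(stratum.n_ref_genomes - c, 0)
    p = fisher_exact_two_sided(a, b, c, d)
    if odds_ratio == 1.0:
        slp = 0.0
    else:
        slp = -math.log10(p) * (1.0 if odds_ratio > 1.0 else -1.0)
    return EnrichmentResult(
        stratum=stratum, normalization_factor=factor, odds_ratio=odds_ratio,
        odds_ratio_haldane=odds_ratio_haldane(a, b, c, d), p_value=p, signed_log_p=slp)


def correct_multiple_testing(results: list[EnrichmentResult],
                             alpha: float = 0.05) -> list[EnrichmentResult]:
    """Bonferroni across all tested strata; untestable strata do not count."""
    if not results:
        raise ValueError("no results to correct")
    m = sum(not r.untestable for r in results)
    corrected = alpha / m if m else alpha
    for r in results:
        r.corrected_alpha = corrected
        r.significant = (not r.untestable) and r.p_value <= corrected
    return results


def excess_variants(observed: int, odds_ratio: float) -> tuple[float, float]:
    """Observed-minus-expected variant count implied by the odds ratio.

    ``expected = observed / OR`` is the count expected by chance, so the
    excess is ``observed * (1 - 1/OR)``.  Returns ``(excess, expected)``.
    """
    if observed < 0:
        raise ValueError("observed must be non-negative")
    if not odds_ratio > 0:
        raise ValueError("odds ratio must be positive")
    expected = observed / odds_ratio
    return observed - expected, expected


def rounded_cohort_fraction(n_patients: int, excess: float) -> int:
    """'One in N patients' implied by an excess count: round(n / excess)."""
    if excess <= 0:
        raise ValueError("excess must be positive")
    return round(n_patients / excess)


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        s = r.stratum
        rows.append({
            "class": s.annotation_class, "maf_lo": s.maf_bin[0], "maf_hi": s.maf_bin[1],
            "case_panel": s.case_panel, "case_background": s.case_background,
            "ref_panel": s.ref_panel, "ref_background": s.ref_background,
            "n_case_genomes": s.n_case_genomes, "n_ref_genomes": s.n_ref_genomes,
            "normalization_factor": r.normalization_factor,
            "odds_ratio": r.odds_ratio, "p_value": r.p_value,
            "signed_log_p": r.signed_log_p, "untestable": r.untestable,
            "corrected_alpha": r.corrected_alpha, "significant": r.significant,
        })
    return pd.DataFrame(rows)
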