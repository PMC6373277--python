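"""MAF binning, stratified counting, normalization and the exact test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from sle_trio import enrichment
from sle_trio.enrichment import (StratumCounts, classify_maf_bin,
                                 correct_multiple_testing, enrichment_test,
                                 excess_variants, normalization_factor,
                                 rounded_cohort_fraction)
from sle_trio.panel import default_panel
from sle_trio.stats import fisher_exact_two_sided, odds_ratio_haldane
from tests.oracles import fisher_two_sided_oracle


class TestMafBinning:
    @pytest.mark.parametrize("maf,expected", [
        (0.0, 0),        # absent from the reference: ultra-rare by convention
        (0.0005, 0),
        (0.001, 0),      # inclusive upper edge
        (0.0011, 1),
        (0.01, 1),
        (0.03, 2),
        (0.05, 2),
        (0.5, 3),
    ])
    def test_half_open_bins(self, maf, expected):
        assert classify_maf_bin(maf) == expected

    def test_maf_above_half_is_an_error_not_folded(self):
        with pytest.raises(ValueError):
            classify_maf_bin(0.51)
        with pytest.raises(ValueError):
            classify_maf_bin(-0.1)

    @given(st.floats(0, 0.5))
    def test_bin_contains_its_maf(self, maf):
        edges = enrichment.DEFAULT_BIN_EDGES
        b = classify_maf_bin(maf)
        lo, hi = edges[b], edges[b + 1]
        assert (lo < maf <= hi) or (maf == 0 and b == 0)


def _mini_inputs():
    """Handcrafted two-gene scenario for counting semantics."""
    panel = default_panel()
    g = panel.genes[0]
    coding_pos = g.coding[0][0] + 5
    promoter_pos = g.promoter[0] + 5
    ann = pd.DataFrame({
        "variant_id": ["v1", "v2", "v3", "v4", "v5", "v6"],
        "chrom": [g.chrom] * 4 + ["chrS9"] * 2,
        "pos": [coding_pos, coding_pos + 1, coding_pos + 2, promoter_pos, 10, 20],
        "ref": "A", "alt": "G",
        "class": ["missense", "silent", "nonsense", "promoter", "missense", "promoter"],
        "ref_maf": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        "dann": 0.5, "sift": 0.5, "polyphen": 0.5,
    })
    case_gt = pd.DataFrame({
        "variant_id": ["v1", "v2", "v3", "v4", "v5", "v1"],
        "sample_id": ["P1", "P1", "P1", "P2", "P2", "X1"],
        "gt": [1, 1, 2, 1, 1, 1],
    })
    ref = pd.DataFrame({
        "variant_id": ["v6"], "chrom": ["chrS9"], "pos": [20],
        "ref": "A", "alt": "G", "ac": [3], "an": [200],
    })
    return ann, case_gt, ref, panel


class TestCountStrata:
    def test_counting_semantics(self):
        ann, case_gt, ref, panel = _mini_inputs()
        strata = enrichment.count_strata(
            ann, case_gt, ["P1", "P2"], ref, panel, n_ref_genomes=100)
        by = {(s.annotation_class, s.maf_bin[0]): s for s in strata}
        ultra = by[("non_silent_coding", 0.0)]
        # P1 carries v1 (het) and v3 (hom, counted once); silent v2 excluded;
        # X1 is not a patient; v5 is background missense
        assert ultra.case_panel == 2
        assert ultra.case_background == 1
        prom = by[("promoter", 0.0)]
        assert prom.case_panel == 1         # v4 in a promoter interval
        assert prom.case_background == 0
        assert prom.ref_background == 3     # v6 allele count
        assert ultra.n_case_genomes == 2 and ultra.n_ref_genomes == 100

    def test_allele_mode_counts_homozygotes_twice(self):
        ann, case_gt, ref, panel = _mini_inputs()
        strata = enrichment.count_strata(
            ann, case_gt, ["P1", "P2"], ref, panel, n_ref_genomes=100,
            count_mode="allele")
        ultra = next(s for s in strata
                     if s.annotation_class == "non_silent_coding"
                     and s.maf_bin[0] == 0.0)
        assert ultra.case_panel == 3        # het + hom(2)

    def test_flagged_sites_excluded(self):
        ann, case_gt, ref, panel = _mini_inputs()
        strata = enrichment.count_strata(
            ann, case_gt, ["P1", "P2"], ref, panel, n_ref_genomes=100,
            flagged={"v1"})
        ultra = next(s for s in strata
                     if s.annotation_class == "non_silent_coding"
                     and s.maf_bin[0] == 0.0)
        assert ultra.case_panel == 1

    def test_empty_cohort_all_zero(self):
        ann, case_gt, ref, panel = _mini_inputs()
        strata = enrichment.count_strata(
            ann, case_gt.iloc[:0], [], ref.iloc[:0], panel, n_ref_genomes=100)
        assert all(s.case_panel == 0 and s.case_background == 0 for s in strata)

    def test_missing_class_counted_nowhere(self, caplog):
        ann, case_gt, ref, panel = _mini_inputs()
        ann.loc[0, "class"] = np.nan
        with caplog.at_level("WARNING"):
            strata = enrichment.count_strata(
                ann, case_gt, ["P1", "P2"], ref, panel, n_ref_genomes=100)
        ultra = next(s for s in strata
                     if s.annotation_class == "non_silent_coding"
                     and s.maf_bin[0] == 0.0)
        assert ultra.case_panel == 1        # v1 dropped
        assert "lack a class annotation" in caplog.text


class TestNormalization:
    def _stratum(self, **kw):
        base = dict(annotation_class="non_silent_coding", maf_bin=(0.0, 0.001),
                    case_panel=5, case_background=100, ref_panel=50,
                    ref_background=1000, n_case_genomes=100, n_ref_genomes=1000)
        base.update(kw)
        return StratumCounts(**base)

    def test_identical_rates_give_unity(self):
        assert normalization_factor(self._stratum()) == pytest.approx(1.0)

    def test_invariant_to_duplicating_reference(self):
        s1 = self._stratum()
        s2 = self._stratum(ref_panel=100, ref_background=2000, n_ref_genomes=2000)
        assert normalization_factor(s1) == pytest.approx(normalization_factor(s2))

    def test_empty_reference_background_untestable(self):
        s = self._stratum(ref_background=0)
        assert normalization_factor(s) is None
        assert enrichment_test(s).untestable

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            self._stratum(case_panel=-1)


class TestFisher:
    def test_balanced_table_is_null(self):
        assert fisher_exact_two_sided(10, 990, 10, 990) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [
        (5, 95, 5, 995), (0, 7, 27, 37), (3, 0, 0, 3), (1, 1, 1, 1),
        (12, 8, 3, 17), (0, 0, 5, 5), (21, 50, 14, 986),
    ])
    def test_matches_enumeration_oracle(self, table):
        assert fisher_exact_two_sided(*table) == pytest.approx(
            fisher_two_sided_oracle(*table), abs=1e-12)

    def test_matches_oracle_on_random_tables_margins_le_80(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            r1, r2 = rng.integers(0, 81, 2)
            n = r1 + r2
            if n == 0:
                continue
            c1 = int(rng.integers(max(0, n - 80), min(80, n) + 1))
            a = int(rng.integers(max(0, c1 - r2), min(r1, c1) + 1))
            table = (a, r1 - a, c1 - a, r2 - (c1 - a))
            assert fisher_exact_two_sided(*table) == pytest.approx(
                fisher_two_sided_oracle(*table), abs=1e-12)

    def test_agrees_with_scipy_convention(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 40, 4)
            ours = fisher_exact_two_sided(int(a), int(b), int(c), int(d))
            theirs = scipy_fisher([[a, b], [c, d]])[1]
            assert ours == pytest.approx(theirs, rel=1e-7, abs=1e-12)

    def test_haldane_correction_only_with_zero_cells(self):
        assert odds_ratio_haldane(2, 3, 4, 5) == pytest.approx(10 / 12)
        assert odds_ratio_haldane(0, 3, 4, 5) == pytest.approx(
            (0.5 * 5.5) / (3.5 * 4.5))


class TestEnrichmentTest:
    def _stratum(self, case_panel, ref_panel, n_case=100, n_ref=1000,
                 case_bg=100, ref_bg=1000):
        return StratumCounts("non_silent_coding", (0.0, 0.001), case_panel,
                             case_bg, ref_panel, ref_bg, n_case, n_ref)

    def test_equal_rates_or_one_p_one(self):
        r = enrichment_test(self._stratum(10, 100), factor=1.0)
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)
        assert r.signed_log_p == 0.0

    def test_p_equals_oracle_for_known_table(self):
        # genome-margin table (5, 95, 5, 995)
        r = enrichment_test(self._stratum(5, 5, n_case=100, n_ref=1000), factor=1.0)
        assert r.p_value == pytest.approx(
            fisher_two_sided_oracle(5, 95, 5, 995), abs=1e-12)

    def test_normalization_scales_reference_expectation(self):
        r = enrichment_test(self._stratum(20, 80), factor=1.25)
        assert r.odds_ratio == pytest.approx((20 / 100) / (1.25 * 80 / 1000))

    @given(st.integers(0, 50), st.integers(0, 50))
    def test_or_monotone_in_case_panel(self, a1, a2):
        lo, hi = sorted((a1, a2))
        s_lo = self._stratum(lo, 30)
        s_hi = self._stratum(hi, 30)
        assert (enrichment_test(s_hi, 1.0).odds_ratio
                >= enrichment_test(s_lo, 1.0).odds_ratio)

    def test_depletion_symmetry(self):
        s = self._stratum(30, 10, n_case=1000, n_ref=1000)
        swapped = self._stratum(10, 30, n_case=1000, n_ref=1000)
        r, rs = enrichment_test(s, 1.0), enrichment_test(swapped, 1.0)
        assert rs.odds_ratio == pytest.approx(1 / r.odds_ratio)
        assert rs.p_value == pytest.approx(r.p_value, abs=1e-12)
        assert rs.signed_log_p == pytest.approx(-r.signed_log_p, abs=1e-9)

    def test_zero_reference_panel_infinite_or(self):
        r = enrichment_test(self._stratum(5, 0), factor=1.0)
        assert np.isinf(r.odds_ratio)
        assert np.isfinite(r.odds_ratio_haldane)


class TestMultipleTesting:
    def _results(self, pvals):
        out = []
        for p in pvals:
            s = StratumCounts("non_silent_coding", (0.0, 0.001), 1, 1, 1, 1, 10, 10)
            r = enrichment_test(s, 1.0)
            r.p_value = p
            out.append(r)
        return out

    def test_single_test_alpha_unchanged(self):
        r = correct_multiple_testing(self._results([0.03]))
        assert r[0].corrected_alpha == pytest.approx(0.05)
        assert r[0].significant

    def test_bonferroni_arithmetic(self):
        rs = correct_multiple_testing(self._results([0.5] * 8))
        assert rs[0].corrected_alpha == pytest.approx(0.00625)

    def test_printed_headline_p_survives_up_to_27_strata(self):
        rs = correct_multiple_testing(self._results([0.00182] + [0.5] * 26))
        assert rs[0].corrected_alpha == pytest.approx(0.05 / 27)
        assert rs[0].significant

    def test_untestable_strata_do_not_consume_alpha(self):
        rs = self._results([0.01, 0.5])
        rs[1].untestable = True
        correct_multiple_testing(rs)
        assert rs[0].corrected_alpha == pytest.approx(0.05)


class TestExcess:
    def test_printed_worked_example(self):
        excess, expected = excess_variants(21, 2.07)
        assert round(excess, 1) == 10.9
        assert expected == pytest.approx(21 / 2.07)

    @pytest.mark.parametrize("observed,odds_ratio,expected", [
        (10, 1.0, 0.0), (0, 3.0, 0.0),
    ])
    def test_degenerate_cases(self, observed, odds_ratio, expected):
        assert excess_variants(observed, odds_ratio)[0] == pytest.approx(expected)

    def test_invalid_or_rejected(self):
        with pytest.raises(ValueError):
            excess_variants(10, 0.0)

    def test_cohort_fraction(self):
        assert rounded_cohort_fraction(71, 10.9) == 7
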