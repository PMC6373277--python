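#!/usr/bin/env python
"""MAF- and annotation-stratified gene-panel enrichment versus reference.

Counts variant observations in the 22-gene monogenic-SLE panel per
(class x MAF bin) stratum for patients and the reference cohort, applies
the cross-cohort normalization factor, and reports Fisher odds ratios
with Bonferroni-corrected significance plus the excess-variant estimate
for the ultra-rare coding stratum.
"""

from common import driver_args
from sle_trio.enrichment import excess_variants, rounded_cohort_fraction
from sle_trio.io import read_tsv
from sle_trio.pipeline import ARTIFACTS, stage_enrich


def main():
    args = driver_args(__doc__)
    stage_enrich(args.config, args.out_dir)
    table = read_tsv(f"{args.out_dir}/{ARTIFACTS['enrichment']}")
    cols = ["class", "maf_hi", "case_panel", "odds_ratio", "p_value", "significant"]
    print(table[cols].to_string(index=False))
    ultra = table[(table["class"] == "non_silent_coding") & (table["maf_lo"] == 0.0)].iloc[0]
    if not ultra["untestable"]:
        excess, expected = excess_variants(int(ultra["case_panel"]), ultra["odds_ratio"])
        n = int(ultra["n_case_genomes"])
        print(f"ultra-rare coding: observed {int(ultra['case_panel'])}, "
              f"expected {expected:.1f}, excess {excess:.1f} "
              f"(~1 in {rounded_cohort_fraction(n, excess)} patients)")


if __name__ == "__main__":
    main()
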