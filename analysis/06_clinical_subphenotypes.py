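#!/usr/bin/env python
"""ACR sub-phenotype comparison and the aggregated study report.

Compares the 11 binary ACR criteria between heterozygous candidate
carriers and non-carriers (Fisher exact, Bonferroni over 11 criteria),
then aggregates all stage outputs into summary.json and the figure set.
"""

from common import driver_args
from sle_trio.io import read_tsv
from sle_trio.pipeline import ARTIFACTS, stage_clinical, stage_report


def main():
    args = driver_args(__doc__)
    stage_clinical(args.config, args.out_dir)
    acr = read_tsv(f"{args.out_dir}/{ARTIFACTS['acr']}")
    if len(acr):
        cols = ["criterion", "carrier_freq", "comparator_freq", "p_value", "p_corrected"]
        print(acr[cols].to_string(index=False))
    else:
        print("no carrier/non-carrier split in this cohort")
    stage_report(args.config, args.out_dir)
    print(f"summary + figures written under {args.out_dir}")


if __name__ == "__main__":
    main()
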