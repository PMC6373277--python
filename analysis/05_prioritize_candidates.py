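#!/usr/bin/env python
"""Candidate-variant prioritization (Table 1-style report).

Filters refined in-panel non-silent ultra-rare variants by the
deleteriousness predictors (SIFT < 0.05, PolyPhen2 >= 0.85, DANN >= 0.96;
nonsense always damaging) and summarizes zygosity and carrier counts.
"""

import json

from common import driver_args
from sle_trio.io import read_tsv
from sle_trio.pipeline import ARTIFACTS, stage_prioritize
from sle_trio.prioritize import headline


def main():
    args = driver_args(__doc__)
    stage_prioritize(args.config, args.out_dir)
    cands = read_tsv(f"{args.out_dir}/{ARTIFACTS['candidates']}")
    summary = json.load(open(f"{args.out_dir}/{ARTIFACTS['prioritization']}"))
    head = headline(cands)
    cols = ["variant_id", "gene", "vclass", "zygosity", "dann", "sift",
            "polyphen", "carrier_risk_score", "parent_of_origin"]
    print(head[cols].to_string(index=False))
    print(f"{summary['n_headline']} damaging candidates in "
          f"{summary['n_patients']} patients "
          f"({summary['n_het']} het / {summary['n_hom']} hom); "
          f"~1 carrier per {summary['rounded_patients_per_carrier']} patients")


if __name__ == "__main__":
    main()
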