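#!/usr/bin/env python
"""Trio-aware genotype refinement and quality flagging.

Re-reads the cohort VCF, refines every child call with the Mendelian
transmission prior, writes per-trio calls (posterior phred, low-quality
flag, Mendelian status, parent of origin) and a refined VCF carrying GPP
and the LOWGP site filter.
"""

import pandas as pd
from common import driver_args
from sle_trio.io import read_tsv
from sle_trio.pipeline import ARTIFACTS, stage_refine


def main():
    args = driver_args(__doc__)
    stage_refine(args.config, args.out_dir)
    calls = read_tsv(f"{args.out_dir}/{ARTIFACTS['trio_calls']}")
    print(f"{len(calls)} trio calls refined; "
          f"{int(calls['low_quality'].sum())} flagged below Q20; "
          f"Mendelian-consistent fraction "
          f"{(calls['mendelian'] == 'consistent').mean():.4f}")
    print(calls["parent_of_origin"].value_counts().to_string())


if __name__ == "__main__":
    main()
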