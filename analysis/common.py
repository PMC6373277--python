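"""Shared plumbing for the numbered analysis drivers."""

import argparse
import logging
import sys

from sle_trio.config import preset


def driver_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=0, help="master seed")
    parser.add_argument("--out-dir", default="results/pipeline",
                        help="shared artifact directory")
    parser.add_argument("--preset", default="paper_like",
                        choices=["paper_like", "null", "tiny"])
    args = parser.parse_args()
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    args.config = preset(args.preset, seed=args.seed)
    return args
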