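#!/usr/bin/env python
"""Random-forest risk scores, parent partition and Fig 1-style summaries.

Trains the case/control forest on the simulated training panel, scores
every trio member and control, partitions each family's parents into
higher/lower risk, and reports the group means and patient-parent
correlations that characterize one-parent inheritance of polygenic risk.
"""

import json

from common import driver_args
from sle_trio.pipeline import ARTIFACTS, stage_score


def main():
    args = driver_args(__doc__)
    stage_score(args.config, args.out_dir)
    report = json.load(open(f"{args.out_dir}/{ARTIFACTS['correlations']}"))
    means = report["group_means"]
    print("mean risk scores (%): patients {:.1f} | higher parents {:.1f} | "
          "lower parents {:.1f} | controls {:.1f}".format(
              means["mean_patient"], means["mean_higher_parent"],
              means["mean_lower_parent"], means["mean_control"]))
    hi, lo = report["patient_vs_higher"], report["patient_vs_lower"]
    print(f"patient vs higher parent: r={hi['r']:.3f} (p={hi['p']:.2e}); "
          f"patient vs lower parent: r={lo['r']:.3f} (p={lo['p']:.2e})")


if __name__ == "__main__":
    main()
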