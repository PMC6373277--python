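"""ACR sub-phenotype comparison between candidate carriers and the cohort.

Each of the 11 binary ACR classification criteria is compared between
patients carrying a prioritized rare variant and the rest of the cohort
with a two-sided Fisher exact test, Bonferroni-corrected for the 11
criteria.  The default comparison is carriers versus non-carriers
(disjoint groups — the exact test assumes independent samples); a
carriers-versus-all mode is available for descriptive frequencies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .stats import fisher_exact_two_sided


def acr_comparison(
    table: pd.DataFrame,
    carrier_col: str = "carrier",
    comparison_mode: str = "noncarriers",
) -> pd.DataFrame:
    """Per-criterion carrier-vs-comparator frequencies and Fisher p values.

    ``table`` has one row per patient: binary criterion columns plus a
    boolean carrier flag.  Criteria with no variance in the whole cohort
    are reported with p = 1 and flagged.  Corrected p values are
    Bonferroni over the criteria tested.
    """
    if comparison_mode not in ("noncarriers", "all"):
        raise ValueError(f"unknown comparison_mode {comparison_mode!r}")
    carrier = table[carrier_col].astype(bool)
    if carrier.all() or not carrier.any():
        raise ValueError("need at least one carrier and one non-carrier")
    criteria = [c for c in table.columns if c not in (carrier_col, "sample_id")]

    rows = []
    for crit in criteria:
        vals = table[crit].astype(int)
        car = vals[carrier]
        comp = vals if comparison_mode == "all" else vals[~carrier]
        zero_variance = vals.nunique() == 1
        if zero_variance:
            p = 1.0
        else:
            a = int(car.sum())
            b = int(len(car) - a)
            c = int(comp.sum())
            d = int(len(comp) - c)
            p = fisher_exact_two_sided(a, b, c, d)
        rows.append({
            "criterion": crit,
            "carrier_freq": float(car.mean()),
            "comparator_freq": float(comp.mean()),
            "n_carriers": int(len(car)),
            "n_comparators": int(len(comp)),
            "p_value": p,
            "zero_variance": zero_variance,
        })
    out = pd.DataFrame(rows)
    out["p_corrected"] = multipletests(out["p_value"], method="bonferroni")[1]
    return out
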