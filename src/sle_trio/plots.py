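"""Figure helpers: score distributions, enrichment profile, carrier scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def score_distributions(scores: pd.DataFrame, partition: pd.DataFrame, path) -> None:
    """Risk-score density comparison: patients, higher/lower parents, controls."""
    groups = {
        "patients": scores.loc[scores["role"] == "patient", "score"],
        "higher parents": scores.set_index("sample_id")["score"].reindex(partition["higher"]),
        "lower parents": scores.set_index("sample_id")["score"].reindex(partition["lower"]),
        "controls": scores.loc[scores["role"] == "control", "score"],
    }
    fig, ax = plt.subplots(figsize=(7, 4))
    bins = np.linspace(0, 100, 30)
    for label, vals in groups.items():
        vals = vals.dropna()
        if len(vals):
            ax.hist(vals, bins=bins, density=True, histtype="step", label=label)
    ax.set_xlabel("risk score (% trees voting case)")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def enrichment_profile(table: pd.DataFrame, path) -> None:
    """Signed log10 p per MAF bin and class, with the corrected threshold."""
    fig, ax = plt.subplots(figsize=(7, 4))
    tested = table[~table["untestable"]]
    for cls, sub in tested.groupby("class"):
        sub = sub.sort_values("maf_hi")
        labels = [f"≤{hi:g}" for hi in sub["maf_hi"]]
        ax.plot(labels, sub["signed_log_p"], marker="o", label=cls)
    if len(tested):
        thresh = -np.log10(tested["corrected_alpha"].iloc[0])
        ax.axhline(thresh, color="red", lw=1,
                   label="corrected 0.05 threshold")
        ax.axhline(-thresh, color="red", lw=1)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("reference MAF bin (upper edge)")
    ax.set_ylabel("signed -log10 p (negative = depletion)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def carrier_scatter(scores: pd.DataFrame, families: pd.DataFrame,
                    carrier_by_family: dict[str, str], path) -> None:
    """Patient score vs carrier-parent and non-carrier-parent scores."""
    by_id = scores.set_index("sample_id")["score"]
    pat, car, non = [], [], []
    for fam in families.itertuples(index=False):
        carrier = carrier_by_family.get(fam.family)
        if carrier not in (fam.mother, fam.father):
            continue
        other = fam.father if carrier == fam.mother else fam.mother
        pat.append(by_id[fam.patient]); car.append(by_id[carrier]); non.append(by_id[other])
    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharey=True)
    for ax, ys, title in ((axes[0], non, "parent lacking the variant"),
                          (axes[1], car, "parent carrying the variant")):
        ax.scatter(pat, ys, s=18)
        ax.set_xlabel("patient risk score")
        ax.set_title(title, fontsize=9)
    axes[0].set_ylabel("parent risk score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
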