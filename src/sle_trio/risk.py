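"""Random-forest genotype risk score and per-family parent partitioning.

A random forest is trained on case/control common-marker dosages; the risk
score of a sample is the percentage of trees voting "case".  Scores are
comparable within a run only — the analyses downstream use relative
structure (parent partitions, correlations), never absolute risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

log = logging.getLogger(__name__)

DEFAULT_N_TREES = 500
DEFAULT_MIN_OVERLAP = 0.9


@dataclass
class RiskModel:
    """A trained forest plus the marker list and imputation means it expects."""

    forest: RandomForestClassifier
    markers: list[str]
    train_mean_dosage: np.ndarray
    seed: int

    def save(self, path) -> None:
        joblib.dump({"version": 1, "model": self}, path)

    @classmethod
    def load(cls, path) -> "RiskModel":
        payload = joblib.load(path)
        return payload["model"]


def train_model(
    genotypes: pd.DataFrame,
    labels,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    **forest_kwargs,
) -> RiskModel:
    """Train the case/control forest on a samples x markers dosage matrix.

    ``labels`` are 1 for cases, 0 for controls; training is deterministic
    given ``seed``.  Degenerate single-class labels are an error.
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class; cannot train")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1, **forest_kwargs)
    x = genotypes.to_numpy(dtype=float)
    forest.fit(x, y)
    return RiskModel(
        forest=forest,
        markers=list(genotypes.columns),
        train_mean_dosage=np.nanmean(x, axis=0),
        seed=seed,
    )


def score_samples(
    model: RiskModel,
    genotypes: pd.DataFrame,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> pd.Series:
    """Risk score (percent of trees voting case) for each sample.

    Markers absent from ``genotypes`` (and NaN dosages) are imputed to the
    training-set mean dosage; the fraction of the model's markers present
    must reach ``min_overlap``.  A sample with no observed marker at all is
    an error.
    """
    if genotypes.shape[0] == 0:
        return pd.Series(dtype=float, name="score")
    present = [m for m in model.markers if m in genotypes.columns]
    overlap = len(present) / len(model.markers)
    if overlap < min_overlap:
        raise ValueError(
            f"marker overlap {overlap:.1%} below the scoring threshold {min_overlap:.0%}")
    if overlap < 1.0:
        log.info("scoring with %.1f%% marker overlap; %d markers imputed",
                 100 * overlap, len(model.markers) - len(present))
    x = genotypes.reindex(columns=model.markers).to_numpy(dtype=float)
    all_missing = np.all(np.isnan(x), axis=1)
    if all_missing.any():
        bad = list(genotypes.index[all_missing])
        raise ValueError(f"samples with no observed markers cannot be scored: {bad}")
    nan_r, nan_c = np.nonzero(np.isnan(x))
    x[nan_r, nan_c] = model.train_mean_dosage[nan_c]
    votes = np.zeros(x.shape[0])
    for tree in model.forest.estimators_:
        votes += (tree.predict(x) == 1)
    return pd.Series(100.0 * votes / len(model.forest.estimators_),
                     index=genotypes.index, name="score")


def score_table(model: RiskModel, cohort, min_overlap: float = DEFAULT_MIN_OVERLAP) -> pd.DataFrame:
    """RiskScoreTable: score every cohort sample, annotated with role and family."""
    scores = score_samples(model, cohort.common_gt, min_overlap=min_overlap)
    out = cohort.samples.copy()
    out["score"] = scores.loc[out["sample_id"]].to_numpy()
    return out[["sample_id", "family", "role", "score"]]


def partition_parents(scores: pd.DataFrame, families: pd.DataFrame) -> pd.DataFrame:
    """Label each family's parents higher/lower by risk score.

    Exact ties break deterministically to the lexicographically smaller
    sample id and are flagged.  Families with an unscored parent are
    excluded with a warning.
    """
    by_id = scores.set_index("sample_id")["score"]
    rows = []
    for fam in families.itertuples(index=False):
        sm = by_id.get(fam.mother, np.nan)
        sf = by_id.get(fam.father, np.nan)
        if np.isnan(sm) or np.isnan(sf):
            log.warning("family %s excluded from partition: missing parent score", fam.family)
            continue
        tie = sm == sf
        if sm > sf or (tie and fam.mother < fam.father):
            higher, lower = fam.mother, fam.father
        else:
            higher, lower = fam.father, fam.mother
        rows.append((fam.family, higher, lower, tie))
    return pd.DataFrame(rows, columns=["family", "higher", "lower", "tie"])


def pearson_with_p(x, y) -> dict:
    """Pearson r, R^2, two-sided t-distribution p and n for one pair of vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": np.nan, "r2": np.nan, "p": np.nan, "n": n, "defined": False}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "r2": float(r * r), "p": float(p), "n": n, "defined": True}


def correlation_report(
    scores: pd.DataFrame,
    families: pd.DataFrame,
    partition: pd.DataFrame,
) -> dict:
    """Patient-vs-parent score correlations and cohort group means.

    Reports the patient/higher-parent and patient/lower-parent Pearson
    correlations plus the mean scores of patients, higher parents, lower
    parents and controls — the distribution summary of the one-parent
    inheritance analysis.
    """
    by_id = scores.set_index("sample_id")["score"]
    merged = partition.merge(families, on="family")
    patient = by_id.loc[merged["patient"]].to_numpy()
    higher = by_id.loc[merged["higher"]].to_numpy()
    lower = by_id.loc[merged["lower"]].to_numpy()
    means = {
        f"mean_{role}": float(scores.loc[scores["role"] == role, "score"].mean())
        for role in ("patient", "control", "case_training")
        if (scores["role"] == role).any()
    }
    means["mean_higher_parent"] = float(higher.mean())
    means["mean_lower_parent"] = float(lower.mean())
    means["mean_parent"] = float(np.concatenate([higher, lower]).mean())
    return {
        "patient_vs_higher": pearson_with_p(patient, higher),
        "patient_vs_lower": pearson_with_p(patient, lower),
        "group_means": means,
        "n_families": len(merged),
    }


def carrier_correlation_report(
    scores: pd.DataFrame,
    families: pd.DataFrame,
    carrier_parent: dict[str, str],
) -> dict:
    """Correlations split by which parent carries the rare candidate variant.

    ``carrier_parent`` maps family id to the carrier parent's sample id;
    families whose candidate is not attributable to a single parent are
    skipped.  Reports patient-vs-carrier-parent and
    patient-vs-noncarrier-parent correlations (the mode-of-inheritance
    comparison for candidate-variant families).
    """
    by_id = scores.set_index("sample_id")["score"]
    pat, car, non = [], [], []
    for fam in families.itertuples(index=False):
        carrier = carrier_parent.get(fam.family)
        if carrier not in (fam.mother, fam.father):
            continue
        other = fam.father if carrier == fam.mother else fam.mother
        pat.append(by_id[fam.patient])
        car.append(by_id[carrier])
        non.append(by_id[other])
    if len(pat) < 3:
        return {"n_families": len(pat), "patient_vs_carrier": None,
                "patient_vs_noncarrier": None}
    return {
        "n_families": len(pat),
        "patient_vs_carrier": pearson_with_p(pat, car),
        "patient_vs_noncarrier": pearson_with_p(pat, non),
    }
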