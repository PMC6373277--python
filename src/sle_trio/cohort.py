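"""Synthetic trio-cohort generator.

Generates parent-offspring trio cohorts with the statistical structure the
downstream analyses assume:

* an additive Gaussian liability-threshold disease model over a panel of
  common markers (an ImmunoChip-scale marker set, scaled down), with
  affected offspring obtained by rejection sampling;
* per-family concentration of the polygenic burden in one designated
  parent, implemented by conditioning that parent's genetic liability on
  an upper quantile of the population distribution;
* ultra-rare private variants in a monogenic-SLE gene panel injected into
  patients at ``background x enrichment_factor`` and transmitted from the
  non-designated parent (the "second hit" structure);
* a shared pool of low-frequency variants segregating in both the trio
  cohort and a reference cohort, so frequency-stratified counts are
  comparable across cohorts by construction;
* a reference cohort emitted as per-variant allele counts, optionally with
  a calling-efficiency deflation of private-variant counts so the
  cross-cohort normalization has a real signal to correct;
* binary ACR sub-phenotypes for the patients.

Every stochastic operation draws from a generator derived from the master
seed and a stable operation key (plus the family index for per-family
operations), so cohorts are reproducible family-by-family and the
reference cohort can be regenerated independently of the trios.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .panel import GenePanel, default_panel

REF_ALLELE, ALT_ALLELE = "A", "G"
BACKGROUND_CONTIG = "chrS9"     # cohort-private background variants
POOL_CONTIG = "chrS8"           # shared low-frequency pool (non-panel part)
COMMON_CONTIG = "chrS0"         # common-marker block

#: functional-class mix of background (non-panel) rare variants
BACKGROUND_CLASSES = ("missense", "nonsense", "silent", "promoter", "other")
BACKGROUND_CLASS_P = np.array([0.45, 0.05, 0.20, 0.15, 0.15])
PANEL_POOL_CLASSES = ("missense", "nonsense", "silent", "promoter")
PANEL_POOL_CLASS_P = np.array([0.40, 0.05, 0.20, 0.35])

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "gene", "vclass",
                   "ref_maf", "dann", "sift", "polyphen", "deleterious", "origin"]


class RejectionSamplingError(RuntimeError):
    """Raised when rejection sampling cannot satisfy its acceptance condition."""


def derive_rng(master_seed: int, *keys) -> np.random.Generator:
    """Child generator derived from the master seed and stable string/int keys."""
    digest = hashlib.sha256(("/".join(map(str, keys))).encode()).digest()
    entropy = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([master_seed, entropy]))


@dataclass
class SyntheticTruth:
    """Generator ground truth, kept for parameter-recovery tests."""

    causal_weights: dict[str, float]
    high_burden_parent: dict[str, str]          # family -> mother | father | none
    injected_panel_variants: pd.DataFrame       # family, variant_id, transmitting_parent, zygosity, deleterious
    liabilities: dict[str, float]
    parent_genetic: dict[str, float] = field(default_factory=dict)


@dataclass
class TrioCohort:
    """In-memory synthetic cohort; file emission lives in :mod:`sle_trio.io`."""

    config: SimulationConfig
    panel: GenePanel
    samples: pd.DataFrame          # sample_id, family, role, sex
    families: pd.DataFrame         # family, patient, mother, father, designated
    common_markers: pd.DataFrame   # variant_id, chrom, pos, ref, alt, maf, causal_weight
    common_gt: pd.DataFrame        # emitted dosages, samples x markers
    common_gt_true: pd.DataFrame   # pre-error dosages
    rare_variants: pd.DataFrame    # per-variant annotation incl. truth columns
    rare_gt: pd.DataFrame          # long: variant_id, sample_id, gt
    reference_counts: pd.DataFrame  # variant_id, chrom, pos, ref, alt, ac, an
    phenotypes: pd.DataFrame       # sample_id + 11 binary ACR criteria
    truth: SyntheticTruth

    @property
    def patients(self) -> list[str]:
        return list(self.families["patient"])

    def samples_by_role(self, role: str) -> list[str]:
        return list(self.samples.loc[self.samples["role"] == role, "sample_id"])

    def genotype_matrix(self, sample_ids) -> pd.DataFrame:
        return self.common_gt.loc[list(sample_ids)]

    def annotations(self) -> pd.DataFrame:
        return emit_annotations(self.all_variants(), self.panel)

    def all_variants(self) -> pd.DataFrame:
        common = self.common_markers.assign(
            vclass="other", ref_maf=self.common_markers["maf"], dann=np.nan,
            sift=np.nan, polyphen=np.nan,
        )[["variant_id", "chrom", "pos", "ref", "alt", "vclass", "ref_maf",
           "dann", "sift", "polyphen"]]
        rare = self.rare_variants[["variant_id", "chrom", "pos", "ref", "alt",
                                   "vclass", "ref_maf", "dann", "sift", "polyphen"]]
        return pd.concat([common, rare], ignore_index=True)


# ---------------------------------------------------------------------------
# low-level sampling helpers


def _sample_population(rng: np.random.Generator, mafs: np.ndarray, n: int) -> np.ndarray:
    return rng.binomial(2, mafs, size=(n, mafs.size)).astype(np.int8)


def _transmit(rng: np.random.Generator, parent_gt: np.ndarray) -> np.ndarray:
    """One gamete per site from each parental genotype row."""
    return (rng.random(parent_gt.shape) < parent_gt / 2.0).astype(np.int8)


class _VariantFactory:
    """Allocates variant ids and positions from per-stream generators.

    Each consumer stream (``pool``, ``case``, ``ref``) draws positions from
    its own derived generator, so the reference stream can be replayed
    without simulating the trio cohort.  Panel positions are unique within
    a stream; duplicate coordinates across streams are legal (distinct
    variant ids) and harmless downstream.
    """

    def __init__(self, panel: GenePanel, seed: int):
        self.panel = panel
        self.seed = seed
        self._rngs: dict[str, np.random.Generator] = {}
        self._used: dict[str, set] = {}
        self._counter: dict[str, int] = {}
        self._bg_base = {"case": 1_000_000, "ref": 50_000_000, "pool": 100_000_000}

    def _rng(self, stream: str) -> np.random.Generator:
        if stream not in self._rngs:
            self._rngs[stream] = derive_rng(self.seed, "positions", stream)
            self._used[stream] = set()
        return self._rngs[stream]

    def next_ids(self, prefix: str, n: int) -> list[str]:
        start = self._counter.get(prefix, 0)
        self._counter[prefix] = start + n
        return [f"{prefix}{k:06d}" for k in range(start + 1, start + n + 1)]

    def panel_position(self, stream: str, gene_idx: int, region: str) -> tuple[str, int]:
        rng = self._rng(stream)
        gene = self.panel.genes[gene_idx % len(self.panel.genes)]
        for _ in range(1000):
            if region == "promoter":
                start, end = gene.promoter
            else:
                start, end = gene.coding[int(rng.integers(len(gene.coding)))]
            pos = int(rng.integers(start, end)) + 1   # 1-based
            key = (gene.chrom, pos)
            if key not in self._used[stream]:
                self._used[stream].add(key)
                return gene.chrom, pos
        raise RuntimeError("panel intervals exhausted; enlarge the synthetic gene bodies")

    def background_positions(self, stream: str, n: int) -> np.ndarray:
        rng = self._rng(stream)
        steps = rng.integers(3, 20, size=n)
        pos = self._bg_base[stream] + np.cumsum(steps)
        self._bg_base[stream] = int(pos[-1]) if n else self._bg_base[stream]
        return pos


def _benign_scores(rng: np.random.Generator, n: int) -> tuple[np.ndarray, ...]:
    """Sub-threshold deleteriousness score triple for n variants."""
    return (rng.uniform(0.1, 0.9, n), rng.uniform(0.06, 1.0, n), rng.uniform(0.0, 0.8, n))


def _damaging_scores(rng: np.random.Generator, n: int) -> tuple[np.ndarray, ...]:
    """Damaging-range triple: all three predictors pass their conventional cuts."""
    return (rng.uniform(0.96, 1.0, n), rng.uniform(0.0, 0.045, n), rng.uniform(0.85, 1.0, n))


# ---------------------------------------------------------------------------
# family simulation (liability-threshold polygenic model)


def _population_moments(mafs, weights) -> tuple[float, float]:
    """Mean and SD of the population genetic-liability score."""
    mean = float(np.sum(weights * 2 * mafs))
    sd = float(np.sqrt(np.sum(weights ** 2 * 2 * mafs * (1 - mafs))))
    return mean, sd


def _tilted_frequencies(mafs, weights, sigma_g, eta) -> np.ndarray:
    """Causal-allele frequencies tilted along the effect direction.

    A parent drawn at these frequencies has expected genetic liability
    shifted by about ``eta`` population genetic SDs — the elevated-burden
    distribution of the designated parent.  Frequencies are clipped away
    from 0 and 1, so the realized shift saturates for extreme ``eta``.
    """
    tilt = eta * mafs * (1 - mafs) * weights / max(sigma_g, 1e-12)
    return np.clip(mafs + tilt, 0.02, 0.98)


def _simulate_families(cfg: SimulationConfig, mafs, weights):
    """Rejection-sample each trio family until the offspring is affected.

    The designated parent's genotypes are drawn from the elevated-burden
    (tilted-frequency) distribution at the family's latent burden level
    ``eta ~ N(parent_burden_shift, parent_burden_spread^2)``; the other
    parent is a population draw.  Each candidate family (both parents and
    the child) is resampled as a unit, so accepted families are draws from
    the joint distribution conditioned on an affected child — the
    ascertainment of the emulated study design.  Liability is centered at
    the population mean genetic score.
    """
    mu_pop, sigma_g = _population_moments(mafs, weights)
    per_family = []
    batch = 16
    for i in range(cfg.n_families):
        rng = derive_rng(cfg.seed, "family", i)
        designated = rng.random() < cfg.one_parent_fraction
        des_role = "mother" if rng.random() < 0.5 else "father"
        # the designated parent's burden level is elevated, never protective
        eta = max(rng.normal(cfg.parent_burden_shift, cfg.parent_burden_spread), 0.0)
        des_freqs = _tilted_frequencies(mafs, weights, sigma_g, eta)
        tries = 0
        while True:
            tries += batch
            if tries > cfg.max_rejection_tries:
                raise RejectionSamplingError(
                    f"family {i}: no affected offspring after {cfg.max_rejection_tries} "
                    "candidate families; liability_threshold is unreachable under "
                    "the configured genetic architecture"
                )
            if designated:
                des = rng.binomial(2, des_freqs, size=(batch, mafs.size)).astype(np.int8)
            else:
                des = _sample_population(rng, mafs, batch)
            other = _sample_population(rng, mafs, batch)
            child = _transmit(rng, des) + _transmit(rng, other)
            genetic = child @ weights - mu_pop
            env = rng.normal(0.0, cfg.environmental_sd, batch)
            hits = np.nonzero(genetic + env > cfg.liability_threshold)[0]
            if hits.size:
                j = int(hits[0])
                break
        mother_gt, father_gt = (des[j], other[j]) if des_role == "mother" else (other[j], des[j])
        per_family.append({
            "index": i,
            "designated": des_role if designated else "none",
            "mother_gt": mother_gt,
            "father_gt": father_gt,
            "child_gt": child[j],
            "child_env": float(env[j]),
            "child_genetic": float(genetic[j]),
            "patient_sex": "F" if rng.random() < cfg.female_patient_fraction else "M",
        })
    return per_family


def _rejection_sample_cases(cfg: SimulationConfig, rng, mafs, weights, n):
    out, liab, tries = [], [], 0
    while len(out) < n:
        tries += 1
        if tries > 200:
            raise RejectionSamplingError(
                "could not sample affected training cases; liability_threshold "
                "is unreachable under the configured genetic architecture"
            )
        mu_pop, _ = _population_moments(mafs, weights)
        cand = _sample_population(rng, mafs, max(4 * n, 256))
        ll = cand @ weights - mu_pop + rng.normal(0.0, cfg.environmental_sd, cand.shape[0])
        keep = ll > cfg.liability_threshold
        out.extend(cand[keep])
        liab.extend(ll[keep])
    return np.array(out[:n], dtype=np.int8), np.array(liab[:n])


# ---------------------------------------------------------------------------
# rare-variant architecture


def _build_pool(cfg: SimulationConfig, panel: GenePanel, factory: _VariantFactory):
    """Shared low-frequency variant pool segregating in every cohort."""
    rng = derive_rng(cfg.seed, "pool")
    lo, hi = cfg.pool_maf_range
    freqs = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_pool_rare))
    in_panel = rng.random(cfg.n_pool_rare) < cfg.panel_pool_fraction
    n = cfg.n_pool_rare
    vclass = np.array(BACKGROUND_CLASSES)[
        rng.choice(len(BACKGROUND_CLASSES), n, p=BACKGROUND_CLASS_P)]
    vclass[in_panel] = np.array(PANEL_POOL_CLASSES)[
        rng.choice(len(PANEL_POOL_CLASSES), int(in_panel.sum()), p=PANEL_POOL_CLASS_P)]
    chrom = np.full(n, POOL_CONTIG, dtype=object)
    pos = np.zeros(n, dtype=np.int64)
    gene = np.full(n, "", dtype=object)
    pos[~in_panel] = factory.background_positions("pool", int((~in_panel).sum()))
    for k in np.nonzero(in_panel)[0]:
        gene_idx = int(rng.integers(len(panel.genes)))
        region = "promoter" if vclass[k] == "promoter" else "coding"
        chrom[k], pos[k] = factory.panel_position("pool", gene_idx, region)
        gene[k] = panel.genes[gene_idx].name
    dann, sift, polyphen = _benign_scores(rng, n)
    nonsense = vclass == "nonsense"
    dann[nonsense] = sift[nonsense] = polyphen[nonsense] = np.nan
    pool = pd.DataFrame({
        "variant_id": factory.next_ids("pv", n), "chrom": chrom, "pos": pos,
        "ref": REF_ALLELE, "alt": ALT_ALLELE, "gene": gene, "vclass": vclass,
        "pop_maf": freqs, "dann": dann, "sift": sift, "polyphen": polyphen,
        "deleterious": False, "origin": "pool",
    })
    return pool, freqs


def _inject_private(cfg: SimulationConfig, panel: GenePanel, factory: _VariantFactory,
                    families):
    """Per-family private rare variants: enriched panel injections plus the
    genome-wide background every genome carries.

    Every private variant of a patient is transmitted from one parent (the
    non-designated parent for enriched panel injections) so trios remain
    Mendelian-consistent.
    """
    var_rows, gt_rows, truth_rows = [], [], []

    for fam in families:
        i = fam["index"]
        fam_id = f"F{i:03d}"
        patient, mother, father = f"{fam_id}_P", f"{fam_id}_M", f"{fam_id}_F"
        rng = derive_rng(cfg.seed, "rare", i)
        if fam["designated"] == "mother":
            nondesignated = father
        elif fam["designated"] == "father":
            nondesignated = mother
        else:
            nondesignated = None

        # enriched non-silent coding panel variants ("second hits")
        n_inj = rng.poisson(cfg.panel_rare_rate_background * cfg.panel_enrichment_factor)
        for vid in factory.next_ids("rv", n_inj):
            gene_idx = int(rng.integers(len(panel.genes)))
            vclass = "nonsense" if rng.random() < cfg.panel_nonsense_fraction else "missense"
            deleterious = bool(rng.random() < cfg.panel_deleterious_fraction)
            chrom, pos = factory.panel_position("case", gene_idx, "coding")
            if vclass == "nonsense":
                scores = (np.nan, np.nan, np.nan)
            elif deleterious:
                scores = tuple(x[0] for x in _damaging_scores(rng, 1))
            else:
                scores = tuple(x[0] for x in _benign_scores(rng, 1))
            var_rows.append((vid, chrom, pos, REF_ALLELE, ALT_ALLELE,
                             panel.genes[gene_idx].name, vclass, 0.0, *scores,
                             deleterious, "panel_injected"))
            parent = nondesignated or (mother if rng.random() < 0.5 else father)
            gt_rows += [(vid, patient, 1), (vid, parent, 1)]
            truth_rows.append((fam_id, vid, parent, "het", deleterious))

        # non-enriched panel classes: silent coding and promoter
        for rate, region, vclass, origin in (
            (cfg.panel_silent_rate, "coding", "silent", "panel_silent"),
            (cfg.promoter_rare_rate, "promoter", "promoter", "panel_promoter"),
        ):
            for vid in factory.next_ids("rv", rng.poisson(rate)):
                gene_idx = int(rng.integers(len(panel.genes)))
                chrom, pos = factory.panel_position("case", gene_idx, region)
                scores = tuple(x[0] for x in _benign_scores(rng, 1))
                var_rows.append((vid, chrom, pos, REF_ALLELE, ALT_ALLELE,
                                 panel.genes[gene_idx].name, vclass, 0.0, *scores,
                                 False, origin))
                parent = mother if rng.random() < 0.5 else father
                gt_rows += [(vid, patient, 1), (vid, parent, 1)]

        # genome-wide private background (vectorized; these dominate counts)
        n_bg = rng.poisson(cfg.genomewide_rare_rate)
        if n_bg:
            ids = factory.next_ids("rv", n_bg)
            classes = np.array(BACKGROUND_CLASSES)[
                rng.choice(len(BACKGROUND_CLASSES), n_bg, p=BACKGROUND_CLASS_P)]
            pos = factory.background_positions("case", n_bg)
            dann, sift, polyphen = _benign_scores(rng, n_bg)
            nonsense = classes == "nonsense"
            dann[nonsense] = sift[nonsense] = polyphen[nonsense] = np.nan
            parents = np.where(rng.random(n_bg) < 0.5, mother, father)
            for k in range(n_bg):
                var_rows.append((ids[k], BACKGROUND_CONTIG, int(pos[k]), REF_ALLELE,
                                 ALT_ALLELE, "", classes[k], 0.0, dann[k], sift[k],
                                 polyphen[k], False, "background"))
                gt_rows += [(ids[k], patient, 1), (ids[k], parents[k], 1)]

    # optional single homozygous nonsense injection (complement-null analogue)
    if cfg.inject_homozygous_nonsense and families:
        rng = derive_rng(cfg.seed, "homnonsense")
        i = families[int(rng.integers(len(families)))]["index"]
        fam_id = f"F{i:03d}"
        gene_idx = next(k for k, g in enumerate(panel.genes) if g.name == "C1QC")
        chrom, pos = factory.panel_position("case", gene_idx, "coding")
        vid = factory.next_ids("rv", 1)[0]
        var_rows.append((vid, chrom, pos, REF_ALLELE, ALT_ALLELE, "C1QC", "nonsense",
                         0.0, np.nan, np.nan, np.nan, True, "panel_injected_hom"))
        gt_rows += [(vid, f"{fam_id}_P", 2), (vid, f"{fam_id}_M", 1), (vid, f"{fam_id}_F", 1)]
        truth_rows.append((fam_id, vid, "both", "hom", True))

    variants = pd.DataFrame(var_rows, columns=VARIANT_COLUMNS)
    gts = pd.DataFrame(gt_rows, columns=["variant_id", "sample_id", "gt"])
    truth = pd.DataFrame(truth_rows, columns=[
        "family", "variant_id", "transmitting_parent", "zygosity", "deleterious"])
    return variants, gts, truth


def _reference_private(cfg: SimulationConfig, panel: GenePanel, factory: _VariantFactory):
    """Reference-cohort private (singleton) variants with optional deflation.

    Each true singleton is emitted with probability
    ``reference_singleton_call_rate``, emulating the lower sensitivity of a
    cohort-calling pipeline without pedigree support for private variants.
    """
    rng = derive_rng(cfg.seed, "reference")
    frames = []
    specs = (
        ("panel_coding", cfg.panel_rare_rate_background, None),
        ("panel_silent", cfg.panel_silent_rate, "silent"),
        ("panel_promoter", cfg.promoter_rare_rate, "promoter"),
        ("background", cfg.genomewide_rare_rate, None),
    )
    for kind, rate, forced_class in specs:
        n_true = rng.poisson(rate * cfg.n_reference)
        n = rng.binomial(n_true, cfg.reference_singleton_call_rate)
        if n == 0:
            continue
        if kind == "background":
            classes = np.array(BACKGROUND_CLASSES)[
                rng.choice(len(BACKGROUND_CLASSES), n, p=BACKGROUND_CLASS_P)]
            chrom = np.full(n, BACKGROUND_CONTIG, dtype=object)
            pos = factory.background_positions("ref", n)
            gene = np.full(n, "", dtype=object)
        else:
            if kind == "panel_coding":
                classes = np.where(rng.random(n) < cfg.panel_nonsense_fraction,
                                   "nonsense", "missense").astype(object)
                region = "coding"
            else:
                classes = np.full(n, forced_class, dtype=object)
                region = "promoter" if forced_class == "promoter" else "coding"
            chrom = np.empty(n, dtype=object)
            pos = np.zeros(n, dtype=np.int64)
            gene = np.empty(n, dtype=object)
            gene_idx = rng.integers(len(panel.genes), size=n)
            for k in range(n):
                chrom[k], pos[k] = factory.panel_position("ref", int(gene_idx[k]), region)
                gene[k] = panel.genes[int(gene_idx[k])].name
        dann, sift, polyphen = _benign_scores(rng, n)
        nonsense = classes == "nonsense"
        dann[nonsense] = sift[nonsense] = polyphen[nonsense] = np.nan
        frames.append(pd.DataFrame({
            "variant_id": factory.next_ids("rf", n), "chrom": chrom, "pos": pos,
            "ref": REF_ALLELE, "alt": ALT_ALLELE, "gene": gene, "vclass": classes,
            "dann": dann, "sift": sift, "polyphen": polyphen,
        }))
    if not frames:
        return pd.DataFrame(columns=["variant_id", "chrom", "pos", "ref", "alt",
                                     "gene", "vclass", "dann", "sift", "polyphen"])
    return pd.concat(frames, ignore_index=True)


def _pool_genotypes(cfg, pool_freqs, families):
    """Genotype the shared pool in parents and transmit to the children."""
    rng = derive_rng(cfg.seed, "pool_gt")
    n_fam = len(families)
    mothers = rng.binomial(2, pool_freqs, size=(n_fam, pool_freqs.size)).astype(np.int8)
    fathers = rng.binomial(2, pool_freqs, size=(n_fam, pool_freqs.size)).astype(np.int8)
    children = _transmit(rng, mothers) + _transmit(rng, fathers)
    return mothers, fathers, children


def _acr_phenotypes(cfg: SimulationConfig, families, carriers: set[str]):
    """Binary ACR criteria per patient; patients fulfil >= min_acr_criteria.

    Carriers of heterozygous deleterious panel variants use the carrier
    renal rate (default 0), emulating the nephritis depletion of the
    candidate-carrier subgroup.
    """
    criteria = list(cfg.acr_rates)
    rows = []
    for fam in families:
        patient = f"F{fam['index']:03d}_P"
        rng = derive_rng(cfg.seed, "acr", fam["index"])
        rates = dict(cfg.acr_rates)
        if patient in carriers:
            rates["renal"] = cfg.carrier_renal_rate
        for _ in range(1000):
            draw = {c: int(rng.random() < rates[c]) for c in criteria}
            if sum(draw.values()) >= cfg.min_acr_criteria:
                break
        else:
            raise RejectionSamplingError("could not satisfy min_acr_criteria; check acr_rates")
        rows.append({"sample_id": patient, **draw})
    return pd.DataFrame(rows, columns=["sample_id", *criteria])


def _apply_genotype_errors(cfg: SimulationConfig, gt: pd.DataFrame) -> pd.DataFrame:
    if cfg.genotype_error_rate == 0:
        return gt.copy()
    rng = derive_rng(cfg.seed, "errors")
    arr = gt.to_numpy().copy()
    mask = rng.random(arr.shape) < cfg.genotype_error_rate
    shift = rng.integers(1, 3, size=arr.shape)
    arr[mask] = (arr[mask] + shift[mask]) % 3
    return pd.DataFrame(arr, index=gt.index, columns=gt.columns)


# ---------------------------------------------------------------------------
# public operations


def simulate_cohort(config: SimulationConfig, panel: GenePanel | None = None) -> TrioCohort:
    """Generate a full synthetic trio cohort plus its ground-truth ledger."""
    cfg = config
    panel = panel or default_panel()
    rng_mk = derive_rng(cfg.seed, "markers")

    # common-marker architecture
    mafs = rng_mk.uniform(*cfg.common_maf_range, cfg.n_common_markers)
    causal_idx = rng_mk.choice(cfg.n_common_markers, cfg.n_causal_markers, replace=False)
    weights = np.zeros(cfg.n_common_markers)
    weights[causal_idx] = rng_mk.normal(0.0, cfg.effect_size_sd, cfg.n_causal_markers)
    marker_ids = [f"cm{i:04d}" for i in range(cfg.n_common_markers)]
    common_markers = pd.DataFrame({
        "variant_id": marker_ids,
        "chrom": COMMON_CONTIG,
        "pos": np.arange(1, cfg.n_common_markers + 1) * 10_000,
        "ref": REF_ALLELE, "alt": ALT_ALLELE,
        "maf": mafs, "causal_weight": weights,
    })

    mu_pop, _ = _population_moments(mafs, weights)
    families = _simulate_families(cfg, mafs, weights)

    # trio sample bookkeeping
    sample_rows, family_rows = [], []
    gt_blocks, gt_index = [], []
    env_rng = derive_rng(cfg.seed, "parent_env")
    liabilities, parent_genetic = {}, {}
    for fam in families:
        fam_id = f"F{fam['index']:03d}"
        patient, mother, father = f"{fam_id}_P", f"{fam_id}_M", f"{fam_id}_F"
        sample_rows += [
            (patient, fam_id, "patient", fam["patient_sex"]),
            (mother, fam_id, "mother", "F"),
            (father, fam_id, "father", "M"),
        ]
        family_rows.append((fam_id, patient, mother, father, fam["designated"]))
        gt_blocks += [fam["child_gt"], fam["mother_gt"], fam["father_gt"]]
        gt_index += [patient, mother, father]
        for sid, gt in ((mother, fam["mother_gt"]), (father, fam["father_gt"])):
            g = float(gt @ weights) - mu_pop
            parent_genetic[sid] = g
            liabilities[sid] = g + float(env_rng.normal(0.0, cfg.environmental_sd))
        liabilities[patient] = fam["child_genetic"] + fam["child_env"]

    # controls and training cases
    rng_ctl = derive_rng(cfg.seed, "controls")
    controls = _sample_population(rng_ctl, mafs, cfg.n_controls)
    ctl_liab = controls @ weights - mu_pop + \
        rng_ctl.normal(0.0, cfg.environmental_sd, cfg.n_controls)
    cases, case_liab = _rejection_sample_cases(
        cfg, derive_rng(cfg.seed, "cases"), mafs, weights, cfg.n_training_cases)
    for k in range(cfg.n_controls):
        sid = f"C{k:04d}"
        sample_rows.append((sid, "", "control", "F" if k % 2 else "M"))
        gt_blocks.append(controls[k]); gt_index.append(sid)
        liabilities[sid] = float(ctl_liab[k])
    for k in range(cfg.n_training_cases):
        sid = f"T{k:04d}"
        sample_rows.append((sid, "", "case_training", "F" if k % 2 else "M"))
        gt_blocks.append(cases[k]); gt_index.append(sid)
        liabilities[sid] = float(case_liab[k])

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "family", "role", "sex"])
    families_df = pd.DataFrame(
        family_rows, columns=["family", "patient", "mother", "father", "designated"])
    common_gt_true = pd.DataFrame(
        np.vstack(gt_blocks), index=gt_index, columns=marker_ids)
    common_gt = _apply_genotype_errors(cfg, common_gt_true)

    # rare variants: shared pool + private injections + reference privates
    factory = _VariantFactory(panel, cfg.seed)
    pool, pool_freqs = _build_pool(cfg, panel, factory)
    priv_vars, priv_gt, injected = _inject_private(cfg, panel, factory, families)
    mothers_gt, fathers_gt, children_gt = _pool_genotypes(cfg, pool_freqs, families)

    pool_ids = pool["variant_id"].to_numpy()
    pool_gt_frames = []
    for block, suffix in ((children_gt, "_P"), (mothers_gt, "_M"), (fathers_gt, "_F")):
        fam_idx, var_idx = np.nonzero(block)
        pool_gt_frames.append(pd.DataFrame({
            "variant_id": pool_ids[var_idx],
            "sample_id": [f"F{families[j]['index']:03d}{suffix}" for j in fam_idx],
            "gt": block[fam_idx, var_idx].astype(int),
        }))
    pool_gt = pd.concat(pool_gt_frames, ignore_index=True)

    # reference cohort: shared pool counts + its own private variants
    rng_ref = derive_rng(cfg.seed, "reference_pool")
    an = 2 * cfg.n_reference
    pool_ac = rng_ref.binomial(an, pool_freqs)
    ref_priv = _reference_private(cfg, panel, factory)
    reference_counts = pd.concat([
        pool.assign(ac=pool_ac, an=an)[["variant_id", "chrom", "pos", "ref", "alt", "ac", "an"]],
        ref_priv.assign(ac=1, an=an)[["variant_id", "chrom", "pos", "ref", "alt", "ac", "an"]],
    ], ignore_index=True)

    # the empirical reference MAF is the downstream frequency annotation
    pool_annot = pool.assign(ref_maf=pool_ac / an).drop(columns=["pop_maf"])
    ref_priv_annot = ref_priv.assign(ref_maf=1.0 / an, deleterious=False,
                                     origin="reference_private")
    rare_variants = pd.concat([priv_vars, pool_annot[VARIANT_COLUMNS],
                               ref_priv_annot[VARIANT_COLUMNS]], ignore_index=True)
    rare_gt = pd.concat([priv_gt, pool_gt], ignore_index=True)

    # rare-variant liability contribution for patients
    for row in injected.itertuples(index=False):
        liabilities[f"{row.family}_P"] += cfg.rare_variant_effect

    het_del_carriers = {
        f"{row.family}_P" for row in injected.itertuples(index=False)
        if row.deleterious and row.zygosity == "het"
    }
    phenotypes = _acr_phenotypes(cfg, families, het_del_carriers)

    truth = SyntheticTruth(
        causal_weights={marker_ids[i]: float(weights[i]) for i in causal_idx},
        high_burden_parent={f"F{f['index']:03d}": f["designated"] for f in families},
        injected_panel_variants=injected,
        liabilities=liabilities,
        parent_genetic=parent_genetic,
    )
    return TrioCohort(
        config=cfg, panel=panel, samples=samples, families=families_df,
        common_markers=common_markers, common_gt=common_gt,
        common_gt_true=common_gt_true, rare_variants=rare_variants,
        rare_gt=rare_gt, reference_counts=reference_counts,
        phenotypes=phenotypes, truth=truth,
    )


def simulate_reference(config: SimulationConfig, panel: GenePanel | None = None) -> pd.DataFrame:
    """Reference-cohort allele counts, reproducible independently of the trios.

    Uses the same derived seeds and per-stream position generators as
    :func:`simulate_cohort`, so the emitted table equals the cohort's
    ``reference_counts`` without simulating any trio family.
    """
    panel = panel or default_panel()
    factory = _VariantFactory(panel, config.seed)
    pool, pool_freqs = _build_pool(config, panel, factory)
    rng_ref = derive_rng(config.seed, "reference_pool")
    an = 2 * config.n_reference
    pool_ac = rng_ref.binomial(an, pool_freqs)
    ref_priv = _reference_private(config, panel, factory)
    return pd.concat([
        pool.assign(ac=pool_ac, an=an)[["variant_id", "chrom", "pos", "ref", "alt", "ac", "an"]],
        ref_priv.assign(ac=1, an=an)[["variant_id", "chrom", "pos", "ref", "alt", "ac", "an"]],
    ], ignore_index=True)


def emit_annotations(variants: pd.DataFrame, panel: GenePanel) -> pd.DataFrame:
    """Per-variant annotation table (class, reference MAF, score triple).

    Variants without a functional class are classified by panel location:
    promoter intervals yield class ``promoter``, coding intervals
    ``missense``, anything else ``other``.
    """
    out = variants.rename(columns={"vclass": "class"}).copy()
    missing = out["class"].isna() | (out["class"] == "")
    if missing.any():
        filled = []
        for row in out.loc[missing].itertuples(index=False):
            hit = panel.locate(row.chrom, row.pos)
            if hit is None:
                filled.append("other")
            else:
                filled.append("promoter" if hit[1] == "promoter" else "missense")
        out.loc[missing, "class"] = filled
    cols = ["variant_id", "chrom", "pos", "ref", "alt", "class", "ref_maf",
            "dann", "sift", "polyphen"]
    return out[cols]
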