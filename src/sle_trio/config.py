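"""Simulation configuration and scenario presets."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

#: ACR classification criteria used as binary sub-phenotypes, with the
#: population frequencies the generator emulates (typical adult SLE cohort
#: frequencies; renal matches the 38% of the emulated study cohort)
DEFAULT_ACR_RATES: dict[str, float] = {
    "malar_rash": 0.55,
    "discoid_rash": 0.15,
    "photosensitivity": 0.50,
    "oral_ulcers": 0.30,
    "arthritis": 0.80,
    "serositis": 0.35,
    "renal": 0.38,
    "neurologic": 0.08,
    "hematologic": 0.55,
    "immunologic": 0.75,
    "ana": 0.98,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic trio-cohort scenario.

    The defaults describe the paper-like scenario: 71 affected-offspring
    trio families, a 1000-genome reference cohort, and a 120-marker
    common-SNP panel standing in for an ImmunoChip-scale marker set in
    which every marker carries a small liability weight (the chip targets
    known immune-disease loci).  Disease follows an additive Gaussian
    liability-threshold model (threshold 4.0 on the centered liability
    scale, population prevalence about 1%); the polygenic burden is
    concentrated in one designated parent per family, drawn from an
    elevated-burden distribution with both higher mean and higher
    cross-family variance than the population.  Ultra-rare deleterious
    panel variants are injected into patients at twice the background
    rate and transmitted from the non-designated parent.
    """

    # cohort sizes
    n_families: int = 71
    n_controls: int = 2711
    n_training_cases: int = 1160
    n_reference: int = 1000

    # common-marker polygenic architecture
    n_common_markers: int = 120
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_markers: int = 120
    effect_size_sd: float = 0.21
    liability_threshold: float = 4.0
    environmental_sd: float = 1.0
    one_parent_fraction: float = 1.0
    parent_burden_shift: float = 3.0    # designated-parent mean shift, population genetic SDs
    parent_burden_spread: float = 2.0   # SD of the per-family burden level (same units)

    # rare-variant architecture
    panel_rare_rate_background: float = 0.15
    panel_enrichment_factor: float = 2.0
    panel_silent_rate: float = 0.05
    promoter_rare_rate: float = 0.05
    genomewide_rare_rate: float = 25.0
    rare_maf_max: float = 0.001
    n_pool_rare: int = 1500
    pool_maf_range: tuple[float, float] = (2e-4, 0.05)
    panel_pool_fraction: float = 0.01
    panel_deleterious_fraction: float = 0.4
    rare_variant_effect: float = 0.5
    panel_nonsense_fraction: float = 0.05
    inject_homozygous_nonsense: bool = True

    # reference-cohort calling model
    reference_singleton_call_rate: float = 1.0

    # genotype emission
    genotype_error_rate: float = 0.0
    pl_gap: float = 40.0
    pl_gap_error: float = 15.0

    # phenotypes
    female_patient_fraction: float = 0.85
    acr_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ACR_RATES))
    carrier_renal_rate: float = 0.0
    min_acr_criteria: int = 4

    max_rejection_tries: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_families", "n_controls", "n_training_cases", "n_reference",
                     "n_common_markers", "n_causal_markers", "n_pool_rare"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        lo, hi = self.common_maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("common_maf_range must satisfy 0 < lo < hi <= 0.5")
        if not (0 < self.rare_maf_max < lo):
            raise ValueError("rare_maf_max must lie in (0, min(common_maf_range))")
        if self.panel_enrichment_factor < 1:
            raise ValueError("panel_enrichment_factor must be >= 1")
        if not (0 <= self.one_parent_fraction <= 1):
            raise ValueError("one_parent_fraction must lie in [0, 1]")
        if not (0 <= self.genotype_error_rate < 1):
            raise ValueError("genotype_error_rate must lie in [0, 1)")
        if not (0 < self.reference_singleton_call_rate <= 1):
            raise ValueError("reference_singleton_call_rate must lie in (0, 1]")
        if self.n_causal_markers > self.n_common_markers:
            raise ValueError("n_causal_markers cannot exceed n_common_markers")
        if self.effect_size_sd < 0 or self.environmental_sd <= 0:
            raise ValueError("effect_size_sd must be >= 0 and environmental_sd > 0")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Short stable hash of the configuration, for provenance headers."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def preset(name: str, seed: int = 0) -> SimulationConfig:
    """Named scenario presets.

    ``paper_like``
        the default 71-family scenario with twofold panel enrichment.
    ``null``
        no panel enrichment and a minimal polygenic block; intended for
        calibration studies of the exact test, where the polygenic
        component is irrelevant and only slows the rejection sampler.
    ``tiny``
        a seconds-scale smoke-test scenario.
    """
    if name == "paper_like":
        return SimulationConfig(seed=seed)
    if name == "null":
        return SimulationConfig(
            seed=seed,
            panel_enrichment_factor=1.0,
            inject_homozygous_nonsense=False,
            n_common_markers=12,
            n_causal_markers=4,
            liability_threshold=0.5,
            n_controls=50,
            n_training_cases=25,
        )
    if name == "tiny":
        return SimulationConfig(
            seed=seed,
            n_families=8,
            n_controls=40,
            n_training_cases=20,
            n_reference=100,
            n_common_markers=40,
            n_causal_markers=10,
            genomewide_rare_rate=5.0,
            n_pool_rare=200,
            liability_threshold=1.5,
        )
    raise ValueError(f"unknown preset {name!r}")
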