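"""Trio genetics: Mendelian checks, parent-of-origin, and genotype refinement.

Genotypes at a biallelic site are coded as allele dosages: 0 (hom ref),
1 (het), 2 (hom alt); ``MISSING`` (-1) marks an uncalled genotype.

The refinement operation is a simplified pedigree-aware Bayesian update of
the child's genotype: the phred-scaled genotype likelihoods (PL) emitted by
the caller are combined with the Mendelian transmission prior given the
parental genotypes, allowing a small per-allele de novo leak.  The call
quality is expressed as a phred score of the maximum posterior and calls
below Q20 are flagged as low quality.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1
GENOTYPES = (HOM_REF, HET, HOM_ALT)

#: phred threshold below which a refined call is flagged
LOW_QUALITY_PHRED = 20.0
#: numerical slack so that max posterior exactly 0.99 maps to Q20, unflagged
_PHRED_TOL = 1e-6
#: default per-allele de novo mutation leak
DEFAULT_DENOVO_LEAK = 1e-8


class MendelianStatus(enum.Enum):
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"
    INDETERMINATE = "indeterminate"


class ParentOfOrigin(enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    AMBIGUOUS = "ambiguous"
    DE_NOVO = "de_novo"
    INDETERMINATE = "indeterminate"


def _transmissible(genotype: int) -> tuple[int, ...]:
    return {HOM_REF: (0,), HET: (0, 1), HOM_ALT: (1,)}[genotype]


def mendelian_status(child: int, mother: int, father: int) -> MendelianStatus:
    """Total-function Mendelian check; missing genotypes are indeterminate."""
    if MISSING in (child, mother, father):
        return MendelianStatus.INDETERMINATE
    ok = any(
        am + af == child
        for am in _transmissible(mother)
        for af in _transmissible(father)
    )
    return MendelianStatus.CONSISTENT if ok else MendelianStatus.INCONSISTENT


def mendelian_consistent(child: int, mother: int, father: int) -> bool:
    """True iff the child genotype is formable from one allele of each parent.

    Raises ``ValueError`` on a missing genotype rather than returning a
    silently-true (or false) answer; use :func:`mendelian_status` for the
    total function.
    """
    status = mendelian_status(child, mother, father)
    if status is MendelianStatus.INDETERMINATE:
        raise ValueError("Mendelian consistency is indeterminate with a missing genotype")
    return status is MendelianStatus.CONSISTENT


def parent_of_origin(child: int, mother: int, father: int) -> ParentOfOrigin:
    """Assign the transmitting parent of the child's alternate allele.

    A heterozygous child with exactly one carrier parent is assigned to that
    parent; two carrier parents are ambiguous; none is an apparent de novo.
    Homozygous-alt children received one alt allele from each parent, so the
    call is ambiguous when both parents carry, de novo otherwise.  Children
    without an alternate allele (or any missing genotype) are indeterminate.
    """
    if MISSING in (child, mother, father):
        return ParentOfOrigin.INDETERMINATE
    if child == HOM_REF:
        return ParentOfOrigin.INDETERMINATE
    m_carrier, f_carrier = mother > HOM_REF, father > HOM_REF
    if child == HOM_ALT:
        return ParentOfOrigin.AMBIGUOUS if (m_carrier and f_carrier) else ParentOfOrigin.DE_NOVO
    if m_carrier and f_carrier:
        return ParentOfOrigin.AMBIGUOUS
    if m_carrier:
        return ParentOfOrigin.MATERNAL
    if f_carrier:
        return ParentOfOrigin.PATERNAL
    return ParentOfOrigin.DE_NOVO


def _alt_transmission_prob(genotype: int, leak: float, population_af: float | None) -> float:
    """P(transmitted allele is alt) for one parent, with a de novo leak."""
    if genotype == MISSING:
        if population_af is None:
            raise ValueError("population_af required when a parental genotype is missing")
        t = population_af
    else:
        t = genotype / 2.0
    return t * (1.0 - leak) + (1.0 - t) * leak


def transmission_prior(
    mother: int,
    father: int,
    leak: float = DEFAULT_DENOVO_LEAK,
    population_af: float | None = None,
) -> np.ndarray:
    """Prior over the child genotype given parental genotypes.

    Missing parents transmit from Hardy–Weinberg at ``population_af``.
    """
    tm = _alt_transmission_prob(mother, leak, population_af)
    tf = _alt_transmission_prob(father, leak, population_af)
    return np.array(
        [(1 - tm) * (1 - tf), tm * (1 - tf) + (1 - tm) * tf, tm * tf]
    )


def hwe_prior(population_af: float) -> np.ndarray:
    q = population_af
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])


def phred_from_posterior(max_posterior: float) -> float:
    """-10 log10 of the call error probability, capped at Q99."""
    err = max(1.0 - max_posterior, 10 ** -9.9)
    return -10.0 * math.log10(err)


@dataclass
class PosteriorCall:
    """A refined genotype call with its phred-scaled posterior quality."""

    genotype: int
    posterior: np.ndarray = field(repr=False)
    posterior_phred: float = 0.0
    low_quality: bool = False
    prior_source: str = "trio"

    def __post_init__(self) -> None:
        self.posterior_phred = phred_from_posterior(float(self.posterior.max()))
        self.low_quality = self.posterior_phred < LOW_QUALITY_PHRED - _PHRED_TOL


def refine_genotype(
    child_pl: tuple[float, float, float],
    mother: int,
    father: int,
    leak: float = DEFAULT_DENOVO_LEAK,
    population_af: float | None = None,
) -> PosteriorCall:
    """Pedigree-aware posterior genotype call for the child.

    ``child_pl`` are phred-scaled genotype likelihoods (smaller = more
    likely, minimum conventionally 0).  When both parents are missing the
    prior falls back to Hardy–Weinberg at ``population_af`` and the call is
    annotated with ``prior_source="population"``.
    """
    pl = np.asarray(child_pl, dtype=float)
    if pl.shape != (3,):
        raise ValueError("child PL must be a triple")
    likelihood = 10.0 ** (-pl / 10.0)
    if mother == MISSING and father == MISSING:
        if population_af is None:
            raise ValueError("population_af required when both parents are missing")
        prior = hwe_prior(population_af)
        source = "population"
    else:
        prior = transmission_prior(mother, father, leak=leak, population_af=population_af)
        source = "trio" if MISSING not in (mother, father) else "trio+population"
    post = likelihood * prior
    total = post.sum()
    if total == 0.0:
        raise ValueError("degenerate posterior: zero-probability child genotype")
    post /= total
    return PosteriorCall(genotype=int(post.argmax()), posterior=post, prior_source=source)
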