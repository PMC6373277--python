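"""Exact 2x2 statistics shared by the enrichment and clinical modules.

The two-sided Fisher exact p value is computed by minimum-likelihood
summation: conditioning on both margins, the p value is the sum of
hypergeometric probabilities of every table whose probability does not
exceed that of the observed table (with a small relative tolerance for
ties, since probabilities are computed in floating point).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

#: relative tolerance used to group probability ties in the two-sided sum
TIE_RTOL = 1e-9


def _support(n: int, row1: int, col1: int) -> np.ndarray:
    """Support of the table's (1,1) cell given total n and the two margins."""
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    return np.arange(lo, hi + 1)


def two_sided_pvalues(n: int, row1: int, col1: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher p for every table with the given margins.

    Returns ``(support, pvalues)`` where ``support`` is the range of
    possible (1,1) cells and ``pvalues[i]`` the minimum-likelihood
    two-sided p for ``a = support[i]``.  Computing the whole conditional
    family at once is both cheaper and makes the summation convention
    explicit in one place.
    """
    ks = _support(n, row1, col1)
    pmf = hypergeom.pmf(ks, n, row1, col1)
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    # for each table, sum all probabilities <= pmf_obs * (1 + TIE_RTOL)
    sorted_pmf = pmf[order]
    idx = np.searchsorted(sorted_pmf, pmf * (1.0 + TIE_RTOL), side="right")
    pvals = np.where(idx > 0, csum[np.maximum(idx - 1, 0)], 0.0)
    return ks, np.minimum(pvals, 1.0)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact test for the table ``[[a, b], [c, d]]``.

    Degenerate margins (an empty row or column) carry no information and
    return p = 1.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("2x2 cell counts must be non-negative")
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return 1.0
    ks, pvals = two_sided_pvalues(n, row1, col1)
    return float(pvals[np.searchsorted(ks, a)])


def odds_ratio_haldane(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio with the Haldane–Anscombe 0.5 correction.

    The correction is applied only when a zero cell occurs; otherwise the
    plain cross-product ratio is returned.
    """
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)
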