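"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: exact integer
arithmetic for hypergeometric enumeration, elementary Bayes computation
for trio refinement, and allele-set enumeration for Mendelian checks.
"""

from __future__ import annotations

import bisect
from fractions import Fraction
from math import comb

import numpy as np

#: same relative tie tolerance as the implementation, applied in exact
#: integer arithmetic: include k when num_k * 1e9 <= num_a * (1e9 + 1)
TIE_NUM = 10 ** 9


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact-integer minimum-likelihood enumeration."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return 1.0
    ks, ps = fisher_two_sided_pvalues_oracle(n, row1, col1)
    return ps[ks.index(a)]


def fisher_two_sided_pvalues_oracle(n: int, row1: int, col1: int):
    """All conditional two-sided p values for the given margins, exactly."""
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    ks = list(range(lo, hi + 1))
    nums = [comb(row1, k) * comb(n - row1, col1 - k) for k in ks]
    denom = comb(n, col1)
    order = sorted(range(len(nums)), key=nums.__getitem__)
    sorted_nums = [nums[i] for i in order]
    prefix = [0]
    for v in sorted_nums:
        prefix.append(prefix[-1] + v)
    scaled = [v * TIE_NUM for v in sorted_nums]
    pvals = []
    for v in nums:
        idx = bisect.bisect_right(scaled, v * (TIE_NUM + 1))
        pvals.append(min(float(Fraction(prefix[idx], denom)), 1.0))
    return ks, pvals


def mendelian_consistent_oracle(child: int, mother: int, father: int) -> bool:
    """Child formable from one transmitted allele of each parent."""
    alleles = {0: (0,), 1: (0, 1), 2: (1,)}
    return any(am + af == child
               for am in alleles[mother] for af in alleles[father])


def refine_oracle(pl, mother, father, leak, population_af=None):
    """Elementary Bayes posterior over the child genotype."""
    like = [10.0 ** (-p / 10.0) for p in pl]

    def t_alt(g):
        if g == -1:
            t = population_af
        else:
            t = g / 2.0
        return t * (1 - leak) + (1 - t) * leak

    tm, tf = t_alt(mother), t_alt(father)
    prior = [(1 - tm) * (1 - tf), tm * (1 - tf) + (1 - tm) * tf, tm * tf]
    post = np.array([li * pr for li, pr in zip(like, prior)])
    return post / post.sum()


def pearson_oracle(x, y):
    """Pearson r and two-sided t p value from the textbook formulas."""
    from scipy.stats import t as tdist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xm, ym = x - x.mean(), y - y.mean()
    r = float(np.sum(xm * ym) / np.sqrt(np.sum(xm ** 2) * np.sum(ym ** 2)))
    if abs(r) >= 1.0:
        return r, 0.0
    tstat = r * np.sqrt((n - 2) / (1 - r * r))
    return r, float(2 * tdist.sf(abs(tstat), n - 2))
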