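"""Independent brute-force oracles used to pin expected values.

Everything here is deliberately naive — exact integer/rational arithmetic,
per-position set enumeration, direct definition checks — and shares no code
with the implementation paths it validates.
"""

from __future__ import annotations

import math
from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer enumeration of the hypergeometric
    weights, including tables whose probability is within the customary
    1e-7 relative slack of the observed one."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    weights = {k: comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w * 10**7 <= w_obs * (10**7 + 1))
    return min(num / comb(n, c1), 1.0)


def hwe_exact_enumeration(hom_ref: int, het: int, hom_alt: int) -> float:
    """HWE exact p by full enumeration over genotype configurations with the
    same allele counts, in exact rational arithmetic."""
    n = hom_ref + het + hom_alt
    n_a = 2 * hom_ref + het
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0

    def weight(h: int) -> Fraction:
        r_hom = (rare - h) // 2
        c_hom = n - h - r_hom
        return Fraction(
            math.factorial(n) * 2**h,
            math.factorial(r_hom) * math.factorial(h) * math.factorial(c_hom),
        )

    hs = list(range(rare % 2, rare + 1, 2))
    weights = {h: weight(h) for h in hs}
    total = sum(weights.values())
    w_obs = weights[het]
    return float(sum(w for w in weights.values() if w <= w_obs) / total)


def mendelian_violations(child: np.ndarray, mother: np.ndarray,
                         father: np.ndarray) -> int:
    """Count sites where the child's alleles cannot come one-from-each-parent.

    Arrays are (n_sites, 2) allele matrices with -9 marking an absent second
    allele (haploid).  Haploid children must match one maternal allele.
    """
    bad = 0
    for c, m, f in zip(child, mother, father):
        c_all = [a for a in c if a >= 0]
        m_all = [a for a in m if a >= 0]
        f_all = [a for a in f if a >= 0]
        if len(c_all) == 1:
            if c_all[0] not in m_all:
                bad += 1
            continue
        ok = any(
            (c_all[0] == ma and c_all[1] in f_all)
            or (c_all[1] == ma and c_all[0] in f_all)
            for ma in m_all
        )
        if not ok:
            bad += 1
    return bad


def region_positions(start: int, end: int) -> set[int]:
    return set(range(start, end + 1))


def kmeans_1d_two(values: np.ndarray, iters: int = 50) -> np.ndarray:
    """Plain 2-means on a 1-D array; returns 0/1 labels."""
    v = np.asarray(values, dtype=float)
    c0, c1 = v.min(), v.max()
    labels = np.zeros(len(v), dtype=int)
    for _ in range(iters):
        labels = (np.abs(v - c1) < np.abs(v - c0)).astype(int)
        new0 = v[labels == 0].mean() if (labels == 0).any() else c0
        new1 = v[labels == 1].mean() if (labels == 1).any() else c1
        if new0 == c0 and new1 == c1:
            break
        c0, c1 = new0, new1
    return labels
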