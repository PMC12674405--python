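"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a statistic by the most direct route available —
exact rational enumeration, closed-form textbook formulas, literal
pair-by-pair string comparison — sharing no code with the implementation
it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def hwe_exact_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value by exhaustive enumeration in rational arithmetic.

    Conditional on allele counts, P(h heterozygotes) =
    n! / (nAA! h! naa!) * 2^h * nA! * na! / (2n)!; the two-sided p sums
    probabilities <= the observed one. Exact until the final float cast.
    """
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0
    const = Fraction(math.factorial(n) * math.factorial(n_A)
                     * math.factorial(n_a), math.factorial(2 * n))
    probs: dict[int, Fraction] = {}
    for h in range(n_Aa % 2, min(n_A, n_a) + 1, 2):
        naa = (n_a - h) // 2
        nAA = (n_A - h) // 2
        probs[h] = const * Fraction(2 ** h,
                                    math.factorial(nAA) * math.factorial(h)
                                    * math.factorial(naa))
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


def wc_fst_oracle(counts1, counts2) -> tuple[float, float, float]:
    """Two-population Weir-Cockerham (1984) estimator from the published
    closed-form a/b/c variance components. Returns (a, a+b+c, theta)."""
    counts1 = np.asarray(counts1, float)
    counts2 = np.asarray(counts2, float)
    r = 2
    n1, n2 = counts1.sum(), counts2.sum()
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    p1 = (counts1[1] + 2 * counts1[2]) / (2 * n1)
    p2 = (counts2[1] + 2 * counts2[2]) / (2 * n2)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    h1 = counts1[1] / n1
    h2 = counts2[1] / n2
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                             - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    den = a + b + c
    return a, den, (a / den if den != 0 else float("nan"))


def ehh_string_oracle(alleles: np.ndarray, core: int, carriers: np.ndarray,
                      target: int) -> float:
    """EHH by literal pair comparison: the fraction of carrier pairs whose
    haplotypes are identical over the whole interval core..target
    (excluding the core site itself)."""
    lo, hi = (target, core - 1) if target < core else (core + 1, target)
    segs = ["".join(map(str, alleles[h, lo:hi + 1])) for h in carriers]
    n = len(segs)
    same = sum(segs[i] == segs[j] for i in range(n) for j in range(i + 1, n))
    return same / (n * (n - 1) / 2)


def pi_hamming_oracle(column: np.ndarray) -> float:
    """Per-site pi as the literal mean pairwise Hamming difference."""
    n = len(column)
    diffs = sum(int(column[i] != column[j])
                for i in range(n) for j in range(i + 1, n))
    return diffs / (n * (n - 1) / 2)


def quantile_select_oracle(values, fraction, tail):
    """Selection by explicit sorting: indices of the ceil(fraction*n) most
    extreme defined values (ties broaden the set)."""
    values = np.asarray(values, float)
    idx = np.flatnonzero(np.isfinite(values))
    scored = np.abs(values[idx]) if tail == "abs_upper" else values[idx]
    order = np.argsort(scored)
    if tail != "lower":
        order = order[::-1]
    k = max(int(np.ceil(fraction * len(idx))) - 0, 0)
    if k == 0:
        return set()
    cut = scored[order[k - 1]]
    if tail == "lower":
        return set(idx[scored <= cut])
    return set(idx[scored >= cut])
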