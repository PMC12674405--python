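"""Weir-Cockerham Fst between the two groups and nucleotide diversity
within one group, per site and in sliding windows.

Fst uses the two-population Weir-Cockerham variance-components estimator,
computed here by the nested analysis of variance on allele indicators
(populations / individuals within populations / gametes within
individuals). The mean squares map onto the familiar ratio form

    Fst = (MSP - MSG) / (MSP + (Nc - 1) * MSG)

with MSP the between-population mean square, MSG the within-population
mean square and Nc the corrected average sample size; the implementation
retains the variance components' numerator and denominator per site so
windows can be aggregated as a ratio of sums ("weighted" Fst).

Windows tile each chromosome on a step-aligned grid anchored at
coordinate 1; a window [s, s + L - 1] is emitted when it overlaps the
observed SNP span. Windows with no SNPs carry an undefined (NaN) value
for Fst, zero for pi, and are excluded from tail-quantile computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FST_WINDOW_BP = 50_000
FST_STEP_BP = 12_500
PI_WINDOW_BP = 500_000
PI_STEP_BP = 50_000


@dataclass
class FstSiteComponents:
    """Per-site Weir-Cockerham pieces.

    ``num``/``den`` are the variance components a and a+b+c; ``fst_site``
    = num/den when den > 0, else NaN (flagged undefined). ``msp``/``msg``/
    ``nc`` are the nested-ANOVA mean squares and corrected sample size.
    """

    msp: float
    msg: float
    nc: float
    num: float
    den: float
    fst_site: float


@dataclass
class WindowStat:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_snps: int
    value: float


def _anova_components(counts1, counts2):
    """Nested ANOVA on the 0/1 allele indicator: sums of squares at the
    population, individual and gamete levels, from genotype counts."""
    counts1 = np.asarray(counts1, dtype=float)
    counts2 = np.asarray(counts2, dtype=float)
    n1, n2 = counts1.sum(), counts2.sum()
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 called individuals per population")
    r = 2
    n_tot = n1 + n2
    # allele counts: genotype k in {0,1,2} carries k alt alleles
    k = np.array([0.0, 1.0, 2.0])
    alt1, alt2 = counts1 @ k, counts2 @ k
    p1, p2 = alt1 / (2 * n1), alt2 / (2 * n2)
    pbar = (alt1 + alt2) / (2 * n_tot)
    het1, het2 = counts1[1], counts2[1]

    # SS between populations (alleles as units, population means p_i)
    ss_pops = 2 * n1 * (p1 - pbar) ** 2 + 2 * n2 * (p2 - pbar) ** 2
    # SS individuals within populations: individual mean = dosage/2
    # sum over individuals of 2*(dose/2 - p_i)^2
    def ss_ind(counts, p):
        dose_means = np.array([0.0, 0.5, 1.0])
        return float(counts @ (2 * (dose_means - p) ** 2))
    ss_inds = ss_ind(counts1, p1) + ss_ind(counts2, p2)
    # SS gametes within individuals: each het contributes 2*(1/2)^2 = 1/2
    ss_gam = (het1 + het2) / 2.0

    msp = ss_pops / (r - 1)
    df_ind = n_tot - r
    msi = ss_inds / df_ind if df_ind > 0 else 0.0
    msg = ss_gam / n_tot
    nc = (n_tot - (n1 ** 2 + n2 ** 2) / n_tot) / (r - 1)
    return msp, msi, msg, nc


def fst_site_components(counts_pop1, counts_pop2) -> FstSiteComponents:
    """Weir-Cockerham variance components for one biallelic site.

    ``counts_pop*`` are (hom-ref, het, hom-alt) genotype counts. A site
    monomorphic for the same allele in both populations has zero
    denominator and is flagged undefined (NaN).
    """
    msp, msi, msg, nc = _anova_components(counts_pop1, counts_pop2)
    a = (msp - msi) / (2 * nc)  # between-population component
    b = (msi - msg) / 2         # between individuals within populations
    c = msg                     # within individuals
    num, den = a, a + b + c
    fst = num / den if den > 0 else float("nan")
    return FstSiteComponents(msp=msp, msg=msg, nc=nc, num=num, den=den,
                             fst_site=fst)


def pi_site(derived_count: int, called_haplotypes: int) -> float:
    """Per-site nucleotide diversity: average pairwise difference
    2k(n-k)/(n(n-1)) over the n called haplotypes."""
    k, n = derived_count, called_haplotypes
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if n < 2:
        return float("nan")
    return 2.0 * k * (n - k) / (n * (n - 1))


def window_grid(first_pos: int, last_pos: int, window_bp: int, step_bp: int
                ) -> np.ndarray:
    """Start coordinates of all step-aligned windows (grid anchored at 1)
    whose [start, start+window-1] interval overlaps [first_pos, last_pos]."""
    lo = max(1, first_pos - window_bp + 1)
    start0 = 1 + ((lo - 1) // step_bp) * step_bp
    if start0 < lo:  # the aligned start just below lo no longer overlaps
        start0 += step_bp
    # never start past first_pos, never miss a window covering it
    start0 = min(start0, 1 + ((first_pos - 1) // step_bp) * step_bp)
    return np.arange(start0, last_pos + 1, step_bp, dtype=np.int64)


def _windowize(pos, per_site_num, per_site_den, window_bp, step_bp, chrom,
               mode: str, norm_by_length: bool) -> list[WindowStat]:
    pos = np.asarray(pos)
    order = np.argsort(pos)
    pos = pos[order]
    per_site_num = np.asarray(per_site_num, dtype=float)[order]
    if per_site_den is not None:
        per_site_den = np.asarray(per_site_den, dtype=float)[order]
    out = []
    for start in window_grid(int(pos[0]), int(pos[-1]), window_bp, step_bp):
        end = start + window_bp - 1
        i0, i1 = np.searchsorted(pos, [start, end + 1])
        n = int(i1 - i0)
        if n == 0:
            value = 0.0 if norm_by_length else float("nan")
        elif norm_by_length:
            value = float(np.nansum(per_site_num[i0:i1])) / window_bp
        elif mode == "weighted":
            den = float(np.nansum(per_site_den[i0:i1]))
            value = float(np.nansum(per_site_num[i0:i1])) / den \
                if den > 0 else float("nan")
        else:  # mean of defined per-site values
            vals = per_site_num[i0:i1] / per_site_den[i0:i1]
            vals = vals[np.isfinite(vals)]
            value = float(vals.mean()) if len(vals) else float("nan")
        out.append(WindowStat(chrom, int(start), int(end), n, value))
    return out


def fst_windowed(pos, components: list[FstSiteComponents],
                 window_bp: int = FST_WINDOW_BP, step_bp: int = FST_STEP_BP,
                 mode: str = "weighted", chrom: str = "1") -> list[WindowStat]:
    """Sliding-window Fst. ``weighted`` mode is the ratio of summed
    numerators to summed denominators (negative site values retained);
    ``mean`` averages the defined per-site ratios."""
    if mode not in ("weighted", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    num = [c.num for c in components]
    den = [c.den for c in components]
    return _windowize(pos, num, den, window_bp, step_bp, chrom, mode, False)


def pi_windowed(pos, pi_sites, window_bp: int = PI_WINDOW_BP,
                step_bp: int = PI_STEP_BP, chrom: str = "1") -> list[WindowStat]:
    """Sliding-window nucleotide diversity: sum of per-site pi divided by
    window length (monomorphic positions contribute zero implicitly)."""
    return _windowize(pos, pi_sites, None, window_bp, step_bp, chrom,
                      "sum", True)
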