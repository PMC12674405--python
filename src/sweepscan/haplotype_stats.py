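"""Extended haplotype homozygosity and the haplotype-length scan
statistics built on it.

EHH at distance x from a core site is the probability that two randomly
drawn carrier haplotypes of the core allele are identical over the whole
interval from the core to x. With carriers partitioned into groups of
identical extended haplotypes of sizes n_g,

    EHH(x) = sum_g C(n_g, 2) / C(n, 2).

iHH integrates EHH over genetic distance separately for ancestral- and
derived-allele carriers; uniHS = ln(iHH_A / iHH_D) is standardized within
derived-allele-frequency bins to give iHS. iES integrates the pooled
homozygosity profile of all haplotypes of one population; the
cross-population contrast unxpEHH = ln(iES_ref / iES_test) is
standardized genome-wide to give xpEHH. The pooled profile is anchored at
1 at the core (the core allele itself does not partition haplotypes), so
the statistic measures flanking haplotype length only.

Profiles stop at the chromosome edge, when EHH falls below ``limehh``
(that point is kept, so the trapezoid closes), or when the gap to the
next SNP exceeds ``maxgap_bp``; which one is recorded. For xpEHH the two
populations share one truncation point: extension continues until both
pooled profiles are below ``limehh`` (or edge/gap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import HaplotypeMatrix

LIMEHH = 0.05
MAXGAP_BP = 200_000
MIN_MAF = 0.05
FREQ_BIN = 0.05
MIN_BIN_RECORDS = 10


@dataclass
class EHHProfile:
    core_index: int
    allele: str  # ancestral | derived | pooled
    side: str  # left | right
    distances_cM: np.ndarray  # from the core, starting at 0
    ehh: np.ndarray  # starting at 1
    truncated_by: str  # edge | limehh | maxgap


def _homozygosity(labels: np.ndarray) -> float:
    counts = np.bincount(labels)
    n = labels.size
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _refine(labels: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    # split each group by the allele at the new site; canonicalize labels
    return np.unique(labels * 2 + alleles, return_inverse=True)[1]


def ehh_profile(hap: HaplotypeMatrix, core_index: int, allele: str,
                side: str, limehh: float = LIMEHH,
                maxgap_bp: int = MAXGAP_BP) -> EHHProfile | None:
    """EHH decay profile on one side of a core site.

    Returns None (undefined) when fewer than 2 haplotypes carry the
    requested core allele; such cores are skipped downstream.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be left/right, got {side!r}")
    col = hap.alleles[:, core_index]
    if allele == "ancestral":
        carriers = np.flatnonzero(col == 0)
    elif allele == "derived":
        carriers = np.flatnonzero(col == 1)
    elif allele == "pooled":
        carriers = np.arange(hap.n_haps)
    else:
        raise ValueError(f"unknown core allele {allele!r}")
    if carriers.size < 2:
        return None
    sub = hap.alleles[carriers]
    dists = [0.0]
    ehh = [1.0]
    labels = np.zeros(carriers.size, dtype=np.int64)
    step = -1 if side == "left" else 1
    j = core_index
    truncated = "edge"
    while True:
        jn = j + step
        if jn < 0 or jn >= hap.n_sites:
            break
        if abs(int(hap.positions_bp[jn]) - int(hap.positions_bp[j])) > maxgap_bp:
            truncated = "maxgap"
            break
        labels = _refine(labels, sub[:, jn])
        e = _homozygosity(labels)
        dists.append(abs(hap.positions_cM[jn] - hap.positions_cM[core_index]))
        ehh.append(e)
        if e < limehh:
            truncated = "limehh"
            break
        j = jn
    return EHHProfile(core_index, allele, side, np.asarray(dists),
                      np.asarray(ehh), truncated)


def ihh(left: EHHProfile, right: EHHProfile) -> float:
    """Integrated EHH: trapezoidal integral over cM, both sides summed."""
    if left.core_index != right.core_index:
        raise ValueError("profiles have different cores")
    total = 0.0
    for p in (left, right):
        if p.distances_cM.size > 1:
            total += float(np.trapezoid(p.ehh, p.distances_cM))
    return total


def ihh_at(hap: HaplotypeMatrix, core_index: int, allele: str,
           limehh: float = LIMEHH, maxgap_bp: int = MAXGAP_BP) -> float:
    """iHH for one core allele; NaN when the allele has < 2 carriers."""
    left = ehh_profile(hap, core_index, allele, "left", limehh, maxgap_bp)
    right = ehh_profile(hap, core_index, allele, "right", limehh, maxgap_bp)
    if left is None or right is None:
        return float("nan")
    return ihh(left, right)


# ---------------------------------------------------------------------------
# iHS


def _merge_small_bins(bin_ids: np.ndarray, defined: np.ndarray,
                      n_bins: int, min_records: int) -> np.ndarray:
    """Merge frequency bins holding < min_records defined records into the
    nearest (by bin center) non-empty neighbour. Returns merged bin ids."""
    groups: list[list[int]] = [[b] for b in range(n_bins)]
    while len(groups) > 1:
        cnt = [int(defined[np.isin(bin_ids, g)].sum()) for g in groups]
        # drop empty groups outright; they constrain nothing
        if 0 in cnt:
            k = cnt.index(0)
            groups.pop(k)
            continue
        small = [i for i, c in enumerate(cnt) if c < min_records]
        if not small:
            break
        k = min(small, key=lambda i: cnt[i])
        nb = k - 1 if k > 0 else k + 1
        if 0 < k < len(groups) - 1:
            # nearest neighbour by mean bin index
            left_c = np.mean(groups[k - 1])
            right_c = np.mean(groups[k + 1])
            me = np.mean(groups[k])
            nb = k - 1 if abs(me - left_c) <= abs(right_c - me) else k + 1
        groups[min(k, nb)] = groups[min(k, nb)] + groups[max(k, nb)]
        groups.pop(max(k, nb))
    merged = np.full(n_bins, -1, dtype=np.int64)
    for gi, g in enumerate(groups):
        merged[g] = gi
    return merged[bin_ids]


def standardize_by_bin(values: np.ndarray, ps: np.ndarray,
                       freq_bin: float = FREQ_BIN,
                       min_records: int = MIN_BIN_RECORDS) -> np.ndarray:
    """(value - mean_bin) / sd_bin within derived-frequency bins; bins with
    too few defined records are merged with their nearest neighbour. Bins
    whose sd is zero after merging yield NaN."""
    values = np.asarray(values, dtype=float)
    n_bins = int(np.ceil(1.0 / freq_bin))
    bin_ids = np.minimum((np.asarray(ps) / freq_bin).astype(int), n_bins - 1)
    defined = np.isfinite(values)
    bin_ids = _merge_small_bins(bin_ids, defined, n_bins, min_records)
    out = np.full_like(values, np.nan)
    for b in np.unique(bin_ids):
        sel = (bin_ids == b) & defined
        if not sel.any():
            continue
        mu = values[sel].mean()
        sd = values[sel].std()
        if sd > 0:
            out[sel] = (values[sel] - mu) / sd
    return out


def ihs_scan(hap: HaplotypeMatrix, min_maf: float = MIN_MAF,
             freq_bin: float = FREQ_BIN, limehh: float = LIMEHH,
             maxgap_bp: int = MAXGAP_BP,
             standardize: bool = True) -> pd.DataFrame:
    """iHS over every core whose derived frequency lies in
    [min_maf, 1 - min_maf], within a single population.

    Returns a frame with columns chrom, pos, ps, ihh_a, ihh_d, unihs, ihs;
    records with a zero or undefined integral carry NaN and are excluded
    from the bin standardization.
    """
    ps_all = hap.derived_freq()
    rows = []
    for core in range(hap.n_sites):
        ps = float(ps_all[core])
        if ps < min_maf or ps > 1 - min_maf:
            continue
        a = ihh_at(hap, core, "ancestral", limehh, maxgap_bp)
        d = ihh_at(hap, core, "derived", limehh, maxgap_bp)
        unihs = np.log(a / d) if a > 0 and d > 0 else float("nan")
        rows.append((hap.chrom, int(hap.positions_bp[core]), ps, a, d, unihs))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ps", "ihh_a", "ihh_d",
                                     "unihs"])
    if standardize and len(df):
        df["ihs"] = standardize_by_bin(df["unihs"].to_numpy(),
                                       df["ps"].to_numpy(), freq_bin)
    else:
        df["ihs"] = np.nan
    return df


# ---------------------------------------------------------------------------
# xpEHH


def _pooled_side(hap1: HaplotypeMatrix, hap2: HaplotypeMatrix,
                 core: int, side: str, limehh: float, maxgap_bp: int
                 ) -> tuple[float, float]:
    """Side integrals of the two pooled homozygosity profiles, walked in
    lockstep to a shared truncation point (both below limehh, edge, gap)."""
    step = -1 if side == "left" else 1
    l1 = np.zeros(hap1.n_haps, dtype=np.int64)
    l2 = np.zeros(hap2.n_haps, dtype=np.int64)
    dists = [0.0]
    e1s, e2s = [1.0], [1.0]
    j = core
    while True:
        jn = j + step
        if jn < 0 or jn >= hap1.n_sites:
            break
        if abs(int(hap1.positions_bp[jn]) - int(hap1.positions_bp[j])) > maxgap_bp:
            break
        l1 = _refine(l1, hap1.alleles[:, jn])
        l2 = _refine(l2, hap2.alleles[:, jn])
        e1, e2 = _homozygosity(l1), _homozygosity(l2)
        dists.append(abs(hap1.positions_cM[jn] - hap1.positions_cM[core]))
        e1s.append(e1)
        e2s.append(e2)
        if e1 < limehh and e2 < limehh:
            break
        j = jn
    x = np.asarray(dists)
    if x.size < 2:
        return 0.0, 0.0
    return (float(np.trapezoid(np.asarray(e1s), x)),
            float(np.trapezoid(np.asarray(e2s), x)))


def ies_pair(hap_ref: HaplotypeMatrix, hap_test: HaplotypeMatrix, core: int,
             limehh: float = LIMEHH, maxgap_bp: int = MAXGAP_BP
             ) -> tuple[float, float]:
    """(iES_ref, iES_test) at one core, common truncation on each side."""
    la, lb = _pooled_side(hap_ref, hap_test, core, "left", limehh, maxgap_bp)
    ra, rb = _pooled_side(hap_ref, hap_test, core, "right", limehh, maxgap_bp)
    return la + ra, lb + rb


def xpehh_scan(hap_ref: HaplotypeMatrix, hap_test: HaplotypeMatrix,
               limehh: float = LIMEHH, maxgap_bp: int = MAXGAP_BP,
               standardize: bool = True) -> pd.DataFrame:
    """Cross-population EHH scan; reference population in the numerator.

    Both matrices must share an identical site list. Returns a frame with
    columns chrom, pos, ies_pop1 (reference), ies_pop2 (test), unxpehh,
    xpehh (standardized genome-wide to mean 0, sd 1).
    """
    if not np.array_equal(hap_ref.positions_bp, hap_test.positions_bp):
        raise ValueError("reference and test matrices must share sites")
    rows = []
    for core in range(hap_ref.n_sites):
        i1, i2 = ies_pair(hap_ref, hap_test, core, limehh, maxgap_bp)
        un = np.log(i1 / i2) if i1 > 0 and i2 > 0 else float("nan")
        rows.append((hap_ref.chrom, int(hap_ref.positions_bp[core]),
                     i1, i2, un))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ies_pop1", "ies_pop2",
                                     "unxpehh"])
    if standardize and len(df):
        un = df["unxpehh"].to_numpy()
        ok = np.isfinite(un)
        x = np.full_like(un, np.nan)
        if ok.sum() >= 2 and un[ok].std() > 0:
            x[ok] = (un[ok] - un[ok].mean()) / un[ok].std()
        df["xpehh"] = x
    else:
        df["xpehh"] = np.nan
    return df
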