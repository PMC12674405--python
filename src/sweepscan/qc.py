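"""Dataset QC: the five chip-style filtering criteria with an exact
Hardy-Weinberg test.

Filtering order is the standard chip-QC convention: low-call-rate
individuals are removed first, then site filters are applied in the order
(missing chrom/pos, site missingness, MAF, HWE); a site is charged to the
first criterion it fails. All thresholds are strict inequalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .variant_io import VariantTable

logger = logging.getLogger(__name__)


class QcError(RuntimeError):
    """All samples or all sites removed by QC."""


@dataclass
class QcConfig:
    """Thresholds for the five filtering criteria (all strict).

    Defaults: site missingness > 0.1 removed; MAF < 0.01 removed;
    individual call rate < 0.90 removed; exact HWE p < 1e-5 removed.
    """

    max_site_missing: float = 0.1
    min_maf: float = 0.01
    min_ind_call_rate: float = 0.90
    hwe_p_threshold: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("max_site_missing", "min_maf", "min_ind_call_rate",
                     "hwe_p_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name}={v} outside (0, 1]")


@dataclass
class QcReport:
    n_samples_in: int = 0
    n_samples_out: int = 0
    n_sites_in: int = 0
    n_sites_out: int = 0
    removed_samples: list[str] = field(default_factory=list)
    # criterion name -> number of sites removed by it (first-failure charging)
    site_removals: dict[str, int] = field(default_factory=dict)
    removed_sites: list[str] = field(default_factory=list)  # "chrom:pos reason"

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("axis\tmetric\tvalue\n")
            fh.write(f"samples\tin\t{self.n_samples_in}\n")
            fh.write(f"samples\tout\t{self.n_samples_out}\n")
            fh.write(f"samples\tremoved_low_call_rate\t{len(self.removed_samples)}\n")
            fh.write(f"sites\tin\t{self.n_sites_in}\n")
            fh.write(f"sites\tout\t{self.n_sites_out}\n")
            for crit, n in self.site_removals.items():
                fh.write(f"sites\tremoved_{crit}\t{n}\n")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    the observed one (the standard exact-HWE tail; no mid-p). Returns 1.0
    for a monomorphic site by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa < 1:
        raise ValueError("counts must be non-negative with total >= 1")
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # rarer-or-not does not matter; symmetric below
    n_A = 2 * n_AA + n_Aa
    if n_a == 0 or n_A == 0:
        return 1.0
    n_minor = min(n_A, n_a)
    # possible heterozygote counts share the parity of the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # P(het = h | allele counts) ~ 2^h * n! / (nAA! nAa! naa!) with
    # nAA = (n_A - h)/2 etc.; normalized below, so drop the shared factor
    naa = (n_minor - hets) // 2
    nAA = (max(n_A, n_a) - hets) // 2
    logp = (hets * np.log(2.0) - gammaln(nAA + 1) - gammaln(hets + 1)
            - gammaln(naa + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    # tolerance guards against ties lost to floating point
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def site_missingness(vt: VariantTable) -> np.ndarray:
    return (vt.genotypes < 0).any(axis=2).mean(axis=1)


def site_maf(vt: VariantTable) -> np.ndarray:
    """Minor allele frequency from called alleles only."""
    g = vt.genotypes
    called = g >= 0
    alt = np.where(called, g, 0).sum(axis=(1, 2))
    tot = called.sum(axis=(1, 2))
    with np.errstate(invalid="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    return np.minimum(p, 1 - p)


def genotype_counts(vt: VariantTable) -> np.ndarray:
    """(M, 3) counts of hom-ref, het, hom-alt among fully called samples."""
    g = vt.genotypes
    ok = (g >= 0).all(axis=2)
    dose = g.sum(axis=2)
    out = np.zeros((vt.n_sites, 3), dtype=np.int64)
    for k in range(3):
        out[:, k] = ((dose == k) & ok).sum(axis=1)
    return out


def filter_individuals(vt: VariantTable, cfg: QcConfig | None = None
                       ) -> tuple[VariantTable, QcReport]:
    """Remove samples with genotyping rate below ``min_ind_call_rate``."""
    cfg = cfg or QcConfig()
    rep = QcReport(n_samples_in=vt.n_samples, n_sites_in=vt.n_sites,
                   n_sites_out=vt.n_sites)
    called = (vt.genotypes >= 0).all(axis=2)  # (M, N)
    rate = called.mean(axis=0)
    keep = rate >= cfg.min_ind_call_rate  # strict <: removal
    rep.removed_samples = [s for s, k in zip(vt.samples, keep) if not k]
    if not keep.any():
        raise QcError("no samples survive QC")
    out = vt.take_samples(np.flatnonzero(keep)) if not keep.all() else vt
    rep.n_samples_out = out.n_samples
    if rep.removed_samples:
        logger.info("QC: removed %d low-call-rate individuals",
                    len(rep.removed_samples))
    return out, rep


def filter_variants(vt: VariantTable, cfg: QcConfig | None = None
                    ) -> tuple[VariantTable, QcReport]:
    """Apply the four site-level criteria; each site is charged to the
    first criterion it fails."""
    cfg = cfg or QcConfig()
    rep = QcReport(n_samples_in=vt.n_samples, n_samples_out=vt.n_samples,
                   n_sites_in=vt.n_sites)
    keep = np.ones(vt.n_sites, dtype=bool)
    rep.site_removals = {"no_position": 0, "missingness": 0, "maf": 0, "hwe": 0}

    no_pos = (vt.pos < 1) | np.array(
        [c in ("", ".", "0", "NA") for c in vt.chrom])
    miss = site_missingness(vt)
    maf = site_maf(vt)
    counts = genotype_counts(vt)

    for i in range(vt.n_sites):
        if no_pos[i]:
            reason = "no_position"
        elif miss[i] > cfg.max_site_missing:
            reason = "missingness"
        elif not np.isnan(maf[i]) and maf[i] < cfg.min_maf:
            reason = "maf"
        elif hwe_exact_test(*counts[i]) < cfg.hwe_p_threshold:
            reason = "hwe"
        else:
            continue
        keep[i] = False
        rep.site_removals[reason] += 1
        rep.removed_sites.append(f"{vt.chrom[i]}:{vt.pos[i]}\t{reason}")
    if not keep.any():
        raise QcError("no sites survive QC")
    out = vt.take_sites(keep) if not keep.all() else vt
    rep.n_sites_out = out.n_sites
    logger.info("QC sites: %d -> %d (%s)", vt.n_sites, out.n_sites,
                rep.site_removals)
    return out, rep


def run_qc(vt: VariantTable, cfg: QcConfig | None = None
           ) -> tuple[VariantTable, QcReport]:
    """Individuals first, then sites; merged report."""
    cfg = cfg or QcConfig()
    vt1, rep_ind = filter_individuals(vt, cfg)
    vt2, rep_var = filter_variants(vt1, cfg)
    rep = QcReport(
        n_samples_in=rep_ind.n_samples_in, n_samples_out=rep_ind.n_samples_out,
        n_sites_in=rep_var.n_sites_in, n_sites_out=rep_var.n_sites_out,
        removed_samples=rep_ind.removed_samples,
        site_removals=rep_var.site_removals,
        removed_sites=rep_var.removed_sites)
    return vt2, rep
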