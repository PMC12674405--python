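"""Two-population phased haplotype simulator with an optional hard sweep.

The generator is a fast haplotype-copying model, not a population-genetic
simulator: it produces exactly the features the scan statistics respond
to — background allele-frequency differentiation between the two groups,
chip-like allele-frequency spectrum, local linkage disequilibrium, and a
hard sweep in the test population that creates long shared haplotypes,
elevated differentiation and a diversity trough around a known core.

Mechanics: ancestral frequencies are drawn from a 1/p spectrum truncated
at ``maf_floor``; each population's frequency is a Beta perturbation with
variance ``fst_background`` * p(1-p) (the drift parameter the Fst scan
should recover); population haplotypes are mosaics block-copied from a
per-population founder panel (panel size adds ~1/n_founders of apparent
drift, which the default panel of 200 keeps small). The sweep replaces a
fraction ``sweep_freq`` of test-population haplotypes with copies of one
template haplotype over contiguous spans whose left/right extents are
exponential with mean ``decay_cM``, so the per-site probability that a
swept haplotype still carries the template at genetic distance d is
exp(-d / decay_cM).

All randomness flows from ``cfg.seed`` through one generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .variant_io import (GeneModel, GeneticMap, HaplotypeMatrix, SampleSet,
                         VariantTable, write_genetic_map, write_sample_groups,
                         write_vcf)

_BASES = np.array(list("ACGT"))


@dataclass
class SweepSimConfig:
    """Simulation parameters; defaults mirror the study design (76
    reference-group and 81 test-group diploids) at desk scale."""

    n_pop1: int = 76  # two_teat (reference) diploids
    n_pop2: int = 81  # multi_teat (test) diploids
    n_sites: int = 2000
    region_bp: int = 5_000_000
    sweep_pos_bp: int = 2_500_000
    sweep_freq: float = 0.8  # fraction of test haplotypes swept
    decay_cM: float = 0.3  # sweep haplotype-identity decay scale
    fst_background: float = 0.02  # drift divergence between the groups
    maf_floor: float = 0.01
    seed: int = 0
    n_founders: int = 200  # copying-panel size per population
    ld_scale_cM: float = 0.05  # founder-switch scale (local LD extent)
    chrom: str = "1"

    def __post_init__(self) -> None:
        if not 0 < self.sweep_freq < 1:
            raise ValueError("sweep_freq must be in (0, 1)")
        if not 1 <= self.sweep_pos_bp <= self.region_bp:
            raise ValueError("sweep_pos_bp outside region")
        for name in ("n_pop1", "n_pop2", "n_sites", "region_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SweepTruth:
    core_index: int
    core_pos_bp: int
    carriers: list[int]  # haplotype row indices in the test matrix
    template: int
    sweep_gene: str | None = None


def _mosaic(founders: np.ndarray, n_haps: int, switch_p: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Assemble haplotypes by block-copying from a founder panel; founder
    changes between adjacent sites with probability switch_p[j]."""
    n_f, m = founders.shape
    out = np.empty((n_haps, m), dtype=np.uint8)
    for h in range(n_haps):
        seg = np.zeros(m, dtype=np.int64)
        seg[1:] = np.cumsum(rng.random(m - 1) < switch_p)
        fids = rng.integers(0, n_f, seg[-1] + 1)
        out[h] = founders[fids[seg], np.arange(m)]
    return out


def _enforce_maf_floor(alleles_pooled: list[np.ndarray], maf_floor: float,
                       rng: np.random.Generator) -> None:
    """Flip the minimum number of random entries so every site's pooled
    minor-allele count reaches ceil(maf_floor * total haplotypes)."""
    total = sum(a.shape[0] for a in alleles_pooled)
    need = int(np.ceil(maf_floor * total))
    stacked = np.vstack(alleles_pooled)
    ones = stacked.sum(axis=0)
    for j in np.flatnonzero((ones < need) | (ones > total - need)):
        minor = 1 if ones[j] < need else 0
        deficit = need - (ones[j] if minor == 1 else total - ones[j])
        rows = np.flatnonzero(stacked[:, j] != minor)
        for r in rng.choice(rows, int(deficit), replace=False):
            # map the pooled row back to its population matrix
            for a in alleles_pooled:
                if r < a.shape[0]:
                    a[r, j] = minor
                    break
                r -= a.shape[0]


def _neutral(cfg: SweepSimConfig, rng: np.random.Generator
             ) -> tuple[HaplotypeMatrix, HaplotypeMatrix]:
    m = cfg.n_sites
    pos = np.sort(rng.choice(cfg.region_bp, m, replace=False)) + 1
    cm = pos.astype(float) * 1e-6  # 1 cM/Mb
    a, b = cfg.maf_floor, 1 - cfg.maf_floor
    # 1/p spectrum on [a, b] via inverse CDF
    p_anc = a * (b / a) ** rng.random(m)
    freqs = []
    f = cfg.fst_background
    for _ in range(2):
        if f > 0:
            alpha = p_anc * (1 - f) / f
            beta = (1 - p_anc) * (1 - f) / f
            freqs.append(rng.beta(alpha, beta))
        else:
            freqs.append(p_anc.copy())
    switch_p = 1 - np.exp(-np.diff(cm) / cfg.ld_scale_cM)
    mats = []
    for pop, (n_dip, prefix) in enumerate([(cfg.n_pop1, "T"),
                                           (cfg.n_pop2, "M")]):
        founders = (rng.random((cfg.n_founders, m)) < freqs[pop]).astype(np.uint8)
        alleles = _mosaic(founders, 2 * n_dip, switch_p, rng)
        samples = [f"{prefix}{i:03d}" for i in range(n_dip) for _ in range(2)]
        mats.append((alleles, samples))
    _enforce_maf_floor([mats[0][0], mats[1][0]], cfg.maf_floor, rng)
    return tuple(
        HaplotypeMatrix(alleles, pos.copy(), cm.copy(), samples, cfg.chrom)
        for alleles, samples in mats
    )


def simulate_neutral(cfg: SweepSimConfig
                     ) -> tuple[HaplotypeMatrix, HaplotypeMatrix]:
    """Two drift-diverged populations with no sweep; deterministic in
    cfg.seed."""
    return _neutral(cfg, np.random.default_rng(cfg.seed))


def impose_sweep(hap_test: HaplotypeMatrix, cfg: SweepSimConfig,
                 rng: np.random.Generator | None = None
                 ) -> tuple[HaplotypeMatrix, SweepTruth]:
    """Overwrite a fraction ``sweep_freq`` of haplotypes with contiguous
    copies of one template around the core nearest ``sweep_pos_bp``."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    core = int(np.argmin(np.abs(hap_test.positions_bp - cfg.sweep_pos_bp)))
    alleles = hap_test.alleles.copy()
    n_haps = alleles.shape[0]
    derived = np.flatnonzero(alleles[:, core] == 1)
    template = int(rng.choice(derived)) if derived.size else \
        int(rng.integers(n_haps))
    alleles[template, core] = 1
    n_swept = int(round(cfg.sweep_freq * n_haps))
    others = np.setdiff1d(np.arange(n_haps), [template])
    carriers = np.concatenate(
        [[template], rng.choice(others, max(n_swept - 1, 0), replace=False)])
    cm = hap_test.positions_cM
    core_cm = cm[core]
    for h in carriers:
        if h == template:
            continue
        left = rng.exponential(cfg.decay_cM)
        right = rng.exponential(cfg.decay_cM)
        span = (cm >= core_cm - left) & (cm <= core_cm + right)
        alleles[h, span] = alleles[template, span]
        alleles[h, core] = 1
    out = HaplotypeMatrix(alleles, hap_test.positions_bp.copy(),
                          hap_test.positions_cM.copy(),
                          list(hap_test.sample_of_hap), hap_test.chrom)
    truth = SweepTruth(core, int(hap_test.positions_bp[core]),
                       sorted(int(h) for h in carriers), template)
    return out, truth


def simulate_sweep_dataset(cfg: SweepSimConfig
                           ) -> tuple[HaplotypeMatrix, HaplotypeMatrix,
                                      SweepTruth]:
    """Neutral pair plus a sweep in the test population, one seed."""
    rng = np.random.default_rng(cfg.seed)
    hap1, hap2 = _neutral(cfg, rng)
    hap2, truth = impose_sweep(hap2, cfg, rng)
    return hap1, hap2, truth


# ---------------------------------------------------------------------------
# dataset emission


def haplotypes_to_variant_table(hap1: HaplotypeMatrix, hap2: HaplotypeMatrix,
                                rng: np.random.Generator) -> VariantTable:
    """Merge the two populations into one phased VariantTable; REF is the
    ancestral (0) allele, ALT the derived, with random base letters."""
    m = hap1.n_sites
    ref_i = rng.integers(0, 4, m)
    alt_i = (ref_i + rng.integers(1, 4, m)) % 4
    alleles = np.vstack([hap1.alleles, hap2.alleles])  # (2N, M)
    geno = alleles.T.reshape(m, -1, 2).astype(np.int8)
    samples = hap1.sample_of_hap[::2] + hap2.sample_of_hap[::2]
    return VariantTable(
        chrom=np.array([hap1.chrom] * m, dtype=object),
        pos=hap1.positions_bp.astype(np.int64),
        ref=_BASES[ref_i].astype(object),
        alt=_BASES[alt_i].astype(object),
        genotypes=geno,
        phased=np.ones((m, len(samples)), dtype=bool),
        samples=samples,
    )


def toy_annotation(cfg: SweepSimConfig, n_genes: int = 50
                   ) -> tuple[list[GeneModel], str]:
    """~n_genes tiled gene models; exactly one spans the sweep position."""
    slot = cfg.region_bp // n_genes
    margin = slot // 10
    genes = []
    sweep_slot = (cfg.sweep_pos_bp - 1) // slot
    sweep_gene = f"G{sweep_slot + 1:03d}"
    half = min(2 * slot // 5, 40_000)
    for k in range(n_genes):
        if k == sweep_slot:
            start = max(1, cfg.sweep_pos_bp - half)
            end = min(cfg.region_bp, cfg.sweep_pos_bp + half)
        else:
            start = k * slot + margin + 1
            end = (k + 1) * slot - margin
        genes.append(GeneModel(f"G{k + 1:03d}", cfg.chrom, start, end,
                               "+" if k % 2 == 0 else "-"))
    return genes, sweep_gene


def write_gff3(genes: list[GeneModel], path: str, region_bp: int) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        chroms = {g.chrom for g in genes}
        for chrom in sorted(chroms):
            fh.write(f"##sequence-region {chrom} 1 {region_bp}\n")
        for g in genes:
            fh.write(f"{g.chrom}\tsweepscan_sim\tgene\t{g.start}\t{g.end}\t."
                     f"\t{g.strand}\t.\tID={g.gene_id};Name={g.gene_id}\n")


def emit_dataset(cfg: SweepSimConfig, outdir: str, sweep: bool = True
                 ) -> dict[str, str]:
    """Write the full synthetic dataset: phased VCF (both populations),
    sample-group TSV, genetic-map TSV, toy GFF3 and a truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    hap1, hap2 = _neutral(cfg, rng)
    truth: SweepTruth | None = None
    if sweep:
        hap2, truth = impose_sweep(hap2, cfg, rng)
    vt = haplotypes_to_variant_table(hap1, hap2, rng)
    genes, sweep_gene = toy_annotation(cfg)
    if truth is not None:
        truth.sweep_gene = sweep_gene
    groups = SampleSet(
        vt.samples,
        ["two_teat"] * cfg.n_pop1 + ["multi_teat"] * cfg.n_pop2)
    gmap = GeneticMap({cfg.chrom: np.array(
        [[1.0, 1e-6], [float(cfg.region_bp), cfg.region_bp * 1e-6]])})

    paths = {k: str(out / v) for k, v in {
        "vcf": "genotypes.vcf", "groups": "groups.tsv",
        "map": "genetic_map.tsv", "gff3": "genes.gff3",
        "truth": "truth.json"}.items()}
    write_vcf(vt, paths["vcf"])
    write_sample_groups(groups, paths["groups"])
    write_genetic_map(gmap, paths["map"])
    write_gff3(genes, paths["gff3"], cfg.region_bp)
    with open(paths["truth"], "w") as fh:
        payload = {"config": asdict(cfg), "sweep": sweep}
        if truth is not None:
            payload.update(asdict(truth))
            payload["sweep_pos_bp"] = cfg.sweep_pos_bp
        json.dump(payload, fh, indent=1)
    return paths
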