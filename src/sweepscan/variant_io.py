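"""Readers/writers for VCF, GFF3/BED, sample-group and genetic-map TSVs.

In-memory containers for diploid genotypes (:class:`VariantTable`) and
phased haplotypes (:class:`HaplotypeMatrix`). All internal coordinates are
1-based inclusive (VCF/GFF3 native); BED is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1

GROUP_LABELS = ("two_teat", "multi_teat")


class VariantIOError(RuntimeError):
    """Fatal problem with an input file."""


@dataclass
class SampleSet:
    """Sample -> population-group assignment.

    Groups are the two phenotype classes contrasted by the scan
    (``two_teat`` reference vs ``multi_teat`` test population).
    """

    sample_id: list[str]
    group: list[str]

    def __post_init__(self) -> None:
        if len(set(self.sample_id)) != len(self.sample_id):
            raise ValueError("duplicate sample ids")
        bad = sorted(set(self.group) - set(GROUP_LABELS))
        if bad:
            raise ValueError(f"unknown group labels: {bad}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in zip(self.sample_id, self.group) if g == group]


@dataclass
class VariantTable:
    """Biallelic SNP genotypes for a set of samples.

    ``genotypes`` is (n_sites, n_samples, 2) int8 with allele codes
    0 (REF), 1 (ALT) and -1 (missing). ``phased`` is (n_sites, n_samples)
    bool. Sites are sorted by (chrom, pos), 1-based positions.
    """

    chrom: np.ndarray  # (M,) str
    pos: np.ndarray  # (M,) int64, 1-based
    ref: np.ndarray  # (M,) str single characters
    alt: np.ndarray  # (M,) str
    genotypes: np.ndarray  # (M, N, 2) int8
    phased: np.ndarray  # (M, N) bool
    samples: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take_sites(self, idx: np.ndarray) -> "VariantTable":
        return VariantTable(self.chrom[idx], self.pos[idx], self.ref[idx],
                            self.alt[idx], self.genotypes[idx],
                            self.phased[idx], list(self.samples))

    def take_samples(self, idx: np.ndarray) -> "VariantTable":
        idx = np.asarray(idx)
        return VariantTable(self.chrom, self.pos, self.ref, self.alt,
                            self.genotypes[:, idx], self.phased[:, idx],
                            [self.samples[i] for i in idx])

    def subset_samples(self, sample_ids: list[str]) -> "VariantTable":
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise VariantIOError(f"samples not in table: {missing}")
        return self.take_samples(np.array([lookup[s] for s in sample_ids]))


@dataclass
class HaplotypeMatrix:
    """2N x M phased binary haplotypes; 0 = ancestral-coded, 1 = derived.

    Rows 2i and 2i+1 are the two haplotypes of sample i; no missing
    entries. Physical positions are strictly increasing, map positions
    monotone non-decreasing.
    """

    alleles: np.ndarray  # (2N, M) uint8
    positions_bp: np.ndarray  # (M,) int64
    positions_cM: np.ndarray  # (M,) float64
    sample_of_hap: list[str]
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.alleles.shape[0] % 2:
            raise ValueError("odd haplotype count")
        if np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("positions_bp not strictly increasing")
        if np.any(np.diff(self.positions_cM) < 0):
            raise ValueError("positions_cM decreasing")

    @property
    def n_haps(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def derived_freq(self) -> np.ndarray:
        return self.alleles.mean(axis=0)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass
class GeneticMap:
    """Piecewise-linear bp -> cM map, one anchor list per chromosome."""

    anchors: dict[str, np.ndarray] = field(default_factory=dict)
    # anchors[chrom] is (k, 2) float array of (bp, cM), both strictly increasing

    def __post_init__(self) -> None:
        for chrom, a in self.anchors.items():
            a = np.asarray(a, dtype=float)
            if a.ndim != 2 or a.shape[1] != 2:
                raise ValueError(f"map for {chrom}: need (k,2) anchors")
            if np.any(np.diff(a[:, 0]) <= 0) or np.any(np.diff(a[:, 1]) <= 0):
                raise ValueError(f"map for {chrom}: anchors not increasing")
            self.anchors[chrom] = a

    def interpolate(self, chrom: str, bp: np.ndarray) -> np.ndarray:
        """cM positions by linear interpolation; extrapolation beyond the
        terminal anchors continues the terminal interval's slope."""
        bp = np.asarray(bp, dtype=float)
        a = self.anchors.get(chrom)
        if a is None:
            raise VariantIOError(f"no genetic map for chromosome {chrom}")
        x, y = a[:, 0], a[:, 1]
        if len(x) == 1:
            # single anchor: 1 cM/Mb fallback slope through it
            return y[0] + (bp - x[0]) * 1e-6
        cm = np.interp(bp, x, y)
        lo = bp < x[0]
        hi = bp > x[-1]
        if lo.any():
            slope = (y[1] - y[0]) / (x[1] - x[0])
            cm[lo] = y[0] + (bp[lo] - x[0]) * slope
        if hi.any():
            slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
            cm[hi] = y[-1] + (bp[hi] - x[-1]) * slope
        return cm


# ---------------------------------------------------------------------------
# readers


def read_vcf(path: str, sample_filter: list[str] | None = None) -> VariantTable:
    """Read biallelic SNPs from a VCF 4.x file.

    Multiallelic or non-SNP records are skipped with a logged count.
    Missing calls and per-call phase flags are preserved.
    """
    try:
        vcf = VCF(str(path), samples=sample_filter)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise VariantIOError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    chroms, poss, refs, alts, gts, phs = [], [], [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        g = rec.genotype.array()  # (N, 3): a0, a1, phased
        gts.append(g[:, :2].astype(np.int8))
        phs.append(g[:, 2].astype(bool))
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not poss:
        raise VariantIOError(f"empty input: no biallelic SNPs in {path}")
    vt = VariantTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=np.stack(gts),
        phased=np.stack(phs),
        samples=samples,
    )
    order = np.lexsort((vt.pos, vt.chrom.astype(str)))
    return vt.take_sites(order)


def write_vcf(vt: VariantTable, path: str) -> None:
    """Write a VariantTable as an uncompressed VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for chrom in dict.fromkeys(vt.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vt.samples) + "\n")
        for i in range(vt.n_sites):
            sep = np.where(vt.phased[i], "|", "/")
            a = vt.genotypes[i]
            calls = [
                f"{'.' if a[j, 0] < 0 else a[j, 0]}{sep[j]}"
                f"{'.' if a[j, 1] < 0 else a[j, 1]}"
                for j in range(vt.n_samples)
            ]
            fh.write(f"{vt.chrom[i]}\t{vt.pos[i]}\t.\t{vt.ref[i]}\t{vt.alt[i]}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def to_haplotypes(vt: VariantTable,
                  genetic_map: GeneticMap | None = None,
                  ancestral_policy: str = "ref_is_ancestral",
                  drop_incomplete: bool = False) -> dict[str, HaplotypeMatrix]:
    """Phased genotypes -> one HaplotypeMatrix per chromosome.

    Allele 0 is ancestral-coded: under ``ref_is_ancestral`` REF is
    ancestral; under ``major_is_ancestral`` the major allele is. Without a
    genetic map, map positions default to 1 cM/Mb from physical positions.

    Sites with any missing or unphased call are fatal unless
    ``drop_incomplete`` is set, in which case they are excluded (logged).
    """
    if ancestral_policy not in ("ref_is_ancestral", "major_is_ancestral"):
        raise ValueError(f"unknown ancestral_policy {ancestral_policy!r}")
    g = vt.genotypes
    bad = (g < 0).any(axis=(1, 2)) | ~vt.phased.all(axis=1)
    if bad.any():
        if not drop_incomplete:
            idx = np.flatnonzero(bad)[:10]
            locs = [f"{vt.chrom[i]}:{vt.pos[i]}" for i in idx]
            raise VariantIOError(
                f"{bad.sum()} sites with missing/unphased calls "
                f"(first: {locs}); pre-filter or pass drop_incomplete=True")
        logger.info("to_haplotypes: dropped %d missing/unphased sites", bad.sum())
        vt = vt.take_sites(~bad)
        g = vt.genotypes
    out: dict[str, HaplotypeMatrix] = {}
    sample_of_hap = [s for s in vt.samples for _ in range(2)]
    for chrom in dict.fromkeys(vt.chrom):
        sel = vt.chrom == chrom
        # (M, N, 2) -> (M, 2N) -> (2N, M); rows 2i, 2i+1 = sample i's haps
        alleles = g[sel].reshape(sel.sum(), -1).T.astype(np.uint8)
        if ancestral_policy == "major_is_ancestral":
            flip = alleles.mean(axis=0) > 0.5
            alleles = np.where(flip[None, :], 1 - alleles, alleles).astype(np.uint8)
        bp = vt.pos[sel]
        if genetic_map is not None:
            cm = genetic_map.interpolate(chrom, bp)
        else:
            cm = bp.astype(float) * 1e-6  # 1 cM/Mb fallback
        out[chrom] = HaplotypeMatrix(alleles, bp.copy(), cm, sample_of_hap, chrom)
    return out


def read_gene_annotation(path: str, fmt: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 (1-based inclusive) or BED4 (0-based
    half-open, converted). Returns an empty list for an empty file."""
    genes: list[GeneModel] = []
    if fmt == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise VariantIOError(f"{path}:{lineno}: need >=4 BED columns")
                try:
                    start0, end0 = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise VariantIOError(f"{path}:{lineno}: bad coordinates") from exc
                strand = parts[5] if len(parts) > 5 else "."
                genes.append(GeneModel(parts[3], parts[0], start0 + 1, end0, strand))
    elif fmt == "gff3":
        import gffutils

        try:
            db = gffutils.create_db(str(path), ":memory:", force=True,
                                    merge_strategy="create_unique",
                                    keep_order=True)
        except Exception as exc:
            raise VariantIOError(f"cannot parse GFF3 {path}: {exc}") from exc
        for feat in db.features_of_type("gene"):
            gid = (feat.attributes.get("ID") or feat.attributes.get("Name")
                   or [feat.id])[0]
            genes.append(GeneModel(gid, feat.seqid, feat.start, feat.end,
                                   feat.strand or "."))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise VariantIOError(f"duplicate gene ids in {path}")
    return genes


def read_sample_groups(path: str) -> SampleSet:
    """Read the two-column sample_id<TAB>group table."""
    ids, groups = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise VariantIOError(f"{path}:{lineno}: need sample_id<TAB>group")
            ids.append(parts[0])
            groups.append(parts[1])
    return SampleSet(ids, groups)


def read_genetic_map(path: str) -> GeneticMap:
    """Read a chrom<TAB>bp<TAB>cM anchor table."""
    per_chrom: dict[str, list[tuple[float, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "chrom\t")):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise VariantIOError(f"{path}:{lineno}: need chrom<TAB>bp<TAB>cM")
            per_chrom.setdefault(parts[0], []).append(
                (float(parts[1]), float(parts[2])))
    return GeneticMap({c: np.array(sorted(a)) for c, a in per_chrom.items()})


def write_sample_groups(sample_set: SampleSet, path: str) -> None:
    with open(path, "w") as fh:
        for s, g in zip(sample_set.sample_id, sample_set.group):
            fh.write(f"{s}\t{g}\n")


def write_genetic_map(gmap: GeneticMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tbp\tcM\n")
        for chrom, anchors in gmap.anchors.items():
            for bp, cm in anchors:
                fh.write(f"{chrom}\t{int(bp)}\t{cm:.8g}\n")
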