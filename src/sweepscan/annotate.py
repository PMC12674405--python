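"""Map selected windows/sites onto gene models and compute the four-way
intersection that yields the candidate-gene list.

Overlap is 1-based inclusive interval overlap, strand-ignored; gene
identity is the (case-normalized) gene_id. Window-level selections
annotate by window-interval overlap, site-level ones by point overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd
from intervaltree import IntervalTree

from .variant_io import GeneModel


class AnnotationError(RuntimeError):
    """Records and annotation disagree on chromosome naming."""


@dataclass
class VennSummary:
    set_sizes: dict[str, int]
    # membership pattern (sorted tuple of method names) -> exclusive size
    region_sizes: dict[tuple[str, ...], int]
    common_genes: list[str]  # sorted, present in all four sets

    @property
    def union_size(self) -> int:
        return sum(self.region_sizes.values())


def _gene_trees(genes: list[GeneModel], flank_bp: int
                ) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo = max(1, g.start - flank_bp)
        hi = g.end + flank_bp
        # intervaltree is half-open; +1 converts the inclusive end
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi + 1,
                                                       g.gene_id.upper())
    return trees


def map_to_genes(records: pd.DataFrame, genes: list[GeneModel],
                 flank_bp: int = 0) -> set[str]:
    """Gene ids whose (flanked) interval overlaps a selected record.

    ``records`` must carry ``chrom`` plus either ``pos`` (site records) or
    ``start``/``end`` (window records, 1-based inclusive).
    """
    if not genes or records.empty:
        return set()
    trees = _gene_trees(genes, flank_bp)
    rec_chroms = set(map(str, records["chrom"].unique()))
    if not rec_chroms & set(trees):
        raise AnnotationError(
            f"no shared chromosomes: records on {sorted(rec_chroms)}, "
            f"annotation on {sorted(trees)}")
    hits: set[str] = set()
    windowed = "start" in records.columns and "end" in records.columns
    for row in records.itertuples(index=False):
        tree = trees.get(str(row.chrom))
        if tree is None:
            continue
        if windowed:
            found = tree.overlap(int(row.start), int(row.end) + 1)
        else:
            found = tree.at(int(row.pos))
        hits.update(iv.data for iv in found)
    return hits


def intersect(gene_sets: dict[str, set[str]]) -> VennSummary:
    """All 15 intersection-region sizes and the common set of 4 named sets."""
    if len(gene_sets) != 4:
        raise ValueError(f"need exactly 4 named sets, got {len(gene_sets)}")
    methods = sorted(gene_sets)
    universe = set().union(*gene_sets.values())
    region_sizes: dict[tuple[str, ...], int] = {}
    for k in range(1, 5):
        for combo in combinations(methods, k):
            inside = set(universe)
            for m in combo:
                inside &= gene_sets[m]
            for m in methods:
                if m not in combo:
                    inside -= gene_sets[m]
            region_sizes[combo] = len(inside)
    common = sorted(set.intersection(*(gene_sets[m] for m in methods)))
    return VennSummary({m: len(gene_sets[m]) for m in methods},
                       region_sizes, common)


def candidate_gene_table(gene_sets: dict[str, set[str]],
                         genes: list[GeneModel],
                         best_stats: dict[str, dict[str, float]] | None = None
                         ) -> pd.DataFrame:
    """One row per gene in the union: coordinates, per-method membership
    flags, and (optionally) each method's best statistic at the gene."""
    union = set().union(*gene_sets.values())
    coords = {g.gene_id.upper(): g for g in genes}
    rows = []
    for gid in sorted(union):
        g = coords.get(gid)
        row = {"gene_id": gid,
               "chrom": g.chrom if g else ".",
               "start": g.start if g else 0,
               "end": g.end if g else 0}
        for m in sorted(gene_sets):
            row[f"in_{m}"] = gid in gene_sets[m]
        if best_stats:
            for m, table in sorted(best_stats.items()):
                row[f"best_{m}"] = table.get(gid, float("nan"))
        row["n_methods"] = sum(gid in s for s in gene_sets.values())
        rows.append(row)
    return pd.DataFrame(rows)


def venn_to_frame(v: VennSummary) -> pd.DataFrame:
    rows = [{"region": "+".join(combo), "size": n}
            for combo, n in sorted(v.region_sizes.items(),
                                   key=lambda kv: (len(kv[0]), kv[0]))]
    rows.append({"region": "union", "size": v.union_size})
    rows.append({"region": "common", "size": len(v.common_genes)})
    return pd.DataFrame(rows)
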