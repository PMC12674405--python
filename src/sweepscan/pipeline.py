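"""End-to-end orchestration: QC -> four statistics -> tail selection ->
gene annotation -> four-way intersection, from one config.

`run_scan` is the in-memory core (haplotype matrices in, ScanResults and
Venn summary out); `run` wraps it with file I/O, logging and a manifest
so the whole scan is reproducible from a single seed/config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import classic_stats as cs
from . import haplotype_stats as hs
from .qc import QcConfig, run_qc
from .scan_select import ScanResult, make_scan_result
from .variant_io import (GeneModel, GeneticMap, HaplotypeMatrix,
                         read_gene_annotation, read_genetic_map, read_sample_groups,
                         read_vcf, to_haplotypes, write_vcf)

logger = logging.getLogger(__name__)

TSV_FLOAT = "%.10g"


@dataclass
class PipelineConfig:
    """All knobs of the scan; defaults are the study's printed parameters
    (50 kb / 12.5 kb Fst windows, 500 kb / 50 kb pi windows, 5% tails,
    chip-QC thresholds)."""

    vcf: str = ""
    groups: str = ""
    annotation: str = ""
    annotation_format: str = "gff3"
    genetic_map: str | None = None
    outdir: str = "sweepscan_run"
    seed: int = 0
    qc: QcConfig = field(default_factory=QcConfig)
    fst_window_bp: int = cs.FST_WINDOW_BP
    fst_step_bp: int = cs.FST_STEP_BP
    fst_mode: str = "weighted"
    pi_window_bp: int = cs.PI_WINDOW_BP
    pi_step_bp: int = cs.PI_STEP_BP
    pi_tail: str = "upper"  # "lower" selects diversity troughs instead
    fraction: float = 0.05
    ancestral_policy: str = "ref_is_ancestral"
    limehh: float = hs.LIMEHH
    maxgap_bp: int = hs.MAXGAP_BP
    ihs_min_maf: float = hs.MIN_MAF
    freq_bin: float = hs.FREQ_BIN
    flank_bp: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunResult:
    scans: dict[str, ScanResult]
    gene_sets: dict[str, set[str]]
    venn: ann.VennSummary
    candidates: pd.DataFrame
    outdir: str | None = None
    manifest: dict | None = None


def _genotype_counts_from_hap(hap: HaplotypeMatrix) -> np.ndarray:
    """(M, 3) hom-ref/het/hom-alt counts from phased haplotype pairs."""
    dose = hap.alleles[0::2].astype(np.int64) + hap.alleles[1::2]
    return np.stack([(dose == k).sum(axis=0) for k in range(3)], axis=1)


def fst_table(hap1: HaplotypeMatrix, hap2: HaplotypeMatrix,
              window_bp: int, step_bp: int, mode: str) -> tuple[pd.DataFrame,
                                                                pd.DataFrame]:
    """Per-site components and windowed Fst for one chromosome."""
    c1 = _genotype_counts_from_hap(hap1)
    c2 = _genotype_counts_from_hap(hap2)
    comps = [cs.fst_site_components(c1[j], c2[j]) for j in range(hap1.n_sites)]
    sites = pd.DataFrame({
        "chrom": hap1.chrom, "pos": hap1.positions_bp,
        "num": [c.num for c in comps], "den": [c.den for c in comps],
        "fst": [c.fst_site for c in comps]})
    wins = cs.fst_windowed(hap1.positions_bp, comps, window_bp, step_bp,
                           mode, hap1.chrom)
    wdf = pd.DataFrame([asdict(w) for w in wins])
    return sites, wdf


def pi_table(hap: HaplotypeMatrix, window_bp: int, step_bp: int
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = hap.n_haps
    k = hap.alleles.sum(axis=0)
    pis = 2.0 * k * (n - k) / (n * (n - 1))
    sites = pd.DataFrame({"chrom": hap.chrom, "pos": hap.positions_bp,
                          "pi": pis})
    wins = cs.pi_windowed(hap.positions_bp, pis, window_bp, step_bp, hap.chrom)
    return sites, pd.DataFrame([asdict(w) for w in wins])


def run_scan(haps_ref: dict[str, HaplotypeMatrix],
             haps_test: dict[str, HaplotypeMatrix],
             genes: list[GeneModel],
             cfg: PipelineConfig | None = None) -> RunResult:
    """The four statistics, tail selection, annotation and intersection,
    from per-chromosome haplotype matrices of the two groups.

    Fst and pi are selected at window level (pi within the test group);
    iHS (test group) and xpEHH (reference vs test) at site level on
    absolute values. iHS/xpEHH standardization pools all chromosomes.
    """
    cfg = cfg or PipelineConfig()
    chroms = sorted(haps_ref, key=str)
    if set(haps_ref) != set(haps_test):
        raise ValueError("reference/test chromosome sets differ")

    fst_w, pi_w, ihs_parts, xp_parts = [], [], [], []
    for c in chroms:
        _, fw = fst_table(haps_ref[c], haps_test[c], cfg.fst_window_bp,
                          cfg.fst_step_bp, cfg.fst_mode)
        fst_w.append(fw)
        _, pw = pi_table(haps_test[c], cfg.pi_window_bp, cfg.pi_step_bp)
        pi_w.append(pw)
        ihs_parts.append(hs.ihs_scan(haps_test[c], cfg.ihs_min_maf,
                                     cfg.freq_bin, cfg.limehh, cfg.maxgap_bp,
                                     standardize=False))
        xp_parts.append(hs.xpehh_scan(haps_ref[c], haps_test[c], cfg.limehh,
                                      cfg.maxgap_bp, standardize=False))
    fst_df = pd.concat(fst_w, ignore_index=True).rename(columns={"value": "fst"})
    pi_df = pd.concat(pi_w, ignore_index=True).rename(columns={"value": "pi"})
    ihs_df = pd.concat(ihs_parts, ignore_index=True)
    xp_df = pd.concat(xp_parts, ignore_index=True)
    if len(ihs_df):
        ihs_df["ihs"] = hs.standardize_by_bin(ihs_df["unihs"].to_numpy(),
                                              ihs_df["ps"].to_numpy(),
                                              cfg.freq_bin)
    un = xp_df["unxpehh"].to_numpy()
    ok = np.isfinite(un)
    x = np.full_like(un, np.nan)
    if ok.sum() >= 2 and un[ok].std() > 0:
        x[ok] = (un[ok] - un[ok].mean()) / un[ok].std()
    xp_df["xpehh"] = x

    # windows with no SNPs never enter the quantile
    fst_sel = fst_df.copy()
    fst_sel.loc[fst_sel["n_snps"] == 0, "fst"] = np.nan
    pi_sel = pi_df.copy()
    pi_sel.loc[pi_sel["n_snps"] == 0, "pi"] = np.nan

    scans = {
        "fst": make_scan_result("fst", fst_sel, "fst", "upper", cfg.fraction),
        "pi": make_scan_result("pi", pi_sel, "pi", cfg.pi_tail, cfg.fraction),
        "ihs": make_scan_result("ihs", ihs_df, "ihs", "abs_upper",
                                cfg.fraction),
        "xpehh": make_scan_result("xpehh", xp_df, "xpehh", "abs_upper",
                                  cfg.fraction),
    }
    gene_sets = {m: ann.map_to_genes(sr.selected, genes, cfg.flank_bp)
                 if len(sr.selected) and genes else set()
                 for m, sr in scans.items()}
    for m, sr in scans.items():
        sr.gene_set = gene_sets[m]
    venn = ann.intersect(gene_sets)
    best = _best_stats_per_gene(scans, genes, cfg.flank_bp)
    candidates = ann.candidate_gene_table(gene_sets, genes, best)
    return RunResult(scans, gene_sets, venn, candidates)


def _best_stats_per_gene(scans: dict[str, ScanResult], genes: list[GeneModel],
                         flank_bp: int) -> dict[str, dict[str, float]]:
    """Per method, the most extreme statistic among records overlapping
    each gene (the candidate-table shape)."""
    value_col = {"fst": "fst", "pi": "pi", "ihs": "ihs", "xpehh": "xpehh"}
    out: dict[str, dict[str, float]] = {}
    for m, sr in scans.items():
        rec = sr.records
        table: dict[str, float] = {}
        for g in genes:
            lo, hi = g.start - flank_bp, g.end + flank_bp
            on = rec[rec["chrom"].astype(str) == g.chrom]
            if "pos" in on.columns and "start" not in on.columns:
                hit = on[(on["pos"] >= lo) & (on["pos"] <= hi)]
            else:
                hit = on[(on["end"] >= lo) & (on["start"] <= hi)]
            vals = hit[value_col[m]].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size:
                if sr.tail == "lower":
                    table[g.gene_id.upper()] = float(vals.min())
                elif sr.tail == "abs_upper":
                    table[g.gene_id.upper()] = float(vals[np.abs(vals).argmax()])
                else:
                    table[g.gene_id.upper()] = float(vals.max())
        out[m] = table
    return out


def export_manhattan(records: pd.DataFrame, threshold: float,
                     value_col: str) -> pd.DataFrame:
    """Plot-data table: chromosome-cumulative x, value, selected flag and
    the threshold line value, one row per defined record."""
    rec = records.copy()
    if "pos" not in rec.columns:
        rec["pos"] = (rec["start"] + rec["end"]) // 2  # window midpoints
    rec = rec[np.isfinite(rec[value_col].to_numpy(dtype=float))]
    offset = 0
    cum = np.empty(len(rec), dtype=np.int64)
    pieces = []
    for c in dict.fromkeys(rec["chrom"]):
        sub = rec[rec["chrom"] == c]
        pieces.append(sub["pos"].to_numpy() + offset)
        offset += int(sub["pos"].max())
    if pieces:
        cum = np.concatenate(pieces)
    rec = rec.assign(cum_pos=cum, threshold=threshold)
    cols = ["chrom", "pos", "cum_pos", value_col, "selected", "threshold"]
    return rec[[c for c in cols if c in rec.columns]]


def plot_manhattan(manhattan: pd.DataFrame, value_col: str, path: str) -> None:
    """Optional image companion to the plot-data table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    for i, c in enumerate(dict.fromkeys(manhattan["chrom"])):
        sub = manhattan[manhattan["chrom"] == c]
        ax.scatter(sub["cum_pos"], sub[value_col], s=4,
                   color=["#3b5ba5", "#e8743b"][i % 2])
    thr = manhattan["threshold"].iloc[0] if len(manhattan) else np.nan
    if np.isfinite(thr):
        ax.axhline(thr, color="red", lw=0.8)
    ax.set_xlabel("cumulative position (bp)")
    ax.set_ylabel(value_col)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# file-level run


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=TSV_FLOAT)


def run(cfg: PipelineConfig) -> RunResult:
    """File-level pipeline: read inputs, QC, scan, write every artifact.

    Emits into cfg.outdir: qc_report.tsv, filtered.vcf, four statistic
    TSVs, four selection TSVs, thresholds.tsv, candidate_genes.tsv,
    venn.tsv, four Manhattan data TSVs, and manifest.json. On a stage
    failure a FAILED marker naming the stage is left in the run directory.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read-inputs"
    try:
        vt = read_vcf(cfg.vcf)
        groups = read_sample_groups(cfg.groups)
        genes = read_gene_annotation(cfg.annotation, cfg.annotation_format) \
            if cfg.annotation else []
        gmap: GeneticMap | None = (read_genetic_map(cfg.genetic_map)
                                   if cfg.genetic_map else None)

        stage = "qc"
        vt = vt.subset_samples(groups.sample_id)
        vt_qc, report = run_qc(vt, cfg.qc)
        report.to_tsv(out / "qc_report.tsv")
        write_vcf(vt_qc, out / "filtered.vcf")

        stage = "haplotypes"
        kept = set(vt_qc.samples)
        ref_ids = [s for s in groups.samples_in("two_teat") if s in kept]
        test_ids = [s for s in groups.samples_in("multi_teat") if s in kept]
        haps_ref = to_haplotypes(vt_qc.subset_samples(ref_ids), gmap,
                                 cfg.ancestral_policy, drop_incomplete=True)
        haps_test = to_haplotypes(vt_qc.subset_samples(test_ids), gmap,
                                  cfg.ancestral_policy, drop_incomplete=True)

        stage = "scan"
        result = run_scan(haps_ref, haps_test, genes, cfg)

        stage = "write-outputs"
        value_col = {"fst": "fst", "pi": "pi", "ihs": "ihs", "xpehh": "xpehh"}
        thr_rows = []
        for m, sr in result.scans.items():
            _write_tsv(sr.records, out / f"{m}.tsv")
            _write_tsv(sr.selected, out / f"{m}_selected.tsv")
            man = export_manhattan(sr.records, sr.threshold, value_col[m])
            _write_tsv(man, out / f"manhattan_{m}.tsv")
            thr_rows.append({"method": m, "tail": sr.tail,
                             "fraction": sr.fraction,
                             "threshold": sr.threshold,
                             "n_selected": len(sr.selected),
                             "n_records": len(sr.records)})
        _write_tsv(pd.DataFrame(thr_rows), out / "thresholds.tsv")
        _write_tsv(result.candidates, out / "candidate_genes.tsv")
        _write_tsv(ann.venn_to_frame(result.venn), out / "venn.tsv")

        stage = "manifest"
        inputs = {k: _sha256(p) for k, p in
                  [("vcf", cfg.vcf), ("groups", cfg.groups)] if p}
        if cfg.annotation:
            inputs["annotation"] = _sha256(cfg.annotation)
        if cfg.genetic_map:
            inputs["genetic_map"] = _sha256(cfg.genetic_map)
        outputs = {p.name: _sha256(str(p)) for p in sorted(out.glob("*.tsv"))}
        from . import __version__
        manifest = {"config": cfg.to_dict(), "seed": cfg.seed,
                    "input_sha256": inputs, "output_sha256": outputs,
                    "version": __version__}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        result.outdir = str(out)
        result.manifest = manifest
        return result
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise
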