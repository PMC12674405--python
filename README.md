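# sweepscan

A reusable pipeline for the four-statistic genome-wide selection scan used
to nominate candidate genes for the multi-teat trait in Hu sheep: chip-style
QC filtering, Weir–Cockerham **Fst** and windowed nucleotide diversity
(**π**) alongside the haplotype-length statistics **iHS** and **xpEHH**,
top-5% empirical-tail selection, gene annotation, and the four-way
intersection that yields the candidate-gene list. A built-in two-population
sweep simulator makes every stage runnable and testable at desk scale with
no downloads.

It is aimed at population-genetics practitioners who have phased diploid
genotypes in VCF, a two-column sample→group table (`two_teat` /
`multi_teat`), and gene models in GFF3 or BED.

## The statistics

For two populations with genotype counts per biallelic site, the
Weir–Cockerham variance components a (between populations), b (between
individuals within populations) and c (within individuals) give

    Fst = a / (a + b + c),

computed here by the nested analysis of variance on allele indicators and
aggregated over sliding windows (50 kb window, 12.5 kb step by default) as
a ratio of sums ("weighted" Fst). Per-site diversity is the average
pairwise difference π = 2k(n−k)/(n(n−1)) for k derived alleles among n
haplotypes, summed over 500 kb windows (50 kb step) and divided by window
length.

Extended haplotype homozygosity EHH(x) is the probability that two random
carrier haplotypes of a core allele are identical from the core out to
distance x. Integrating EHH over genetic distance gives iHH per core
allele, and

    uniHS = ln(iHH_A / iHH_D),      iHS = standardize(uniHS | p_s)

standardized within derived-allele-frequency bins. Pooling all haplotypes
of one population gives iES, and the cross-population contrast

    unxpEHH = ln(iES_ref / iES_test),   xpEHH = genome-wide standardize

flags sweeps at or near fixation in one population. Candidates are the top
5% tails: upper for Fst, absolute-value upper for iHS and xpEHH, and a
configurable direction for π (a sweep depresses diversity, so the lower
tail marks troughs). Genes overlapping selected windows/sites feed a
four-way Venn intersection.

## Worked example

Simulate a dataset at the study's scale (76 + 81 diploids, 2,000 SNPs on a
5 Mb region, hard sweep at 2.5 Mb reaching 80% of test-population
haplotypes), then run the whole scan with π windows scaled to the region:

```
sweepscan simulate --outdir data --seed 7
printf 'pi_tail: lower\npi_window_bp: 100000\npi_step_bp: 10000\n' > scan.yaml
sweepscan run-all --config scan.yaml \
    --vcf data/genotypes.vcf --groups data/groups.tsv \
    --annotation data/genes.gff3 --genetic-map data/genetic_map.tsv \
    --outdir run
```

which prints

```
run directory: run
fst: threshold 0.141557, 20 selected, 4 genes
pi: threshold 3.83992e-05, 25 selected, 7 genes
ihs: threshold 2.41413, 58 selected, 14 genes
xpehh: threshold 2.58677, 98 selected, 4 genes
four-way overlap: 4 genes
```

Each line is one statistic's empirical 5% threshold, how many
windows/sites lie beyond it, and how many genes those regions annotate to;
the final line is the size of the four-way intersection. The planted sweep
gene (`G025`, spanning the core at 2.5 Mb — see `data/truth.json`) is
recovered in all four sets; `run/candidate_genes.tsv` shows its row with
membership flags and each method's most extreme statistic at the gene:

```
gene_id chrom start    end      in_fst in_ihs in_pi in_xpehh best_fst best_ihs best_pi     best_xpehh n_methods
G025    1     2460000  2540000  True   True   True  True     0.241    4.39     2.64e-05    -4.23      4
```

The run directory also contains per-statistic TSVs, per-method Manhattan
plot data (`sweepscan manhattan --run-dir run --method fst --image fst.png`),
a QC report, the filtered VCF, the Venn summary, and a `manifest.json`
with config, seed and input/output hashes — two runs with the same config
and inputs are byte-identical.

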