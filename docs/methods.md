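# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, the synthetic-data generator's scope, and the
numerical conventions that determine exactly which loci come out of the
scan.

## QC model

Five chip-style criteria, applied as strict inequalities: sites without a
chromosome/position; site missingness > 0.1; minor allele frequency
< 0.01 (computed from called alleles only); individual genotyping rate
< 0.90; exact Hardy–Weinberg p < 1e-5. Individuals are filtered first,
then sites, each site charged to the first criterion it fails, so the QC
report's removal counts sum exactly to the input/output difference.

The Hardy–Weinberg test is the standard exact test: conditional on the
observed allele counts, the probability of every heterozygote count with
the right parity is computed in log-gamma form and the two-sided p-value
sums all configurations whose probability does not exceed the observed one
(no mid-p). Monomorphic sites return p = 1 by convention. The test is
evaluated on all samples pooled; per-group testing is a config switch.

## Fst

The two-population Weir–Cockerham estimator, computed as a nested analysis
of variance on the 0/1 allele indicator with three strata — populations,
individuals within populations, gametes within individuals. The mean
squares yield the familiar components a, b, c, with c equal to half the
observed heterozygosity; per site the numerator a and denominator a+b+c
are retained so windows can be aggregated as a ratio of sums (weighted
Fst, the default) or as a mean of defined per-site ratios. Negative
per-site values are retained for aggregation — clamping to zero would bias
window scores upward. Because a+b+c is a sum of non-negative mean squares
rearranged, the per-site estimate never exceeds 1 and equals 1 exactly only
for a fixed difference. Sites monomorphic for the same allele in both
groups have zero denominator and are flagged undefined.

## Nucleotide diversity

Per site π = 2k(n−k)/(n(n−1)) over called haplotypes (haplotype counts
when phased data are available, genotype-derived otherwise); the window
value is the sum of per-site π divided by the full window length, so
monomorphic positions contribute implicitly and adding monomorphic sites
never changes a window.

## Windows

Windows lie on a step-aligned grid anchored at coordinate 1; every window
overlapping the observed SNP span is emitted, so an interior SNP appears
in exactly window/step windows. Windows with no SNPs are emitted (value
NaN for Fst, 0 for π) but never enter the tail quantile. Windows at the
edges of the covered span are partially unobserved and can carry diluted
π; at genome scale these are a negligible fraction, at desk scale the
experiment configuration keeps the window small relative to the region
(see below).

## EHH-family statistics

EHH at distance x from the core is Σ_g C(n_g,2)/C(n,2) over groups of
carriers identical from the core to x. Profiles start at (0 cM, 1) and
extend site by site until the chromosome edge, the first point below
`limehh` (kept, so the trapezoid closes), or an inter-SNP gap above
`maxgap_bp`; which condition stopped the walk is recorded. Defaults
`limehh = 0.05` and `maxgap_bp = 200 kb` are the conventional EHH-scan
settings. Integration is trapezoidal over genetic distance; without a map,
physical positions are converted at 1 cM/Mb, and a supplied anchor map is
interpolated linearly with terminal-slope extrapolation.

iHS scans every core with derived frequency in [0.05, 0.95] (standardization
is unstable beyond; configurable). uniHS = ln(iHH_A/iHH_D) is standardized
within derived-frequency bins of width 0.05; bins with fewer than 10
defined records merge with their nearest neighbour, and a bin whose
spread is zero after merging yields undefined scores rather than
infinities. By construction every bin — hence the pooled set — has mean 0
and standard deviation 1 (population sd).

For xpEHH, the pooled profile uses all haplotypes of one population and is
anchored at 1 at the core: the core allele itself does not partition
haplotypes, so the statistic measures flanking haplotype length only. This
convention makes two exact identities hold: identical populations give
unxpEHH ≡ 0, and swapping reference and test negates every value. Both
populations share one truncation point per side — extension continues
until both profiles fall below `limehh` (or edge/gap) — and
unxpEHH = ln(iES_ref/iES_test) is standardized genome-wide (per-bin
standardization is available as an option). The reference population is
always the numerator; the orientation is recorded in the output.

## Tail selection

Thresholds are empirical quantiles with the linear-interpolation
definition; the selected set is every defined record at or beyond the
threshold (ties included — deterministic and slightly conservative).
Undefined records never enter the quantile or the selection. Fst selects
the upper tail of window values, iHS and xpEHH the upper tail of absolute
site values. For π the direction is a config flag: `upper` is the default
for parity with top-tail reporting conventions, while `lower` selects
diversity troughs, which is what a sweep produces; the sweep-recovery
experiment uses `lower`. With all-identical values the selection is empty
(a threshold that selects everything is useless), with a warning.

## Annotation and intersection

A gene is annotated to a method if its (optionally flanked) 1-based
inclusive interval overlaps a selected site position or window interval;
strand is ignored and gene identity is the case-normalized gene id. The
Venn summary reports all 15 exclusive region sizes (they sum to the union
by construction) and the sorted common set of the four methods.

## The synthetic-data generator

The generator is a haplotype-copying model, not a population-genetic
simulator. It emulates exactly the features the scan responds to:

- a chip-like frequency spectrum (density ∝ 1/p truncated at
  `maf_floor = 0.01`, enforced on the pooled sample);
- background differentiation: each population's site frequency is a Beta
  perturbation of the ancestral frequency with variance
  `fst_background`·p(1−p) (default 0.02, the parameter the Fst scan should
  recover);
- local LD: haplotypes are mosaics block-copied from a per-population
  founder panel (200 founders; switches at scale `ld_scale_cM = 0.05`).
  A finite panel adds roughly 1/200 ≈ 0.005 of apparent drift on top of
  `fst_background`, visible in the calibration results;
- a hard sweep: a fraction `sweep_freq = 0.8` of test-population
  haplotypes is overwritten with one template over contiguous spans whose
  left/right extents are exponential with mean `decay_cM = 0.3`, so the
  probability a swept haplotype still matches the template at distance d
  is exp(−d/decay) while haplotypes stay contiguous (long shared
  haplotypes, a frequency shift, and a diversity trough around the core).

Default sizes mirror the study design: 76 reference and 81 test diploids,
2,000 SNPs on 5 Mb, sweep at 2.5 Mb. All randomness flows from one seed
through one generator; emitted datasets (VCF, group TSV, map TSV, toy
GFF3 with ~50 genes of which exactly one spans the core, truth JSON)
round-trip exactly through the readers.

What it does not emulate: demography, recombination-map heterogeneity,
soft sweeps, background selection, genotyping error. Passing tests
therefore show that the statistics detect the canonical sweep signature
and agree with their definitions — not that the pipeline's power on real
livestock data matches any particular study.

## Desk-scale experiment configuration

The recovery and calibration experiments run 20 replicate seeds at the
default generator configuration. Pipeline defaults keep the production
window sizes (Fst 50 kb/12.5 kb, π 500 kb/50 kb); the recovery experiment
scales the π window to 100 kb/10 kb because a 500 kb window is 10% of the
simulated region and dilutes the trough (the Fst windows are already small
relative to the region and stay at their defaults). Neutral calibration
compares the |iHS| > 2 fraction to 2Φ(−2) with a Monte-Carlo tolerance of
max(3×SE across seeds, 0.01), and requires the genome-wide weighted Fst to
recover `fst_background` within ±50%.

## Known limitations

- Within-bin iHS standardization loses power when a large fraction of a
  frequency bin is itself swept — at desk scale (~10% of the 5 Mb region
  swept) the core site's standardized score typically lands near but below
  the top-5% cut even though its raw |uniHS| is extreme; at genome scale
  the bins are overwhelmingly neutral and this vanishes. Gene-level
  recovery (selected sites anywhere in the gene) is the robust desk-scale
  readout and is what the recovery experiment measures.
- π windows partially outside the covered span are diluted; at desk scale
  this can place edge windows in the lower tail alongside genuine troughs.
- The EHH kernel is straightforward vectorized Python; it scans thousands
  of sites per second at chip densities but is not engineered for
  whole-genome sequence data.
- Sites with missing or unphased calls are excluded from haplotype
  construction, not imputed.
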