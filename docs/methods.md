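# Methods

`seedmethylome` re-implements, as a tested library and CLI, a whole-genome
bisulfite analysis workflow for a two-tissue plant seed (embryo vs
endosperm): context-resolved fractional methylation, 50-bp window DMR
calling, feature-anchored metagene profiling, 7-mer local-sequence
preference analysis, sRNA positional accumulation, and expression-stratified
integration.  Because the original genome-scale inputs (a maize B73
methylome at ~10x per-strand depth) are not desk-reproducible, the package
ships a seeded synthetic-data generator whose planted effects give every
stage a ground truth; all quantitative claims made by the tests and the
acceptance script are computed on that generator's output.

## Methylation model

Every cytosine is classified by the two bases downstream in its strand's
5'→3' direction: CG, CHG or CHH (H ∈ {A, C, T}).  A site whose 2-base
downstream window leaves the contig or contains a non-ACGT base has no
defined context and is excluded from all statistics (one deliberate
consequence: a CG dinucleotide within 2 bp of a contig end contributes a
record on only one strand).  Coordinates are 0-based half-open everywhere;
GFF3 is converted on read and BED/bedGraph conventions are used on write.

Per-site fractional methylation is #C/(#C+#T) over deduplicated reads;
sites are retained when covered by at least `min_reads` (default 10,
inclusive) reads.  The bulk frequency of a context is read-weighted,
Σ#C / Σ(#C+#T) — the literal per-site formula applied to pooled counts —
with the unweighted mean of site fractions available as `method="site"`.
Which of the two the original analysis used is not documented; both are
provided and the read-weighted form is the default.  The "3 SE" recovery
checks compare the read-weighted estimator to the planted compartment mean
using a cluster-robust (per-site sandwich) standard error,
SE = sqrt(Σᵢ (mᵢ − cᵢp̂)²)/Σᵢ cᵢ: with bimodal site states the naive
binomial read SE would understate the estimator's sampling variance.

The 20%-bin methylation distribution uses bins [0,20), [20,40), [40,60),
[60,80), [80,100] over percent methylation of methylated sites
(n_meth > 0); boundary values fall deterministically into the right-hand
bin and 100% into the closed last bin.

## DMR calling

Each context and strand is tiled independently with 50-bp windows
(non-overlapping by default; `step` < `window_size` gives a sliding
tiling).  Windows report both the pooled fraction Σ#C/Σ(#C+#T) and the
equal-site-weight fraction (mean of per-site fractions over covered
sites).  A window is a DMR when, in both samples, pooled coverage ≥ 10,
covered sites ≥ 3, |embryo − endosperm| ≥ `min_delta` (default 0.2), and a
two-proportion Fisher exact test on the pooled counts survives
Benjamini–Hochberg FDR control at 0.05 over the delta-passing candidates.

Three of these defaults deserve justification, because a bare pooled
subtraction looks simpler:

* **Equal site weighting for the delta.**  Plant CG/CHG methylation is
  site-bimodal (a cytosine is either heavily methylated or essentially
  not).  In a window mixing both states, the read-pooled fraction depends
  on how coverage happens to distribute over the sites; at 10x depth this
  coverage-composition term inflates the null |Δ| tail by roughly two
  orders of magnitude (measured ~11% of null mixed windows exceed
  |Δ| = 0.2).  Weighting sites equally cancels the composition term while
  leaving a homogeneous planted signal unbiased.  `delta_mode="pooled"`
  restores the literal subtraction.
* **≥ 3 covered sites per window.**  One noisy cytosine should not make a
  region; windows carried by a single 10-read site cross |Δ| = 0.2 with a
  2-read fluctuation (~7% of the time).
* **Fisher + BH on by default.**  Even with the two rules above, an
  effect-size cutoff alone admits ~10⁻³ of null windows, which at
  genome scale swamps a realistic number of true DMRs.  Requiring the
  candidate also to show more evidence than read sampling explains brings
  the measured false-discovery rate on synthetic data to ≤ 5% while
  keeping recall of planted Δ = 0.5 windows ≥ 0.99.

No merging of adjacent windows is done by default (the published
bp-per-locus accounting is consistent with unmerged 50-bp loci); a
`merge_adjacent` post-processing step exists.  Summaries count DMRs, bp
and percent hyper-methylated-in-embryo per context and strand, the
percentage rounded to two decimals.

## Metagene profiles

Sites are assigned strand-oriented offsets from a feature's 5' or 3' end:
offset 0 is the anchor base, negative offsets lie outside the feature,
positive offsets run inward, clipped at the feature's own length (no
percent-of-length scaling).  For − strand features the orientation is the
exact mirror of + strand (the first feature base is offset 0 on both
strands; this is the unique convention consistent with a
reverse-complement strand flip).  Offsets are binned at 50 nt from −2 kb
to +4 kb (120 bins); the per-bin value is the unweighted mean of per-site
fractions over all (site, feature) pairs — a site under two overlapping
features counts once per feature — with a read-pooled mode as an option.
Features with undefined strand are profiled as + strand (a flag drops
them instead).

## 7-mer preferences

Each covered cytosine is labelled with its strand-oriented 7-mer (2 bases
upstream, C at index 2, 4 downstream); windows touching contig ends or
non-ACGT bases are excluded.  Per-7-mer statistics are means of site
fractions (read-pooled mode available); 7-mers with fewer than 10 sites
are omitted from the k-mer table but still feed the position × base
marginal table (positions −2, −1, +1, +2, +3, +4), whose cells are means
over all sites carrying that base at that position.

## sRNA accumulation and expression

sRNA alignments (BED6, length = interval length) are stratified by length
(21–24 nt; other lengths retained but flagged).  Each read is located at
its strand-oriented 5' end (midpoint optional), assigned offsets exactly
as methylation sites are, and accumulated in 100-nt bins over −2 kb..+4 kb;
bin values are percentages of the total mapped sRNA reads of all lengths
(a per-length denominator is an option).  Multi-mapping weights are not
modelled; reads are taken as uniquely placed.

Expression is RPKM = 10⁹ · reads / (length · library size), classified
into five levels: 1 (RPKM = 0), 2 ((0,1]), 3 ((1,10]), 4 ((10,100]),
5 (> 100).  Only the 0, <1 and >100 boundaries are anchored by the
original study; the interior edges are log-decadal and configurable.

## Integration

Stratified profiles partition features by expression class and compute one
profile per class with a shared normaliser; classes with fewer than 30
features are flagged as sparse, never dropped.  The methylation–sRNA
association is Spearman's ρ between the two tracks on a common 100-nt
grid (methylation bins pair-averaged, site-weighted) over a chosen offset
region (default the 2-kb upstream window), with a seeded bin-label
permutation p-value (default 10,000 reps, one-sided for positive
association).  CHH islands are contiguous runs of ≥ 2 upstream bins whose
mean exceeds 2× the median of the defined upstream bins; both the
enrichment factor and width are exposed, since no operational definition
of an island is documented in the source analysis.

## Synthetic data generator

The generator is count-level (the pipeline consumes call tables, so
read-level simulation would test nothing extra).  Defaults define the
study conditions:

* **Genome**: 1 Mb, 46% GC, single contig; 60 protein-coding genes, 20
  pseudogenes, 40 TEs, 40 repeats, placed non-overlapping with ≥ 2-kb
  flanks, random strands.
* **Site states**: CG and CHG sites are bimodal — methylated state 0.95,
  unmethylated 0.02 — with the compartment's target mean setting the
  state probability (gene body CG 0.60 / CHG 0.20; TE and repeat 0.90 /
  0.70; pseudogene 0.75 / 0.45; intergenic 0.80 / 0.50).  CHH rates are
  uniform and low (gene 0.05, TE/repeat 0.10, pseudogene 0.075,
  intergenic 0.02).  Intergenic levels are the package's own choice
  (repeat-rich maize intergenic space is heavily CG/CHG methylated).
* **Tissue effect**: endosperm rates are the embryo rates × 1.0 (CG),
  0.85 (CHG), 0.70 (CHH) — site states are shared between tissues, so CG
  differences are pure noise.
* **CHH islands**: two intervals upstream of every gene, strand-oriented
  offsets (−1500,−1300) and (−400,−200), CHH rate 0.25.
* **Sequence preference**: CHH rates are multiplied by a per-base factor
  at +1 and +2 (A 2.0, C 1.0, T 1.0), normalised by its expectation under
  the genome's base composition so compartment means are preserved; the
  planted CAH/CCH marginal ratio is exactly 2.
* **TSS openness**: each gene draws a factor in [0.2, 1.5] applied within
  ±300 bp of the TSS — to the methylated-state probability for CG/CHG
  (sites stay bimodal, as at real plant TSSs) and to the rate for CHH.
  Expression classes are then assigned by ranking genes on their true
  TSS-region methylation (lowest methylation → class 5), which plants the
  inverse TSS-methylation/expression relation in all three contexts.
* **DMRs**: 100 grid-aligned 50-bp CG windows with ≥ 3 CG sites per
  strand, outside TSS/island regions; site rates set to 0.95 vs 0.45
  (Δ = 0.5), direction random per window.
* **Reads**: per-site coverage ~ Poisson(10) per tissue, methylated counts
  binomial at the site's true rate; zero-coverage sites are absent from
  the call table.
* **sRNA**: 80,000 reads per tissue split over 21–24 nt (24 nt half),
  mixing a uniform background with island-targeted upstream flank
  components (24-nt flank fraction 0.40 in embryo vs 0.15 in endosperm —
  the embryo flank enrichment), gene-end, expression-weighted gene-body
  and inverse-expression-weighted TE/pseudogene components; 21–23-nt
  totals are higher in endosperm.

All truth (per-site rates per tissue, planted DMR labels, island
intervals, TSS factors, class assignments) is emitted as first-class
tables.  All randomness flows from a single integer seed through named
`numpy` generator streams; a fixed seed reproduces the dataset and every
downstream output byte-for-byte.

What the generator does **not** emulate: bisulfite non-conversion and
M-bias, duplicate reads, mapping bias and multi-mapping sRNAs, realistic
repeat landscapes and nested features, biological replicates, and
between-site rate dispersion beyond the two-state model.  Passing tests
therefore demonstrate correctness of the computations and recoverability
of planted effects at realistic depth — not performance on real maize
data.

## Problem sizes and numerics

Unit tests run on ≤ 10-kb fixtures against brute-force oracles; the
end-to-end recovery suite runs one ~1-Mb study (the default
configuration, a scale chosen so the whole suite completes in well under
a minute while every planted effect is detected with wide margins) plus a
150-kb miniature; the demo's byte-identity check runs at 150 kb.  At
miniature scales (< ~150 kb, < 10 genes) the island caller can fragment
runs because per-bin site counts are small; island-count assertions are
made only at scales with ≥ 10 genes.  Empty inputs yield zero summaries
or `NaN`-flagged bins, never silent drops; undefined statistics (zero
coverage, constant correlation vectors, < 4 common bins) raise or return
flagged `NaN` explicitly.
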