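# Methods

## Signal model

NOMe-seq reports two methylation signals on one molecule.  After M.CviPI
treatment and bisulfite conversion, a cytosine's information content is
decided by its reference trinucleotide: WCG (A/T before CG) carries only
endogenous CpG methylation, GCH (GC before A/T/C) only the exogenous
accessibility mark.  GCG is ambiguous between the two enzymes and CCG is
prone to M.CviPI off-target activity; both are classified and then
excluded by the channel filters rather than dropped at classification, so
QC can still report their abundance.  Classification is reference-based
(the standard choice for aligner-derived call tables): position *i* is
classed from bases (*i*−1, *i*, *i*+1), with reference Gs classified as
minus-strand cytosines from the reverse-complement trinucleotide.
Cytosines at contig ends or adjacent to N are OTHER and never used.

Per-site level is methylated calls over total calls.  All region levels
are unweighted means of per-site levels — site levels are defined first
and regions average them — with a pooled-count mode available for
sensitivity analysis.  Sites require ≥ 3× depth and regions ≥ 3
qualifying sites; both cut-offs are exposed but default to the standard
values.  Coordinates are 0-based half-open everywhere past the readers;
the cytosine-report dialect (1-based on disk) is shifted at parse time.

## DMR calling

The genome is tiled into 300-bp windows.  A sample's window value is its
WCG region level (missing below 3 sites; missing samples are dropped per
window, and a window needs ≥ 2 values per group — the minimum for a
variance).  Windows are tested with the equal-variance two-sample
Student's *t* test (Welch behind a flag); zero-variance identical groups
are treated as non-significant (*p* = 1).  BH adjustment runs over all
tested windows — untested windows have no *p*-value and are excluded from
the FDR universe.  A DMW needs |Δ| strictly > 0.20, *p* ≤ 0.05 and
*q* ≤ 0.05.  Same-direction DMWs on one chromosome with an inter-window
gap ≤ 300 bp merge into a DMR (adjacent tiles always merge; opposite
directions never do, since hyper- and hypo-methylated region sets are
reported separately).

## NDR calling

Windows of 100 bp slide in 20-bp steps.  The test statistic pools read
calls over the window's GCH sites — the test is count-based — while
reported region levels remain site-means.  Each window's pooled counts
are compared with the genome background (the sample's global GCH site
mean by default) by a 1-df chi-squared goodness-of-fit test, two-sided
with an explicit level-above-background gate, which at the 10⁻¹⁰
threshold is equivalent to a one-sided test.  Significant windows merge
into candidate regions; candidate runs separated by less than one window
width (100 bp) are connected, because sparse GCH stretches inside an open
region can interrupt a run of significant windows and split one region
into fragments.  A candidate becomes an NDR only if the merged span
itself passes all three criteria: chi-squared *p* ≤ 10⁻¹⁰ against the
background, ≥ 5 distinct GCH sites, and length ≥ 140 bp.  The site/length
rules apply to the merged region, not to single windows — a lone 100-bp
window can never satisfy the 140-bp rule.

Per-sample NDR sets combine by multi-intersection semantics: the union is
partitioned at every boundary, segments covered by ≥ *k* samples are kept
(*k* = 1, union, by default; the choice is exposed because either reading
of the published procedure is defensible), and kept segments within 10 bp
are connected.  An NDR overlapping a strand-aware promoter (−1 kb/+0.5 kb
around the TSS) by ≥ 1 bp is proximal, otherwise distal.  Background is
per-sample rather than pooled.

## Metagene profiles

Gene-body profiles use 100 proportional bins over TSS–TES plus 100
fixed 20-bp bins per 2-kb flank; TSS profiles use 200 × 20-bp bins over
±2 kb.  Minus-strand genes are reversed so bin 0 is always 5′-most.  Bins
with no qualifying sites are skipped (not imputed as 0) in both the
per-gene and the across-gene mean; the across-gene mean weights genes,
not sites.  Genes shorter than 100 bp are skipped with a warning.

## Differential expression

The package's own contribution on the expression side is the gating and
set logic, not the count model, so the two-group test is a deliberately
simple negative-binomial Wald stand-in honouring the usual (log₂FC, *p*)
contract: median-of-ratios size factors over the pooled samples;
per-gene method-of-moments dispersion from the pooled within-group
variance of normalised counts, floored at 0.01; log₂FC of normalised
group means with pseudocount 1; and a Wald statistic on the log-mean
difference with a delta-method standard error, referred to a *t*
distribution with the within-group degrees of freedom (the *t* reference
accounts for the estimated per-gene variance at the small sample sizes
the design uses, keeping the null type-I error near nominal — measured at
~0.05 for *p* ≤ 0.05 on 2,000 null genes, 6 vs 6).  Externally computed
per-gene statistics (e.g. a DESeq2 export) can be substituted anywhere a
results table is accepted.

DEG gates: |log₂FC| > 0.5 (strict), BH FDR ≤ 0.05, and mean RPKM > 1 for
coding genes or > 0.1 for lncRNAs.  *Cis* pairs test every same-direction
lncRNA–coding DEG pair within 100 kb ("linear distance" = nearest-end gap
between gene spans, 0 if overlapping — the anchor points are otherwise
unspecified, so the least assuming convention is used) by Pearson
correlation across the pooled samples of both contrast groups (pooling is
a flag); kept at *r* ≥ 0.6 and *p* ≤ 0.05.  The fetal program is the
intersection of disease-vs-control and fetal-vs-control DEG sets per
direction; a program gene is reversed when both treated-vs-disease
contrasts move it opposite to its program direction.  Reversal
percentages are integers rounded half-up.

## Synthetic data

The generator emulates the study conditions: a random genome (GC 0.42 by
default), per-site calls with depth ~ Poisson and methylated counts
~ Binomial(depth, level) — binomial noise only by default, since no
overdispersion model is implied by the data the generator mimics —
background WCG 0.72 and GCH 0.15 with NDR-level GCH 0.45, 10× mean depth
and six samples per group.  Plants: non-overlapping NDR intervals
(200–500 bp) raising GCH level in every sample; DMR intervals (900 bp)
shifting group-1 WCG by ±0.30; GCG/CCG sites simulated at background so
the downstream exclusion is exercised.  Expression: NB counts (dispersion
0.05) for five groups — control, disease, fetal, two treated — with a
planted program (88 up + 275 down at 3-fold, sizes and reversal fractions
74/88 and 217/275 mirroring the published design), disease-only 4-fold
genes, fetal-only genes as negative controls, an MYH7/MYH6-style isoform
switch inside the program, and lncRNA–coding pairs placed ≤ 100 kb apart
sharing a per-sample latent factor (giving Pearson *r* ≈ 0.9).
Fold-change and *cis*-pair plants are drawn at elevated base expression
(~500 mean counts): the fold-recovery and pairing contracts concern
well-expressed genes, where the estimate is limited by biological rather
than counting noise.

One seed drives everything through `numpy.random.default_rng`; rerunning
a generator with the same config is byte-identical.  Every dataset ships
a truth table, and recovery is scored by ≥ 50 % reciprocal overlap (for
intervals) or set comparison (for gene lists).

What the generator does **not** model: read-level artefacts (mapping
bias, incomplete bisulfite conversion, strand imbalance), spatial
autocorrelation of methylation outside plants, copy-number variation,
expression batch effects, and overdispersed methylation calls (a
beta-binomial stress mode would change calibration).  Passing recovery
tests therefore demonstrates the callers implement their criteria
correctly under clean sampling noise, not that the thresholds are optimal
on real tissue data.

## Problem sizes and numerical choices

The recovery suites run on a 2 Mb genome with 150 planted NDRs at 20×
(NDR recovery and specificity), a 1 Mb genome with 100 planted DMRs at
10×, 6 vs 6 (DMR recovery; a 300-kb unplanted genome for the null pass
fraction, ~1,000 tested windows), and 2,000 genes for expression
calibration — sizes chosen so each suite completes in seconds while
leaving hundreds of independent plants or windows per estimate.
Chi-squared and *t* tails come from scipy; BH from statsmodels (checked
against an independent step-up oracle in the tests).  Degenerate inputs:
zero-coverage sites are errors at level computation and unobserved in the
simulator; all-zero genes are *p* = 1/log₂FC = 0; empty gene lists and
empty region sets raise rather than silently returning nothing.

## Known limitations

* The NB Wald stand-in is not DESeq2: no dispersion shrinkage, no LFC
  moderation, no outlier handling.  Its gates, not its *p*-values, are
  the point; plug in external statistics for production use.
* `merge_group_ndrs` treats every sample set symmetrically; weighting by
  sample quality or depth is out of scope.
* Element enrichment is base-pair based; a count-based variant would rank
  elements differently for highly fragmented region sets.
* The enhancer/promoter annotation is taken as given; no liftOver or
  cCRE subsetting is reproduced.
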