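# Methods notes

This note documents the models and procedures implemented in `epitrans`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic data does and does not emulate.

## Expression quantification and differential testing

Expression is RPKM: `count × 10^9 / (L × N)` with `L` the summed exon
length and `N` the number of mapped tags. The detection filter keeps
genes with RPKM > 1 in at least one line; only filtered genes are
tested, and the Bonferroni/BH families are the tested genes.

**TMM normalization.** `tmm_factor(ref, test)` is the weighted trimmed
mean of per-gene `M = log2(test/ref)` on genes nonzero in both vectors,
double-trimmed (30% of genes at each M extreme, 5% at each
A = ½(log2 test + log2 ref) extreme) and weighted by inverse approximate
binomial variances, returned as `2^mean`. On identical vectors it is 1,
on an exact 2× library it is 2. The trim fractions and weighting are the
conventional choices for this estimator; they are exposed as arguments.
If fewer than 10 genes survive trimming the untrimmed mean is used with
a warning. For testing, effective library sizes are
`library × factor`, where the per-sample factor divides the raw trimmed
ratio by the library-size ratio, so that the proportions of typical
(non-differential) genes are equalized across samples.

**Per-gene test.** A two-sided Fisher exact test on the 2×2 table
`[count_a, lib_a − count_a; count_b, lib_b − count_b]` with effective
libraries rounded to integers. A DE call requires BH FDR < 0.05 and
`max(fc, 1/fc) ≥ 3`, direction from the fold change. Fold changes of
zero counts use a 0.5 pseudo-count *in the reported ratio only*; the
test always sees the raw counts. Note that with counts fixed, growing
both libraries makes the Fisher p converge to the conditional binomial
comparison of the two counts — it does not shrink indefinitely; the test
suite asserts exactly this convergence.

**Small-RNA test.** Per-gene Pearson chi-square without continuity
correction (counts are large), Bonferroni-corrected over tested genes;
tables with an expected cell below 1 fall back to the Fisher exact test.

**Length-bias-aware enrichment.** The probability-weighting function is
an isotonic (monotone non-decreasing) regression of the DE indicator on
gene length over up to 40 equal-occupancy length bins; every gene
receives its bin's fitted probability, floored at 1e-6. A category's
odds parameter is the mean weight inside over the mean weight outside,
and the enrichment p is the upper tail of the Wallenius noncentral
hypergeometric distribution (exactly the central hypergeometric when the
odds are 1, which is also used as the numerical branch at odds ≈ 1). BH
correction runs across categories; empty categories are dropped with a
log message.

## Island calling

Parameters: window 200 bp; gap 200 bp (600 bp for H3K27me3, which forms
broad domains); effective genome fraction 0.81; window eligibility at
the Poisson upper 0.20 tail; island FDR ≤ 0.001; differential fold ≥ 3
at FDR < 0.05.

The background rate per window is
`λ = chip_library × window / (Σ chrom lengths × effective_fraction)`.
A window is eligible when its count is at least the smallest k with
`P(Pois(λ) ≥ k) < 0.20`; eligible windows separated by at most `gap`
bp of ineligible windows merge into one island. Each island's p-value is
the Poisson upper tail of its total chip count given the input-scaled
expectation (`input_count × chip_lib/input_lib`), floored at the
background expectation for its length so sparse input cannot inflate
significance; BH across candidate islands. With an empty input library
the caller degrades to background-only scoring and logs it. The
aggregate island score of the original SICER clustering algorithm is
deliberately *not* reproduced; this caller keeps the window/gap/genome
parameters but uses a fully specified eligibility + island-level test,
which is what the test suite verifies (null FDR control; planted-region
recovery; merge boundaries).

**Differential islands.** Candidate regions are islands called on the
pooled signal of both samples (against pooled inputs when available), so
both directions share one symmetric region set. Per region the two
library-normalized counts are compared with a two-sided exact binomial
test of `count_a` among `count_a + count_b` at the library-size
proportion; reported "readcounts" are tags per million. Swapping the
samples inverts fold and direction and leaves p unchanged. Regions with
zero tags in both samples are skipped.

**Annotation.** Each island is classified by its midpoint with
precedence promoter (3 kb upstream of a TSS) > 5'UTR > 3'UTR > coding
exon > intron > downstream (3 kb) > distal intergenic, UTRs being exonic
sequence outside the BED12 thick (CDS) range.

## TSS metagene profiles

Genes are ranked by RPKM (descending, ties broken by gene id) and split
into four groups of equal size ±1 (high / medium / low / very low).
Tags are counted per gene in 25-bp bins over ±5 kb around the TSS;
minus-strand genes are mirrored so upstream is always negative. Genes
whose flank crosses a chromosome edge are skipped and logged.

Per-gene-per-bin counts are capped at the smallest k with
`P(Pois(λ) ≥ k) < 1e-5`, λ being the global mean per-gene-per-bin count
for that (mark, sample) so that all quartiles share one cap. The cap
removes tower artifacts; because `E[min(Pois(λ), cap)]` is strictly
increasing in λ, the ordering of bins is preserved as long as true
per-gene bin rates are not far above the cap. The trimming scope
(global λ) and α = 1e-5 are this package's documented defaults, not a
claim about any published pipeline. The quartile profile is the *mean*
(not sum) trimmed count per gene per bin, so quartiles of unequal size
are comparable.

## Copy-number bias control

Same-state segments with gaps strictly below 1 Mb merge (the gap is
absorbed); overlapping input segments are rejected. Islands whose
midpoint falls in a loss segment are excluded and the count and fraction
reported — the fraction is of all input islands, which is this package's
own definition of the denominator. Densities are islands-per-Mb per
chromosome per state footprint; the neutral footprint is the complement
of *all* called events, so lost territory never counts as neutral. Gain
vs neutral and CNLOH vs neutral are compared with a two-sided
Mann–Whitney U test: exact permutation enumeration (a subset-sum dynamic
program over doubled midranks, correct under ties) when
`min(n, m) ≤ 8` and `n + m ≤ 25`, otherwise the normal approximation
with tie correction. All-tied input returns p = 1.

## Candidate prioritization and qPCR statistics

The three criteria are conjunctive: a qualifying Pol II island
(direction increased-in-tumor, oriented fold ≥ 3) within 5 kb of the
*gene body*, a qualifying H3K27me3 island (higher in the normal-like
line) within 5 kb, and an up DE call. Measuring from the gene body
rather than the TSS is the inclusive reading of "within 5 kb of" a gene
and is configurable. By default criterion (3) uses the FDR-gated DE
call rather than the raw fold change; `require_de_fdr=False` gives the
fold-only mode. Removing any criterion can only grow the candidate set.

ΔΔCt: technical replicates are averaged per (sample, assay); the target
Cq is normalized to the arithmetic mean Cq of two housekeeping assays
(equivalently, the geometric mean of their linear quantities), then to
the mean ΔCq of the reference group; relative expression is `2^−ΔΔCt`.
The procedure is invariant to a constant shift of all of a sample's Cq
values. Group fold change is the ratio of arithmetic means and the group
test is the shared Mann–Whitney implementation; groups below n = 3 are
refused.

## Synthetic data: what it emulates, and what it does not

The generator builds, from a seed, a 2-chromosome 5-Mb genome with 150
non-overlapping stranded genes (1–10 exons, 3–12 kb), kept ≥ 12 kb apart
so that promoter-proximal signal planted at one gene cannot fall within
the 5-kb candidate window of a neighbor and planted truth stays
unambiguous.

**Counts.** Negative-binomial: per-gene lognormal abundance, a
gene-level gamma multiplier *shared* by both lines
(`shared_dispersion = 0.1`) and an *independent* per-line gamma
multiplier (`dispersion = 0.01`), then Poisson sampling at 400k expected
tags per line. The shared component shapes the heavy-tailed cross-gene
count distribution but cancels in the between-line ratio; the
independent component plus Poisson noise is what the Fisher stage must
withstand. With a single library per line, a large independent
dispersion would make the realized fold drift arbitrarily far from the
planted fold and no pipeline could recover the planted truth — the split
keeps the planted folds recoverable while counts remain overdispersed.
30 genes are planted differential (folds uniform in [3, 8], half up,
half down), on above-median-abundance genes so truth survives the
detection filter.

**ChIP tags.** Per mark, uniform background (20k tags) plus per-gene
signal: H3K4me3 bimodal at ±350 bp (sd 40) of the TSS, H3K4me1 bimodal
at −700/+1300 bp, Pol II at the TSS (sd 80), H3K27me3 uniform over the
gene body ±1 kb — amplitudes scaled by expression quartile, positively
for the active marks and inversely for H3K27me3. Per-gene signal rates
are deliberately small (tens of tags per gene) so that per-bin counts at
the planted peaks sit near the profile-stage trimming cap, as they do at
realistic depth; towers far above the cap would be flattened into
plateaus and erase the planted geometry. H3K4 marks follow each line's
own expression; Pol II and H3K27me3 follow the cross-line mean
expression so that, apart from planted sites, both lines carry the same
expected signal and differential islands have a clean null. Six planted
candidate genes get tumor-only Pol II enrichment (10× the top-quartile
rate) and normal-only broad H3K27me3 (1600 tags); the tumor-line
H3K27me3 of top-quartile genes is depleted 10-fold within ±300 bp of the
TSS, producing the tumor-line-only TSS dip. Inputs are uniform.

**Copy number and qPCR.** Segments tile fixed fractions of each
chromosome with seed jitter: two gains < 1 Mb apart (exercising the
merge), a CNLOH and a loss per chromosome; candidates are drawn from
loss-free genes. The Cq generator writes
`Cq = baseline − log2(expression) + noise` with two constant
housekeeping assays, a per-sample plate shift (removed by ΔΔCt), 10
samples per group, triplicates, noise sd 0.25 cycles, and a 2-fold
planted effect on one candidate.

**Not emulated:** read sequences and alignment error, duplicate/PCR
artifacts, fragment-length effects (tags are 5′ positions, no
extension), chromatin-state autocorrelation beyond the planted
geometry, inter-gene regulatory correlation, batch structure in qPCR
beyond plate shifts, and sex chromosomes. Passing tests therefore show
that the *algorithms* implement their definitions and recover planted
signal under realistic noise — not that the pipeline's thresholds are
optimal for any particular real dataset.

## Problem sizes and determinism

Default toy scale (2 × 2.5 Mb, 150 genes, ~0.5M ChIP tags across marks,
400k expression tags per line) was chosen so the complete demo runs in
seconds on one CPU; all generators are pure functions of their
parameters and a seed, and the pipeline writes a manifest with
parameters and per-stage row counts so reruns are reproducible.

## Known limitations

- The island caller is a specified stand-in with matched parameters,
  not a re-implementation of SICER's aggregate island score; absolute
  island counts on real data will differ from SICER's.
- Differential-island normalization is per-million library scaling;
  published readcount/fold columns produced by other tools may use
  normalizations that are not recoverable from their outputs.
- The Mann–Whitney exact branch enumerates only at small sizes; at
  larger sizes the tie-corrected normal approximation is used.
- No multiple-testing structure is shared across marks; each mark's
  island and differential FDRs are controlled separately.
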