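# Methods

## The synthetic study

The pipeline is exercised on a generated study whose structure mirrors the
biological design: three repressive marks mapped by ChIP-seq in control and
migrating cells with an input library per condition, plus a five-arm bulk
RNA-seq experiment (control, migrating, migrating + EZH2 inhibitor, and
both Pol-II-inhibited arms, with 5/5/3/3/3 replicates).

**Genome and annotation.** Two chromosomes of 5 Mb. Coding genes
(15 per Mb, 20 kb), noncoding genes (10 per Mb, 2 kb), enhancers
(20 per Mb, 1 kb; 20 % deliberately placed inside gene bodies so priority
resolution is exercised), and four repeat families (LINE/SINE/LTR/DNA at
60/80/40/20 per Mb with typical lengths 1000/200/500/300 bp). Genes are
non-overlapping within their class; repeats land anywhere. The resulting
exclusive partition is roughly 30 % coding genes, 6 % repeats, 2 %
promoters, ~60 % unannotated — repeat content is far below a real mammalian
genome, which only matters for the *absolute* class shares, not for the
direction checks the tests make.

**ChIP fragment model.** Fragments (350 bp, placed by midpoint) are drawn
from a two-component mixture: uniform background at 0.05 fragments/bp and
enriched domains where the rate is multiplied. Control domains are peaked
and strong (250 per mark, mean 4 kb, 6× background); migrating domains are
diffuse and weak (250 per mark, mean 8 kb, 2.2×). These multipliers were
chosen so that (i) domain windows clear the island caller's eligibility
threshold with high probability (window mean ≈ 22 fragments vs an
eligibility cutoff near 19 in the migrating condition), giving > 80 %
planted-bp recovery by design, while (ii) the domain read mass is smaller
in the migrating condition, reproducing the lower fraction-of-reads-in-
peaks of the diffuse state. In migrating cells 40 % of each mark's domains
come from one shared pool (raising inter-mark correlation, as observed),
and the remainder are placed by rejection sampling (escape probability 0.1)
over repeat territory for H3K9me3/H4K20me1 and over gene territory for
H3K27me3, producing the opposite redistribution directions of the two mark
families. H3K27me3 in migrating cells additionally gains 2 kb domains
around the TSS of every planted "buffered" gene. The input track is
background only.

What this generator does *not* emulate: mappability and copy-number
artifacts, PCR duplicates, fragment-length variation, chromatin
accessibility structure in the input, or the 20 % *shortening* of
H3K27me3 peaks seen in the real data (here all three marks lengthen in the
migrating state; the tests only assert the length direction for the
repeat-seeking marks). Passing tests therefore demonstrate correctness of
the machinery and recoverability of planted structure, not quantitative
agreement with any real dataset.

**Count model.** 2000 genes; baseline log2 cpm ~ N(5, 2); gene dispersions
uniform on [0.05, 0.2] (the mean–variance regime the precision-weight
transform assumes); library sizes uniform within ±15 % of 10^6. Planted
classes: 3 % dependent, 6 % independent (matching the ~1:2 ratio of the
biological result), 5 % buffered, 3 % / 5 % stability-up/-down, all with
|log2FC| = 2 and random sign (fixed sign for stability classes), planted
only on genes with baseline ≥ 16 cpm so the labels are identifiable at the
study's replicate numbers. Classes are disjoint by construction. A per-gene
batch offset ~ N(0, 0.3) on the log2 scale is applied to the second batch
(replicates alternate batches within every arm, so batch is never
confounded with condition). A single scenario seed drives named
sub-streams per stage, so any stage can be regenerated independently and
byte-identically.

## Analysis stages

**Island caller.** Windows W = 200 bp, gap 600 bp, fragment size 350 bp,
effective genome fraction 0.8, window eligibility p < 0.2, island FDR
0.05. The fragment size, genome fraction and FDR are the study's stated
values; the remaining knobs follow the cited island method's conventional
defaults and are exposed in `IslandCallerParams`. Fragment–window
membership is by midpoint (single-window assignment, reproducible
fractions). The island-vs-input test uses a pseudocount of 1 on the
control count before library-size scaling, avoiding zero-mean Poisson
tests. Benjamini–Hochberg is the multiple-testing procedure throughout.
Peak "intensity" is fragments per bp per million mapped — a declared
convention, since no formula is printed for it in the source analysis.
Island length/intensity populations are compared with a two-sided
Wilcoxon rank-sum (Mann–Whitney) test, exact for small populations.

**Partition.** Strict priority, so ties cannot occur; "other" is an
explicit sixth class and all fraction tables sum to 100 %. Promoters
default to 1000 bp upstream of the TSS and include noncoding genes (a
flag restricts to coding). Repeat subtypes share one priority tier but
keep their subtype tag for per-family profiling. The implementation is an
elementary-segment sweep validated base-by-base against a brute-force
per-nucleotide oracle on toy genomes.

**Correlation.** 10 kb non-overlapping bins, midpoint assignment,
Spearman with average ranks. Class restriction keeps bins with ≥ 50 %
class overlap; because toy-scale features rarely dominate a 10 kb bin, the
pipeline falls back to correlating per-feature counts when fewer than
three bins survive — both modes are exposed.

**Chromatin states.** Binarisation at 200 bp with a Poisson test at
p < 1e-4 against `global rate × input bin count / mean input count`
(floored at the global rate where the input is empty). The HMM has
independent Bernoulli emissions per mark; Baum–Welch with scaled
forward–backward recursions; log-likelihood is asserted non-decreasing at
every EM iteration; convergence at relative change 1e-4 or 200
iterations. States are reported sorted by total emission probability so
fits are comparable across seeds up to label permutation. Posterior
decoding is the default (per-bin enrichment is a marginal quantity);
Viterbi is available behind a flag. One model is fit per condition; the
fold enrichment of class c in state k is
`(bp of c in k / bp of c) / (bp in k / genome bp)`.

**Differential expression.** The filter keeps genes reaching 1 cpm in at
least 3 samples (the conventional reading of the ambiguous published
phrasing; both thresholds are arguments). TMM uses the upper-quartile
reference, 30 % M-trim, 5 % A-trim and inverse asymptotic-variance
weights, normalised to geometric mean 1 — verified against the
Bioconductor reference implementation on a frozen fixture. The precision
weight transform is `log2((count + 0.5)/(effective libsize + 1)·10^6)`
with a lowess trend (span 0.5) of √sd on mean log-count and weights
`trend(fitted log-count)^-4`. Gene-wise WLS runs batched over genes;
variance moderation estimates the prior df by moment matching on
log s² (trigamma inversion), falling back to prior df 4 when the moment
estimate is non-positive; infinite prior df collapses to the common
variance. Calls require q < 0.05 *and* linear fold change ≥ 1.3. The whole
chain reproduces the reference voom + moderated-t pipeline to < 0.001 in
log2FC and < 0.001 in t on a frozen fixture. Contrast B compares treated
migrating cells to *untreated* control cells, exactly as the study
defines it.

**Classification.** Pure set algebra on called sets with identical
thresholds and a shared gene universe (enforced). "Independent" requires
membership in both contrasts but not direction agreement — discordance is
flagged in a column, not reclassified. The dependency-by-stability
cross-tabulation is emitted over the full filtered universe; restricting
to migration-altered genes is a row-slice of the same table.

## Problem sizes and determinism

Default problem sizes — 10 Mb genome, ~0.6–0.75 M fragments per track,
50 000 HMM bins, 2000 genes × 19 samples, 50 null replicates for the
type-I check — were chosen so the complete default run (all ten stages)
finishes in well under fifteen minutes on one CPU while keeping every
statistical check comfortably powered. All randomness flows from one
integer seed; the end-to-end manifest (parameter sets plus output
digests) is byte-identical across reruns.

## Known limitations

- Absolute class shares and correlation magnitudes are scenario-dependent;
  only directions are asserted.
- The island caller implements the eligible-window/gap-joining mode only —
  no retrospective-island E-value mode and no input-free calling.
- The HMM is fit per condition; a joint fit across conditions (shared
  emissions) is possible via concatenation but not wired into the CLI.
- Expression-ranked profiling ranks per condition; whether ranks should
  pool conditions is left as an option since the source description is
  silent.
- The stability classes are planted disjointly from the dependency
  classes, so the cross-tabulation's off-diagonal structure is a null
  check here, not a planted effect.
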