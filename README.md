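# hetmig

Analysis pipeline for the heterochromatin landscape of migrating cells:
how the repressive histone marks **H3K9me3, H3K27me3 and H4K20me1**
redistribute when melanoma cells are induced to migrate, and which
transcriptome changes depend on H3K27 methylation.

Induction of migration condenses chromatin globally, but ChIP-seq library
normalisation erases the global gain — what remains observable is the
*shape* of the signal. The pipeline therefore quantifies distributional
change: broad domains become longer and weaker ("diffuse spreading"),
H3K9me3/H4K20me1 drift toward repetitive elements while H3K27me3 drifts
toward genes, inter-mark overlap grows, and a small gene set changes
expression, partly rescued by EZH2 inhibition. Everything runs on synthetic
data with planted ground truth, so every stage is testable without any
download.

## What it computes

**Island calling (broad domains).** The genome is tiled into windows of
`W = 200` bp. With `N` mapped fragments, genome length `G` and effective
genome fraction `f = 0.8`, the background rate is `λ = N·W/(G·f)`; a window
with fragment count `k` is *eligible* when the Poisson upper tail
`P(X ≥ k; λ) < 0.2`. Runs of eligible windows whose internal gaps are
`≤ 600` bp form islands, scored by `Σ −ln P(X = k; λ)` over eligible
windows and tested for IP-over-input enrichment with a library-size-scaled
Poisson test (`mean = max(control, 1)·N_t/N_c`), Benjamini–Hochberg across
islands, keeping `q < 0.05`. Differential islands apply the same test in
both directions over the merged island union of both conditions.

**Redistribution accounting.** Every bp is assigned to exactly one class by
the priority *coding genes > noncoding genes > promoters (1000 bp upstream
of the TSS) > enhancers > repeats*, remainder "other". Read fractions
(fragment midpoints) and differential-island bp fractions per class each
sum to 100 %.

**Correlation and chromatin states.** Spearman ρ between marks over 10 kb
genome-tiling bins, optionally restricted to a partition class; a 5-state
hidden Markov model with independent Bernoulli emissions per mark, fit by
Baum–Welch on 200 bp presence/absence calls (Poisson test against an
input-scaled expectation), with per-(class, state) fold enrichments.

**Differential expression and classification.** Genes under 1 cpm in
fewer than 3 samples are dropped; TMM scaling factors; log2-cpm values
with precision weights from the lowess mean–variance trend; per-gene
weighted least squares with a batch term; empirical-Bayes moderated *t*;
calls at FDR < 0.05 and fold change ≥ 1.3. With contrast A (migrating vs
control), B (EZH2-inhibited migrating vs control) and C (Pol-II-inhibited
migrating vs Pol-II-inhibited control): **dependent** = A\B,
**independent** = A∩B, **buffered** = B\A; C calls give RNA-stability
classes.

## Worked example

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_call_domains.py --seed 1
python analysis/05_expression_classes.py --seed 1
```

prints, among other lines:

```
  H3K9me3  : reads-in-peaks 39.0% -> 31.5%; mean length 4238 -> 4772 bp (rank-sum p = 1.24e-02); intensity 0.388 -> 0.175
migration contrast: 187 altered genes of 2000 tested (98 up, 89 down)
dependency: 72 dependent (39% of altered), 115 independent, 102 buffered
  planted dependent: 60 genes, 93.3% recovered
H3K27me3 promoter signal (migrating - control) by class:
  buffered: +9.46 fpm over 13 genes
  unchanged: +0.80 fpm over 213 genes
```

Reading: after induced migration a *smaller* share of H3K9me3 reads sits
inside called islands and the islands are longer and weaker — the diffuse
signature; of the 2000-gene toy transcriptome, 187 genes change on
migration and the planted dependency classes are recovered at ≥ 93 %;
promoters of buffered genes gain H3K27me3 in migrating cells while
unchanged genes do not. `analysis/03_redistribution.py` and
`analysis/04_correlation_states.py` print the repeat-vs-gene redistribution
directions and the correlation/state-segmentation summaries. The whole
chain also runs as one command: `hetmig run-all --seed 1`.

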