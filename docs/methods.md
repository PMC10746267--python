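# Methods

`acidae` implements two analysis pipelines for dissecting a bacterial
stress response: a denoising-autoencoder (DAE) ensemble that separates
condition-specific transcriptional programs from general stress responses
in an expression compendium, and a paired Ribo-Seq/RNA-Seq translatome
analysis (differential expression, translation efficiency, small-ORF
filtering). Everything is exercised against synthetic data with planted
ground truth; this note records the models, the defaults and why, and what
the synthetic results do and do not establish.

## The autoencoder model

Each ensemble member is a six-layer sigmoid network. Three encoder layers
compress a per-sample expression profile `x` (per-gene min–max scaled to
[0, 1]) into a bottleneck activation vector

    a = σ(W3 σ(W2 σ(W1 x + b1) + b2) + b3),

and the decoder mirrors the encoder with *tied weights* — it uses the
transposes of the same arrays, with free bias vectors `c` initialised to
zero:

    x̂ = σ(W1ᵀ σ(W2ᵀ σ(W3ᵀ a + c3) + c2) + c1).

Because the decoder reads the encoder's storage directly, the tying
constraint cannot drift at any checkpoint. Weights are Glorot-uniform
initialised; biases start at zero.

Training corrupts each input by independently zeroing each entry with
probability 0.10 (per-entry Bernoulli masking; an exact-count mode exists)
and minimises the reconstruction loss against the *clean* input with Adam
and shuffled mini-batches. Both mean squared error and binary
cross-entropy (BCE) losses are supported. The class default is MSE, the
conventional choice for continuous [0, 1] data; the pipeline's desk-scale
default is BCE, which on min–max-scaled profiles (whose per-gene extremes
are exactly 0 and 1) has much stronger gradients and reaches the saturated
activation regime that the downstream on/off analysis requires within a
few hundred epochs, where MSE does not.

Each bottleneck node is interpreted as a coordinated expression program:
for a given input, a node is "on" when its sigmoid activation saturates
high and "off" when it saturates low.

### Ensemble, data split, and the desk-scale training schedule

An ensemble of independently seeded members shares one train /
validation / test split (default 80/10/10) and one (learning-rate,
batch-size) setting chosen by a small grid search scored on the test
partition. Member `i` is seeded `base_seed + 1 + i`; everything is
deterministic given the base seed.

Two regimes are configured:

* **Compendium scale** (hundreds to thousands of samples; `scale: full`):
  100 members, layers 2000/1000/50, MSE, early stopping with patience 5 on
  the validation partition, grid search on the test partition.
* **Desk scale** (the synthetic default, 24 samples): 10 members, layers
  256/128/16, BCE, learning rate 1e-3, batch 16, a fixed 400-epoch
  schedule, and a single-point grid. With two or three validation samples
  an early-stopping criterion fires on noise, so it is disabled
  (`early_stopping=False`); and since no stage consults validation or test
  scores in this regime, members train on all samples (`train_on_all`)
  while the split still defines the scaler's fitting partition. Min–max
  parameters therefore come from the 80% partition only, and the remaining
  samples are clipped into [0, 1] — normalisation is always estimated
  after the split, never on the pooled data.

The fixed schedule skips the per-epoch monitoring pass (nothing can halt),
which removes about a quarter of the training cost; the monitored history
then records the running training loss.

Training runs in single precision by default (`dtype="float32"`), which
halves wall time; gradient correctness is verified against central finite
differences in double precision in the test suite.

## Node specificity

For each condition the mean of its scaled replicate profiles is encoded by
every member (a per-replicate mode with unanimity is available), and
activations are binarised with saturation thresholds θ_on = 0.9,
θ_off = 0.1; anything between is AMBIGUOUS and disqualifies a node from
both the on and the off requirement — a conservative convention, chosen
to target the saturation regime of the sigmoid. A
(member, node) pair is *specific* to a focal condition set (e.g. both acid
intensities) when it is ON for every focal condition and OFF for every
background stress. The pattern census additionally counts nodes ON for the
focal set plus exactly one background condition (acid+ethanol,
acid+antibiotic, ...); patterns are mutually exclusive. Nodes are never
matched across members — identity is always the (member, node) pair.

## From nodes to gene signatures and candidates

A specific node is turned on alone (one-hot bottleneck) and propagated
through the decoder; the all-off decode of the same member is its
baseline. Genes are ranked by the node-mean of the *baseline-corrected*
decoder output. The correction is a deliberate design choice: the raw
decoder output is dominated by each gene's decoder resting level (in desk
experiments the planted program genes rank around the middle of the genome
on raw output and at the very top after correction), and the corrected
score is the same signed quantity used for enrichment directionality. The
uncorrected ranking remains available (`baseline_correction=False`). The
top 40 genes (desk default; configurable count or fraction, ties broken
lexicographically) form the signature set.

Enrichment of a gene set in a node's signed score uses gene-label
permutation: the statistic is the term's mean signed score, the null
redraws same-size sets uniformly without replacement, and the two-sided
p-value carries the plus-one correction, so min p = 1/(n_perm+1). Terms
with fewer than 5 or more than 30 genes in the universe are skipped.
Desk default 10,000 permutations; the full-scale setting is 1,000,000 with
BH adjustment across terms and a conservative significance threshold of
adjusted p ≤ 0.0005.

Candidate genes are signature genes whose mean log2 expression under each
acid condition exceeds that under every other stress by ≥ 0.5 in at least
95% of (acid, other) comparisons; output is sorted by mean acid
expression, descending.

## Translatome statistics

Counts are normalised by median-of-ratios size factors (geometric-mean
reference over genes with all-positive counts; a positive-counts fallback
is available). The per-gene differential test is a negative-binomial Wald
test: with normalised condition means μ̂ (pseudocount 0.5) and a pooled
method-of-moments dispersion α̂ = max(0, (s² − μ̂)/μ̂²),

    lfc = log2(μ̂₁/μ̂₀),  SE = sqrt(Σ_c (1/n_c)(1/μ̂_c + α̂)) / ln 2,

with a two-sided normal reference for lfc/SE. Translation efficiency is
footprint density per mRNA, so te_lfc = ribo_lfc − rna_lfc exactly, with
SEs combined in quadrature. Genes are classified per contrast with
|lfc| ≥ 1 and BH-adjusted p ≤ 0.05 per assay into: concordant in both
assays, RNA-exclusive, Ribo-exclusive, opposite directions, or neither.

This is intentionally a simple per-gene pipeline — no dispersion shrinkage
across genes and no GLM — sufficient to recover planted effects in
synthetic data. **Known limitation:** with triplicates, the per-gene
moment estimator of α has ~4 degrees of freedom; under genuinely
overdispersed counts the Wald test is anti-conservative (empirical type-I
error ≈ 0.11–0.13 at nominal 0.05 for α between 0.01 and 0.1). The
built-in null-calibration experiment therefore runs in the Poisson regime,
where the test is slightly conservative (≈ 0.04); treat per-gene p-values
from deeply overdispersed triplicate data with caution.

Expression filtering keeps genes with mean rpkm ≥ 5 (inclusive) across
the declared conditions. The metagene profile extracts a strand-aware
window (default 50 nt upstream to 100 nt downstream of the first
start-codon nucleotide), normalises each gene's window by its own mean,
skips genes whose window does not fit or has zero coverage, and averages.
RT-qPCR fold changes use 2^(−ΔΔCt) against a reference gene and control
condition.

## sORF candidate filtering

Candidates pass through a fixed exclusion cascade; the first failed rule
is recorded for the census:

1. coverage: mean Ribo-Seq rpkm ≥ 30;
2. length: 10–70 codons, waivable per candidate by an explicit
   `length_exception` flag (for manually curated longer ORFs);
3. induction: Ribo **and** RNA log2 FC ≥ 2 with adjusted p ≤ 0.05 in at
   least one stress contrast (an either-assay mode exists but is not the
   default);
4. overlap: any shared nucleotide with an annotated gene on the same
   strand excludes the candidate — antisense overlap does not, since the
   strand-specific signals are distinguishable.

Coordinates are 1-based inclusive on the public surface (GFF3
convention); interval logic uses half-open coordinates internally.

## The synthetic-data generators

The compendium generator plants additive log2-scale programs (gene set,
loading, active-condition set) on per-gene baselines (N(7, 1.5)) with
Gaussian replicate noise (sd 0.5), over eight conditions × 3 replicates:
two acid intensities, control, and five unrelated stressors. The default
scenario contains an acid-only program (20 genes, +3), an acid+ethanol
shared program (15 genes, +2.5), a general stress program (25 genes, +2),
and one private 30-gene program (+2) per condition. The private programs
matter: real compendia are dominated by condition-dependent regulons, and
without them the matrix is almost pure replicate noise, which trains
arbitrary codes.

The paired-count generator draws NB counts (Var = μ + αμ², α = 0.05,
baseline mean 200–300) for two conditions × 3 replicates with shared
per-sample size factors drawn log-uniform in [0.5, 2], planting four
disjoint 50-gene classes: transcriptional (both assays move),
RNA-exclusive (transcriptional effect exactly buffered in the Ribo
channel), Ribo-exclusive (translation-only), and opposite (translational
effect −2× the transcriptional one).

The annotation generator lays out a toy genome and an sORF fixture with
one violator per filter rule plus an antisense survivor, with truth labels.

What the generators do **not** emulate: gene–gene correlation beyond
block programs, skewed or heavy-tailed log-expression noise, trended
(mean-dependent) dispersion, batch effects, coverage periodicity or
read-level artefacts. Passing the recovery and calibration suites
therefore shows that the implementations do what they claim under their
stated models — not that the desk-scale ensemble would reproduce any
particular real-data gene list.

## Problem sizes and runtime

Built-in experiment sizes are chosen for a laptop-class single CPU: the
planted-program recovery runs ten independent pipeline replicates
(≈ 90 s each), the NB null calibration uses 5,000 genes, the fold-change
accuracy 2,000 genes, the TE power study 2,000 genes with 200 planted
effects, and the enrichment null 200 random terms at 2,000 permutations.
The compendium-scale configuration (100 members, 2000/1000/50, 10⁶
permutations) is available behind `scale: full` and is hours of compute.
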