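# Methods

## Codon speed labels

Labels derive from transcriptome-averaged per-codon elongation rates
(inverse mean ribosome footprint density, dimensionless, ~0.4–1.3).
Amino acids whose synonymous codons spread less than `min_spread = 0.35`
in rate are excluded outright: with a narrow spread, a fast/slow contrast
within that amino acid is not meaningful. Within retained amino acids,
`rate < slow_threshold (0.85)` is SLOW and `rate > 0.85` is FAST; an exact
tie is excluded as intermediate (the rules are strict inequalities, so the
boundary belongs to neither class). A small override map reassigns codons
labelled against the threshold on external evidence; the default contains
leucine CTC (rate 0.91) → SLOW. Overrides act only within amino acids that
survive the spread filter and are recorded in the output.

tAI weights follow the standard gene-copy-number construction. An anticodon
decodes a codon when its 2nd/3rd bases Watson–Crick pair the codon's 2nd/1st
bases and the (codon 3rd base, anticodon wobble base) pair is recognised;
the default penalties are the published constants — Watson–Crick 0, G:U
0.41, I:C 0.28, I:A 0.9999, U:G 0.68 — exposed as a configurable map. Raw
weights are normalised by the per-species maximum and zero weights replaced
by the geometric mean of the nonzero weights.

"Variable between species" has no published quantitative definition, so the
consistency filter uses a concrete, order-free rule: for each retained codon
and species, the indicator *tAI(codon) ≥ median tAI of its synonymous
family*; the codon is kept iff the indicator agrees across at least
`min_agreement` (default 1.0, i.e. unanimity) of the species. Amino acids
left with fewer than two labelled codons are then dropped entirely, since no
within-family contrast remains; the cascade is recorded under the same
`variable_tai` reason.

## Corpus construction

Protein/CDS pairs are validated by translation (terminal stop tolerated;
internal stops, non-ACGT characters, or mismatching translations drop the
record with a logged reason). Records in 40%-identity clusters with fewer
than 4 members are removed — the homolog-family floor that guarantees each
training protein has relatives in several species. All members of a
70%-identity cluster receive the same cross-validation fold: fold assignment
shuffles cluster ids under the seed and deals each cluster to the currently
smallest fold by member count (the mechanism is unspecified in the source
analysis; this greedy deal approximates equal fold sizes at cluster
granularity). Test-species proteins are never used for training but carry
their cluster's fold so evaluation can route them to the one head that never
saw their homologs. A greedy k-mer-containment clusterer is included purely
so synthetic-scale runs need no external clustering tool; real runs consume
cluster TSVs from a dedicated tool.

Positions are 1-based codon indices everywhere; proteins are truncated at
the embedding context limit (1024). Training rows are undersampled to equal
SLOW/FAST counts per (gene, amino acid) — the step that removes gene-level
codon bias from the training signal — and test rows are weighted so each
class carries total weight `m = min(n_SLOW, n_FAST)` per (gene, amino acid),
i.e. per-position weight `m / n_class`, group total `2m`.

## Classification head

A feed-forward network maps the per-position embedding (1280 features from
the upstream protein language model; the synthetic generator uses 64) to
P(FAST): hidden layers (128, 128, 64, 64), ReLU, dropout 0.5 after each
hidden layer (disabled at inference), sigmoid output, binary cross entropy,
Adam at learning rate 1e-4, batch size 128. At 1280 inputs this is exactly
192,961 trainable scalars. The head is implemented directly in numpy — at
this size there is nothing a large framework would add — with every random
stream (He-normal initialisation, epoch shuffling, dropout masks) drawn from
seeded PCG64 generators, and the input table canonically sorted before
shuffling, so training is bit-reproducible given the config seed regardless
of input row order.

Two numerical choices are ours: inputs are z-scored per feature (statistics
fitted on the training rows and stored with the head) for optimisation
conditioning, and the default epoch count is 60 — the architecture's source
fixes the optimiser constants but not the epoch count, and at desk scale
(tens of thousands of balanced rows rather than millions) Adam at 1e-4 needs
more passes to reach its loss floor. Early stopping on a validation fold
(patience 2) is available but off by default.

Out-of-fold evaluation scores each test protein with the head whose training
folds exclude the fold of the protein's 70%-identity cluster; routing is
recorded in the score table and checked against the cluster map in tests.

## Evaluation

All test metrics are weighted by the class-balancing test weights, so 50% is
the exact chance level. Score ties at the 0.5 decision threshold count as
FAST (documented convention). The weighted ROC AUC is the probability that a
random FAST-weighted score exceeds a random SLOW-weighted score, ties half.
Quantile-bin accuracies use the mid-mass weighted rank
`u_i = (cum_i − w_i/2) / W` of each score; bins combine the top and bottom
tails symmetrically and partition the weighted mass. The constraint fraction
`f = 2(acc − 1/2)` solves `acc = f + (1 − f)/2`; the gain fraction
`(acc_baseline − 1/2)/(acc_model − 1/2)` reports how much of the model's
above-chance gain a simpler baseline explains.

The random-forest baseline (500 trees, depth 10, min 5000 samples to split;
scikit-learn) classifies FAST vs SLOW from pLDDT, position, and one-hot
amino acid; folds are gene-stratified (a seeded round-robin deal of genes)
because the source analysis is ambiguous on the fold mechanism, and
train/evaluate both use the test weights.

Per-gene mean loss is the weighted mean binary cross entropy over a gene's
scored positions (scores clipped at 1e-12), restricted to genes with total
weight ≥ 20; the lowest decile is exported as the well-predicted gene set.
The gene-level expression correlation uses the *unweighted* per-gene mean
score against log expression: the claim under test is what the model
predicts for a gene overall, and weighting by the class-balancing weights
conditions on the labels, which structurally drags the summary toward the
minority class. A `weighted=True` variant is retained.

## Feature analyses

Group comparisons (inside vs outside signal/transit peptides, structured
pLDDT > 90 vs disordered < 50, active/binding sites vs other positions)
use the weighted Welch construction: reliability-corrected weighted
variances, Kish effective sample sizes, Satterthwaite degrees of freedom,
Cohen's *d* from the pooled weighted SD. This is one concrete reading of a
"weighted t-test"; with unit weights it reduces exactly to the classical
Welch test, and it is verified against a brute-force transcription of the
formulas. Group membership composes from pandas boolean masks over an
annotated position frame, so restrictions ("sites vs other positions within
structured regions only") are set algebra and never change the formulas.
Feature intervals are 1-based inclusive; positions inside several
overlapping annotations belong to every matching group.

The domain-relative profile averages scores at offsets −60..+60 from each
domain start and end, classifying each position as inside or outside *any*
domain of its protein; the summary statistic is the mean score 35–40 codons
past domain ends minus the global outside-domain mean — negative values
would indicate the post-domain translational pause expected under
cotranslational-folding models.

## Screen

Guide selection scans both strands for 20-mers adjacent to NGG whose
protospacer-or-PAM span covers the edited codon. A candidate survives iff
(a) the edit changes a base in the 7 PAM-proximal protospacer bases or a G
of the PAM — otherwise the edited locus would be re-cut — and (b) an
exhaustive scan of all windows on both strands finds no site other than the
target matching with ≤ 2 mismatches followed by NGG. The scan is exact (no
alignment heuristics); it is quadratic in genome size per guide, which is
fine at the scales this package targets.

The 194-nt oligo concatenates 5′ homology, a 100-nt donor window centred on
the edited codon and carrying the edit, the retron scaffold, the 20-nt
guide, and 3′ homology. "Repeat of length ≥ 10" is read strictly: any
10-mer occurring at two distinct positions anywhere in the oligo rejects it
(the strictest defensible reading; the length is configurable). A
start-codon knockout-control designer (ATGN → TAA, removing the start and
frameshifting) is included as a trivial variant.

Read counting trims the 28-base vector prefix and matches the next 72 bases
against every donor prefix: donors with more than 2 mismatches in the first
58 bases are ineligible; the fewest-total-mismatch donor wins; ties and
unmatched reads are discarded (never randomly assigned), so each read
contributes to at most one donor.

The fitness test is a self-contained NB threshold Wald procedure rather than
a wrapper around an external differential-abundance framework: per-variant
moment dispersion `α̂ = max(α_min, (s² − μ)/μ²)` pooled across timepoints
(no dispersion-trend shrinkage, no independent filtering), delta-method SE
of the log2 fold change under NB variance with a pseudo-mean stabiliser
(default 0.5) guarding empty means, p = 1 whenever |log2FC| ≤ 0.58, and
Benjamini–Hochberg across tested variants. Variants with all-zero start
counts are flagged and excluded. The simplifications are deliberate and
fully specified; the null-simulation and power tests bound their
consequences (false-call rate ≤ 1% at nominal 5% on 2,000 neutral variants;
power ≥ 0.9 at |s| = 2%/generation with 4 replicates per timepoint,
dispersion 0.05).

Size factors are median-of-ratios over the top 75% most abundant variants
(by mean raw count, ties broken deterministically). Note the estimator's
exact equivariance: doubling one of *n* samples multiplies its factor by
2^(1−1/n) and the others by 2^(−1/n) — the *relative* factor doubles, and a
global depth change cancels entirely.

Head-to-head competition rates are the least-squares slope of
log2(variant/reference) against generation, minus an optional variant-free
control slope; log2FC converts to growth-rate difference as
`log2FC / generations` (doublings per generation).

## Synthetic data: what it emulates and what it does not

The generator plants exactly the statistical structure the analyses assume.
Homolog families (default 500 proteins across 14 species — 13 training, one
held-out test species — mean length 300) are built from a base sequence via
three divergent ancestors (~55% identity, the 40%-cluster level) each
lightly mutated per species (80–95% identity, the 70%-subcluster level).
Per position, the FAST probability is
`sigmoid(β0 − β_start·1[pos ≤ 50] + β_struct·(pLDDT − 50)/50 + β_site·site
+ β_postdomain·1[35–40 past a domain end] + gene_bias)` with defaults
β0 = 0, β_start = 0.6, β_struct = 1.0, β_site = 1.5, β_postdomain = 0
(no post-domain pause by default, matching the finding the profile machinery
is meant to detect or refute; tests plant a negative value to verify sign
recovery), gene_bias ~ N(0, 0.6²). Effect sizes were chosen once so the
planted constraints are clearly recoverable at the default corpus size while
individual positions remain mostly uncertain (per-position Bayes accuracy
≈ 0.58 under the balanced weighting). Expression is exp(gene_bias) up to
log-normal noise, tying gene-level codon bias to expression as observed in
fast-growing yeast. Embeddings are a fixed seeded linear map of the feature
vector (start flag, scaled structure track, site flag, post-domain flag,
one-hot amino acid, gene bias) plus Gaussian noise (SD 0.3); gene bias is
deliberately encoded so a head trained *without* balancing can exploit it —
the expression-debiasing contrast (|r| < 0.1 balanced vs r > 0.3 unbalanced)
depends on this.

The screen generator draws log-normal start abundances, compounds planted
effects as `2^(s·generations)` (default 81 generations, 10% non-neutral,
|s| ∈ [0.5%, 3%]), renormalises to constant depth (so a planted effect's
expected log2FC is attenuated by the pool-mean shift — negligible when
non-neutral variants are a small minority), and emits NB counts
(dispersion 0.05) with log-normal sample depth factors for 4 replicates per
timepoint (the 2 editing × 2 competition structure).

What passing tests do **not** show about real data: synthetic sequences have
no real phylogeny, amino-acid composition bias, or structural correlation
between homologs; embeddings are linear in the generating features, so the
head's capacity is barely taxed; screen counts have no PCR jackpotting,
editing-efficiency variation, or guide-dependent dropout. The suite
validates the statistical machinery and its calibration, not biological
conclusions.

## Problem sizes

Defaults were chosen so a full run is minutes on one CPU: ~500 proteins ×
~300 residues (≈ 58k labelled positions, ≈ 35k balanced training rows),
embedding dimension 64, five 60-epoch heads; 2,000 screen variants × 8
samples. Real-scale inputs (tens of thousands of proteins, 1280-dim
embeddings) use the same code paths via the embedding-store directory
format.

## Known limitations

- The consistency filter's family-median rule is one defensible reading of
  cross-species tAI variability; published codon sets may differ at the
  margin.
- The NB test's per-variant moment dispersion is noisy at 4 replicates;
  borrowing strength across variants (as dispersion-shrinkage frameworks do)
  would improve power at low counts.
- The greedy clusterer is a convenience for synthetic scale only; its
  k-mer-containment identity is not a substitute for proper local-alignment
  clustering.
- Guide off-target scanning is exhaustive and exact but not indexed; very
  large genomes would need a proper aligner upstream.
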