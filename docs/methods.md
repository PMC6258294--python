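# Methods

This note documents the models and procedures implemented in `xenomir`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## Data model and curation

A record is one mature miRNA: id, uppercase RNA sequence (DNA `T` input
is normalized to `U`; any other symbol rejects the record, not the
file), class label, and optional species/family/abundance annotations.
Sequences shorter than 15 nt are rejected outright; the unlabeled
prediction pool additionally requires ≥ 18 nt so every pool sequence
fills the CNN input window.

Negative-set curation works per sequencing sample: records are ranked by
abundance (descending) and the lowest `floor(0.3·n)` removed —
low-abundance miRNAs are plausible false negatives whose absence from
host samples may only reflect low intake. Survivors from all samples
are pooled by union, sequences present in the positive set are removed,
and the result is deduplicated. Two conventions the procedure needs but
that are otherwise open: abundance ties are broken by lexicographic
sequence order (determinism), and a sequence surviving in *any* sample
is retained (union, matching the idea that the sets are merged across
samples and species before labeling). Deduplication always keeps the
first occurrence in input order.

## Feature encodings

Each sequence yields 129 named features:

| block | count | definition |
|---|---|---|
| length | 1 | untruncated sequence length (nt) |
| positions 1–24 | 24 | nucleotide identity, `-` beyond the sequence end |
| full-sequence k-mers | 4+16+64 | sliding-window frequency, k = 1..3 |
| seed k-mers | 4+16 | same over nucleotides 2–8, k = 1..2 |

k-mer frequency is count/(L−k+1), so each k-mer family sums to 1; the
seed region uses denominators 7 and 6. The normalization is a declared
convention: at k = 1 it coincides with count/length, and for k ≥ 2 any
per-sequence normalization differs from it only by a length-dependent
factor. The 105 numeric features (all but the positional symbols) are
the model/statistics subset; positional identities are descriptive only.
The 24-nt positional window truncates longer sequences *for position
features only* — the `length` feature always reports the true length.

The CNN input is the one-of-K encoding of the first 18 nt (A=0001,
C=0010, G=0100, U=1000), flattened position-major to 72 bits with
all-zero padding blocks after the sequence end. 18 nt covers nearly all
mature plant miRNAs while keeping the input fixed-width; the cost is
that the CNN cannot see length differences or 3′ content beyond
position 18.

## Statistical screen

Per numeric feature, a two-sided Wilcoxon rank-sum test compares the two
groups: the exact null distribution when both groups have ≤ 25
observations and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections. Benjamini–Hochberg
controls the FDR across the 105 tests; features with FDR < α (default
0.01) are flagged. With many correlated k-mer features BH is known to
remain valid under positive dependence; the flagged count can shift by
small amounts under other FDR conventions.

LDA: features are standardized, and the Fisher discriminant is solved
from the within-class scatter with a ridge term λ = 1e-6·trace(S_w)/105.
The ridge is required, not cosmetic: each k-mer family sums to 1, making
the scatter rank-deficient. The direction is normalized to unit length
(the downstream test is scale-invariant) and oriented so the positive
group has the higher mean LD1. Compactness compares all within-group
pairwise |ΔLD1| distances between groups with a two-sided Welch t-test.
The n(n−1)/2 pairwise distances are *not* independent observations, so
the p-value is descriptive — the procedure reproduces the published
analysis as described rather than correcting it.

## Classifiers and protocol

**Split.** round-half-up(0.15·P) positives and the same number of
negatives are held out uniformly at random (25+25 at the study sizes
166/942); everything else trains.

**Oversampling.** Training positives are extended to the
training-negative count as one copy of each positive plus uniform draws
with replacement — every positive appears at least once, and the
training set is exactly class-balanced. In cross-validation (stratified,
seeded) the validation fold is removed *before* oversampling, so no
validation sample is ever duplicated into training.

**Random forest.** scikit-learn's Breiman forest, 501 trees, Gini
criterion, 6 candidate features per split, on the 105-feature matrix.
Feature importance: mean decrease Gini from the fitted forest, and mean
decrease accuracy by out-of-bag permutation — per tree, accuracy on its
OOB samples minus accuracy after permuting one feature within them,
averaged over 10 permutations and all trees. The top 10% (11 of 105)
features are flagged per criterion.

**1-D CNN.** Fixed architecture: input 18 steps × 4 channels →
conv1d(16 ch, kernel 8) → conv1d(32 ch, kernel 4) → flatten →
dense(64) → dense(32) → 2-unit softmax, all hidden activations logistic
sigmoid, dropout 0.3 and L2 (λ = 1e-3) on the dense layers, categorical
cross-entropy, Adam (lr 1e-3), 100 epochs, batch 32. The network is
implemented directly in numpy with analytic backpropagation (verified
against finite differences in the test suite); at this size numpy
training takes seconds and is bit-reproducible from one integer seed.
The 72-bit flattened input is interpreted as an 18-step 4-channel signal
for convolution — the same information, with kernel sizes counted in
nucleotide steps. Hyperparameters are exposed in `CNNConfig`; the
defaults above were fixed once after a small grid check that longer or
faster schedules overfit the duplicated oversampled positives (training
AUC rises above the generator's Bayes ceiling while held-out AUC falls).

**Evaluation.** Confusion at threshold 0.5 on the positive-class score;
SN, SP, ACC; MCC with the 0-on-zero-denominator convention; AUC as the
tie-aware Mann–Whitney statistic; ROC over all score thresholds.

**Consensus.** Pool candidates are nominated only when both models call
them positive. Both models share the 0.5 threshold by default (the same
threshold used in evaluation); per-model thresholds are exposed.

## Synthetic benchmark

The generator emits i.i.d. nucleotides from a class-specific emission
distribution, draws length from a class-specific categorical
distribution over 18–24 nt, and then, with a per-motif probability,
overwrites a planted motif at a uniform random offset. Zero-order
emission plus motif overwrite (rather than a Markov chain) keeps every
planted effect size directly controllable and the expected feature
shifts computable in closed form.

The default study conditions (`table1_like_config`) plant the xenomiR
contrasts: positives emit C at 0.26 vs 0.20, U at 0.24 vs 0.28, carry
CAG with probability 0.6 vs 0.15, and run ~0.8 nt shorter (mean 21.5 vs
22.3). Class sizes default to 166/942 and the 500-sequence unlabeled
pool mixes the generators at a 0.3 positive fraction. The pool's truth
labels exist only so tests can score consensus precision; models never
see them. `null_config` gives both classes one shared generator for
type-I-error and no-signal checks.

What passing tests show — and what they do not. The benchmark
establishes that the pipeline *recovers planted compositional signal*
(screen flags C/CAG/length; both models beat chance; the RF Gini top
decile contains the planted features; a null generator produces neither
significant features nor AUC above chance) and that the protocol
invariants hold (no CV leakage, balanced oversampling, consensus ⊆ each
call set). It does not emulate real miRNA data: no family structure or
phylogenetic correlation, no shared biogenesis motifs, no abundance or
sequencing noise, and independence between positions. Real xenomiR
discrimination draws on many small correlated differences that this
generator deliberately does not model, so absolute accuracy figures on
synthetic data undershoot those reported on real collections. The
exact log-likelihood ratio between the two generating distributions —
computable for this generator — attains AUC ≈ 0.82 under the default
conditions; held-out model AUCs (~0.74–0.77) sit near that information
ceiling, and the CNN's window excludes the length signal entirely.

## Numerical and size choices

* Problem sizes in the test suite: the full 166/942 pipeline with the
  501-tree forest and the default CNN schedule runs once; multi-seed
  properties (null AUC band, consensus precision, type-I calibration)
  use 100–450 sequences per class, 101–201 trees and 30–60 epochs.
* All randomness flows from integer seeds through
  `numpy.random.default_rng`; sub-seeds are derived additively.
* Degenerate inputs: empty groups, single-class labels, sequences
  shorter than the seed region, all-zero score variance and zero MCC
  denominators all raise or return documented conventions rather than
  propagating NaNs.

## Known limitations

* The compactness t-test inherits the pairwise-dependence caveat above.
* Mean-decrease-accuracy importance recovers per-tree bootstrap masks
  via scikit-learn's internal OOB index routine; a major scikit-learn
  upgrade could require touching that one helper.
* CNN reproducibility is exact on a fixed BLAS; across BLAS builds,
  last-ulp differences may perturb individual predictions near the
  decision threshold.
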