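# Methods

## Model

Each peptide is a string over the 21-letter alphabet A…Y plus `X`
(unknown residue). Two tokenizers map it to integer sequences: single mode
prepends a start token and emits one index per residue (vocabulary 23:
pad=0, start=1, residues alphabetical from 2); pair mode emits one index
per non-overlapping residue pair read left to right (vocabulary 443, pair
indices lexicographic over the same residue order). An odd-length sequence
is completed with a single `X` before pairing, so a length-n peptide yields
n+1 single-mode and ⌈n/2⌉+1 pair-mode tokens. Pair tokens are
non-overlapping by default because each token is meant to *cover* two
residues rather than slide over them; `pair_stride=1` switches to sliding
bigrams for comparison. The start token doubles as the classification
anchor for the transformer and is labeled `[CLS]` in interpretation
output.

Two towers with identical architecture but disjoint parameters process the
two tokenizations. A tower is: embedding → backbone → {linear head →
softmax over 2 classes; projection MLP → L2 normalization}. Backbones and
their pooling rules:

- **cnn** — per layer, 1-D convolutions with kernel sizes 3 and 5 (same
  padding), each producing half the hidden width, concatenated and passed
  through ReLU; pooling is a global max over positions restricted to real
  tokens (padded positions are bias-masked to −1e9 before the max).
- **lstm** — stacked unidirectional LSTM layers; the pooled vector is the
  hidden state at each sequence's true final token, so padding cannot
  reach it.
- **transformer** — learned positional embeddings up to `max_len`,
  pre-norm encoder blocks (self-attention + position-wise FFN), final
  layer norm; padded keys are masked out of every attention softmax and
  the start-token position is pooled.

All three obey the same contract, verified by property tests: appending
pure-padding columns changes no output, and permuting samples in a batch
permutes outputs identically.

Projections are L2-normalized before the contrastive loss. The
temperature-scaled loss divides dot products by τ; on unnormalized vectors
the scale of the vectors and τ would be confounded, so unit-norm
projections are the only reading under which a τ grid is meaningful.

## Losses

The cross-entropy term is the standard two-class cross-entropy
−log p̂[y] per head, mixed by β: β=0 trains head 1 alone, β=1 head 2
alone. A literal positive-term-only reading of the mixed CE (summing
yᵢ·log ŷᵢ with yᵢ ∈ {0,1}) would assign zero loss to every negative
sample and could not train a classifier; the one-hot two-class form, which
the printed sum reduces to when yᵢ is one-hot, is the only trainable
interpretation and is what this package implements. Probabilities are
clamped to [1e-12, 1−1e-12] before logs.

The contrastive term anchors on tower-1 projections and contrasts against
tower-2 projections of the whole batch, with the positive pair *excluded*
from the denominator. This is implemented as defined, even though it
departs from standard InfoNCE (the loss is unbounded below: a perfectly
aligned positive pair with orthogonal negatives gives a negative value).
Flags expose the conventional variants: `include_positive_in_denominator`
(standard InfoNCE denominator) and `symmetric` (average of both anchor
directions). The batch loss uses mean reduction by default for learning-rate
stability across batch sizes; `sum` matches the printed equations exactly
and is available via `loss_reduction`. The final objective is the affine
blend (1−α)L_CE + αL_CL; α=0 is the baseline condition.

## Training protocol

Adam at learning rate 1e-3 (the one stated training constant), no
scheduler, no early stopping; 50 epochs and batch size 32 by default, the
terminal short batch kept (the contrastive term is skipped for a batch of
one, where it is undefined). The train/validation split takes a stratified
round(0.1·n) validation subset, fully determined by the seed. The grid
walks (architecture, seed, τ, β, α); per (architecture, seed) the split is
computed once and the model is rebuilt from the seed, so the α=0 baseline
and all contrastive settings start from bit-identical weights — parameter
hashes are recorded so the pairing is verifiable. A ledger directory makes
the grid resumable: finished points are loaded, not retrained.

Model selection maximizes MCC with ties broken by accuracy, then lower α,
then lower seed. Selection on the *test* split mirrors the published
protocol for this family of benchmarks but leaks test information into
model choice; validation is therefore the default and test-selection logs
a warning.

Default grids: α ∈ {0, 0.1, 0.3, 0.5, 0.7, 0.9}, β ∈ {0, 0.5, 1}, seven
seeds. The τ grid {0.05, 0.1, 0.2, 0.5, 1.0} spans the usual contrastive
range around 0.2 on a log-ish scale; only its inclusion of 0.2 is
externally anchored.

## Redundancy audit

A query is redundant if any database sequence other than itself aligns
with e-value ≤ 1e-5. The default backend is exact Smith–Waterman with
affine gaps (BLOSUM62, gap open −11 / extend −1, Biopython's
`PairwiseAligner`; a length-g gap costs 11+(g−1)) and Karlin–Altschul
statistics E = K·m·n·e^(−λS) with gapped-BLOSUM62 conventions λ=0.267,
K=0.041, m the query length and n the summed residue length of the
database. This keeps the audit self-contained; an external BLAST backend
(`makeblastdb`/`blastp`) sits behind the same interface and is
cross-checked at smoke level on exact duplicates. One consequence worth
knowing: a very short exact duplicate (≈10 residues) may legitimately
score above e = 1e-5 against a large database — the statistics, not a bug,
and real BLAST behaves the same way.

## Interpretation

Integrated gradients at the embedding layer, midpoint Riemann sum with 64
steps by default (128 in the validation suite), baseline = the padding
token's embedding (`zero` available) — padding is the model's native
"absence" input. The target is the class-1 probability of the chosen
head. The completeness residual |Σ attributions − (F(x)−F(baseline))| is
computed and reported with every result rather than assumed away; the test
suite requires it below 5% of |ΔF| + 1e-3 at 128 steps and non-increasing
as steps double. Per-residue summaries average token scores over all
occurrences; pair-tower scores are split equally between a pair's two
residues (the only symmetric choice). Attention extraction returns the
post-softmax per-head maps of any transformer layer.

## Synthetic data

The generator emulates the scale and shape of ACP benchmarks: hundreds of
peptides, lengths uniform on 10–50, balanced classes, 21-letter alphabet
with `X` at 1% so the unknown-token path is exercised. The class signal is
compositional: positives sample K/W/L at 3× base weight, negatives D/S/Y —
residues chosen to mirror the attribution structure that trained ACP
classifiers typically report, so the interpretation stage has a known
ground truth. An optional motif can be inserted into a fraction of
positives. The null spec (no enrichment, no motif) is the leakage control:
a harness that shows skill on it is broken.

What passing tests on this corpus do **not** show: performance on real
ACP benchmarks. The generator plants a linear composition signal; real
anticancer activity depends on secondary structure, amphipathicity, and
context effects that no composition model captures. The synthetic results
validate the learning mechanics (losses, pairing, selection,
attribution), not the biology.

## Numerical and engineering choices

The network stack runs on an in-package vectorized reverse-mode autodiff
engine over numpy float64 (tape of array operations, hand-written
backward for the LSTM recurrence for speed). Gradients are verified
against central finite differences in the test suite. Softmax uses a
detached max-shift; masks enter as additive −1e9 biases; MCC and the
ratio metrics define 0/0 as 0; AUC is the tie-aware Mann–Whitney rank
statistic (equal to trapezoidal ROC integration, cross-checked against
scikit-learn). Determinism: every stochastic step (init, splits, batch
order, dropout, generation) draws from a generator derived from an
explicit seed, and the engine is single-threaded numpy, so identical
configurations reproduce bit-identical runs.

Problem sizes in the validation suite and acceptance script — a
400/100-peptide corpus, towers of embed 32 / hidden 64 / 1 layer, 35
epochs, seed-averaged over 3 seeds — are chosen as the smallest scale at
which the planted signal is comfortably recoverable by all three
backbones; the package defaults (embed 64, hidden 128, 2 layers, 50
epochs) suit real benchmark-scale corpora.

## Known limitations

- Exact reproduction of published benchmark figures is out of scope: the
  external benchmark files and the original supplementary hyperparameters
  are not packaged.
- The built-in aligner scores exactly (no word-hit heuristics), so audit
  e-values differ in detail from any specific BLAST parameterization;
  ratios at the 1e-5 threshold are insensitive for realistic peptide
  lengths.
- The engine is CPU-bound and sized for peptide-scale inputs; it is not a
  general deep-learning framework.
- Whether per-residue attribution should aggregate tower 1, tower 2, or
  both is a genuinely open choice; the default follows the tower of the
  selected classifier.
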