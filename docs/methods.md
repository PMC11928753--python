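# Methods

## The model

`condphage` implements a label-conditioned masked-language-modeling
framework for identifying bacteriophage sequence among mixed metagenomic
contigs.

**Tokenization.** A nucleotide segment is decomposed into all overlapping
k-mers (stride 1, default k = 6, vocabulary 4^6 + 7 special tokens). A
class token is prepended and a separator appended, so a 500-bp segment
occupies 495 + 2 = 497 positions. Windows containing a non-ACGT letter map
to `[UNK]`, preserving positional structure; this is a package choice —
dropping ambiguous windows would shift all downstream positions.

**Conditional pre-training.** Unlike a conventional encoder that prepends
the same `[CLS]` token to every sample, the conditional encoder prepends a
*label* token: `[BAC]` for bacterial segments, `[PHA]` for phage segments.
Training is standard masked language modeling: each non-special position
is corrupted independently with probability 0.15 (of the corrupted
positions, 80% become `[MASK]`, 10% a random non-special token, 10% are
left unchanged but still carry a prediction target), and the encoder is
trained with cross-entropy at the corrupted positions only. Because the
class token is visible context, the model learns class-conditional k-mer
statistics, and the class-token representations of the two classes
separate — quantified here by the silhouette score of the position-0
last-hidden-state vectors under the true 2-class partition, rather than by
a visual embedding plot. Per-position Bernoulli(0.15) sampling is used
rather than exact-count sampling; both are defensible readings of
"mask 15%", and the Bernoulli form is the standard collator behavior.
The random-replacement pool excludes special tokens so corruption can
never inject a spurious label signal.

**Paradox-augmented fine-tuning.** At prediction time the true class is
unknown, so a query segment has a 50% chance of receiving the wrong label
token — a situation never seen in pre-training. Fine-tuning therefore
tokenizes every labeled segment twice, once per label token, and assigns
three targets: matching token → the true class; contradicting token →
"paradox". The classifier is the pre-trained encoder (its weights continue
to update) followed by a bidirectional LSTM over all non-pad position
representations, pooled as the concatenation of the final forward and
final backward hidden states, and a small MLP ending in a softmax over the
three classes. A softmax (mutually exclusive classes) is used because each
tokenized sample has exactly one true target and the downstream
aggregation sums scores like probabilities; a sigmoid-per-class variant
would not conserve mass under aggregation. Both augmented copies of a
segment enter the same shuffled pool; they are not forced into one batch.

**Prediction and label aggregation.** A query contig is cut into 500-bp
segments (a trailing remainder ≥ 100 bp is kept as a shorter segment,
since the encoder handles variable length via padding; shorter remainders
are discarded). Each segment is tokenized with both label tokens and
scored. The 3-class triple collapses to binary: with `[PHA]` attached,
"paradox" means "not phage", so its mass is added to bacteria; with
`[BAC]` attached it is added to phage. This conserves total mass exactly
(b_bac + b_pha = p_bac + p_pha + p_par). All 2 × n_segments binary phage
scores are averaged with equal weight — no length weighting for the
remainder segment, and no distinction between averaging over tokenizations
vs segments, which are equivalent under equal weights. The contig is
called phage iff the mean phage score strictly exceeds 0.5; an exact tie
is called bacteria.

## The synthetic data generator

Real training corpora for this task are multi-gigabyte genome collections.
The simulator instead draws two sequence populations from order-m Markov
chains (m ≤ 4) over {A,C,G,T}: a base chain ("bacteria") with
Dirichlet(1,1,1,1) transition rows, and a second chain ("phage") whose
rows are the mixture (1−d)·base + d·independent draw. The divergence dial
d ∈ [0,1] is monotone in the Jensen–Shannon divergence of the resulting
k-mer spectra (checked by simulation). Sequences start from a uniformly
drawn context followed by a 100-base burn-in that is discarded, so the
emitted prefix is approximately stationary.

k-mer composition is exactly the signal an overlapped-k-mer encoder can
exploit, so recovering the labels is a fair test of the *framework* —
tokenizer, conditioning, paradox augmentation, aggregation — rather than
of biological realism. What the simulator deliberately lacks: genes and
coding structure, GC skew, repeats, proviruses embedded in host genomes,
read errors, and any homology structure between train and test beyond the
shared chain. Passing tests therefore demonstrate that the machinery
learns and propagates compositional class signal end to end; they do not
certify performance on real metagenomes.

**Study conditions.** The default `SimulationConfig` is the condition used
throughout the tests: 1000 training and 400 test sequences per class,
lengths uniform in 500–2000 bp, order-2 chains, divergence 0.8, balanced
classes.

## Model sizes and schedules

Two encoder presets exist. `"published"` records the published large-model
recipe (12 layers, hidden 768, 12 heads, masked-LM schedule lr 4e-4,
batch 2048, 10,000 warmup steps, weight decay 0.01); it is not exercised
by the tests. `"tiny"` (2 layers, hidden 64, 4 heads, feed-forward 256,
learned absolute positions, max 512 positions) is the working preset.

The neural network is implemented directly on NumPy with hand-written
backpropagation (verified against finite differences in the test suite),
so the desk schedules are sized for a single CPU core:

| stage | steps/epochs | batch | lr | warmup |
|---|---|---|---|---|
| pre-training (desk) | 80 steps | 8 | 1e-3 | 20 |
| fine-tuning (desk) | 4 epochs | 8 | 1e-3 | 10 |

Profiling informed two sizing rules: per-update cost grows roughly
linearly with batch size at these sequence lengths, and on the synthetic
task optimization progress tracks the number of updates rather than the
number of samples seen — so small batches with more updates are the
efficient regime. The fine-tuning pool used by the end-to-end tests is a
balanced subsample of 100 segments per class (plus 20 per class for
validation); the pre-training corpus is the full segmented training set.
Adam (β = 0.9/0.999, decoupled weight decay 0.01 on weight matrices only)
with linear warmup and linear decay floored at 10% of the base rate; the
best-validation-loss epoch's weights are returned from fine-tuning.
Pre-training runs a fixed step budget (the loss history is logged) rather
than early stopping — predictable cost, and the downstream tests are the
real acceptance signal.

Two deliberate departures from the BERT recipe, chosen for CPU
efficiency and immaterial at these scales: the position-wise activation is
ReLU rather than GELU (transcendental evaluation over [batch, 497, 256]
tensors dominated feed-forward cost), and the MLM head is a single linear
map evaluated only at corrupted positions.

## Numerical choices

- float32 working precision; float64 available for gradient checking.
- Attention masking is additive (−1e9 on padded keys); padded positions
  attend but are never attended to, and their outputs carry no gradient
  (the BiLSTM masks them via a carry-through state update), so
  representations at non-pad positions are independent of padding length.
- Softmax is computed with max-subtraction, in place on the score tensor.
- The silhouette of identical vectors is defined as 0 (degenerate case).
- Checkpoints are single `.npz` files (weights + config + k); save→load
  reproduces bit-identical inference.
- All randomness flows through `numpy.random.Generator` seeded from the
  caller; child streams are split with `SeedSequence.spawn`, so
  simulation output, masking, batching and initialization are exactly
  reproducible for a fixed seed on fixed hardware.

## Known limitations

- The ablation grid covers conditional-vs-[CLS] pre-training and
  paradox-vs-binary fine-tuning on the conditional encoder; the fourth
  cell (unconditional pre-training + paradox fine-tuning) is constructible
  with the public API but not exercised by the tests.
- Forward strand only; no reverse-complement augmentation.
- Sub-500-bp contigs are accepted down to 100 bp (one short segment);
  real tools often refuse such inputs instead.
- The desk-scale model is far below the published model capacity; desk
  metrics quantify the framework on synthetic data, not expected
  performance on real metagenomes.
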