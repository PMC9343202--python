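# Methods

## Scope and data model

`mirsite` performs *site-level* miRNA target prediction: the unit of
classification is a (mature miRNA sequence, candidate target site) pair,
where the candidate target site (CTS) is an extracted mRNA subsequence of
at most 30 nt. Sequences are normalised to the RNA alphabet {A, C, G, U}
(uppercase, T→U) so that DNA-style mRNA records and RNA-style miRNA records
share one four-token vocabulary. Model inputs are right-padded to a fixed
30-nt window — the longest human mature miRNA is 26 nt — with a dedicated
PAD token whose embedding is the zero vector and is never trained.
Right-padding keeps the miRNA 5' seed region (nucleotides 2–8) at fixed
input positions 2–8, which is where Watson–Crick pairing dominates target
recognition; how sub-30-nt sites should be anchored inside the window is
otherwise unspecified, and right-anchoring is this package's choice.

## Nucleotide embeddings (mi2vec / m2vec)

Each sequence is treated as a sentence of single-nucleotide words and a
skip-gram model is trained to predict context nucleotides within a window
of c = 5 positions of each center nucleotide. The training objective is
the negative-sampling surrogate of the softmax log-likelihood: for a
(center, context) pair with k = 5 noise words,

    loss = −log σ(v'_ctx·v_ctr) − Σ_neg log σ(−v'_neg·v_ctr),

with noise drawn from the unigram distribution raised to the 3/4 power,
excluding the true context. Because the vocabulary has only four words,
the exact normalised softmax distribution is also implemented and tested
(it must sum to one to 1e-12); negative sampling is the training path.

Choices that the underlying method leaves open, fixed here as word2vec
conventions: input vectors initialised uniformly in [−0.5/d, 0.5/d] and
output vectors at zero; learning rate decaying linearly from 0.025 to 1e-4
of itself across all pair-updates; min_count = 1 (all four nucleotides kept);
10 epochs. Training is plain sequential SGD, bit-reproducible for a fixed
seed. Tables are written as TSV at 17 significant digits, which round-trips
float64 exactly.

The default embedding dimension for the full classifier is 50; the
dimension grid {2, 4, 10, 20, 30, 50, 100} and a one-hot baseline are
exposed through the encoder-comparison harness.

**A caveat that matters for synthetic data.** Skip-gram vectors are only as
informative as the corpus's co-occurrence structure. Real miRNA/mRNA
corpora are compositionally biased, and the four nucleotide vectors learned
from them differ in usable ways. Sequences generated i.i.d.-uniform have
*no* co-occurrence structure: the optimum makes every context equally
likely given every center, and the learned vectors converge toward a
common direction (pairwise cosines 0.85–0.99 in practice). The information
is not destroyed — four vectors in d ≥ 4 dimensions remain linearly
independent — but the contrast between nucleotides becomes small, which
measurably slows classifier training on synthetic data. One-hot encoding
does not have this failure mode.

## Classifier

Both padded encodings (30 × d) pass through separate branch BiLSTMs
(hidden 50 per direction; branch weights unshared by default because the
two molecules play asymmetric roles, with optional sharing). The LSTM cell
is the standard three-gate formulation with elementwise products; the
forward pass of the cell is additionally exposed as an unbatched,
explicit-parameter function and is tested to 1e-12 against an independent
scalar implementation. The backward direction consumes the reversed
sequence and its outputs are re-reversed, so each output row t is
[h_fwd_t ; h_bwd_t].

The two 30 × 100 branch feature maps are concatenated **along the time
axis** into a 60 × 100 joint map — positions 1–30 are the miRNA, 31–60 the
CTS — which a second BiLSTM (hidden 32) reads in both directions, producing
60 × 64 features. A 64-value summary is pooled and reduced by two linear
layers (64 → 32, ReLU; 32 → 2) and a softmax.

Pooling is **max over time** by default. The alternative last-state
summary ([final forward state ; final backward state]) is available as
`pool="last"`. Both yield the same 2·hidden2 width, so the 50-32-32-2
layout is unaffected. Max pooling is preferred because binding is a
*localised event*: whether a site matches is decided at some offset, and a
max over per-position features propagates gradient directly to the
position where the evidence sits instead of through up to 60 recurrence
steps. (Empirically this choice does not rescue the hardest synthetic
regime; see Limitations.)

PAD positions are fed through the recurrence as zero vectors (no masking)
by default; `mask_pad=True` zeroes layer-1 feature rows at all-zero input
positions before the joint layer.

Initialisation: all weights uniform in ±1/√fan_in, biases zero except the
forget-gate bias b_f = 1 (retain memory by default), all seeded. Ablation
variants substitute vanilla-RNN, GRU, unidirectional-LSTM or BiLSTM units
per layer in the same two-branch topology; a two-block 1-d CNN
(32 then 64 filters, kernel 5, max-pool 2 — the baseline's filter sizes are
this package's choice, since only its existence is specified) serves as the
non-recurrent baseline. All forward/backward passes are hand-written numpy;
finite-difference tests bound the relative gradient error at 1e-4 (1e-5
for the embedding objective).

## Training

Weighted cross-entropy, computed from logits with the log-sum-exp trick;
class weights are inverse-frequency (N/(2·N_c)) by default, exactly 1 on
balanced data. Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) at lr 0.001, batch 32,
100 epochs are the reference settings; SGD is available (it is known to
fail to converge on this architecture), and learning rates ≥ 0.01 trigger
a warning because training collapses to chance there. Shuffling is
re-seeded per epoch from the master seed, the last incomplete batch is
kept, and gradient clipping is off by default (available as a guard).
Embeddings stay frozen during classifier training (pretraining and
classification are separate stages); fine-tuning them through the
classifier is not implemented. Runs are bit-deterministic on CPU given
(dataset, config, seed); checkpoints use a timestamp-free container whose
save→load round trip is bit-exact.

## Evaluation

Predictions are thresholded at 0.5 on the binding-class probability, ties
predicted positive. Metrics follow the standard definitions: accuracy
(TP+TN)/total, sensitivity TP/(TP+FN), specificity TN/(TN+FP), F-measure
2TP/(2TP+FP+FN); an undefined ratio is reported as NaN and excluded from
means. (One published formulation prints sensitivity with a TN+FN
denominator; that is inconsistent with its own reported values and the
standard definition is used here.) Average precision uses step-wise
interpolation over the descending-score threshold sweep; AUC is the
trapezoidal area, which equals the Mann–Whitney probability
P(score⁺ > score⁻) + ½P(tie) — both are verified against brute-force
oracles. Cross-validation is stratified 5-fold with per-fold class counts
within one of proportionality; headline numbers are unweighted means of
fold metrics, with a fresh fold-seeded model per fold. Between-method
comparisons use a paired Student's t-test across fold scores (both methods
on identical folds, n−1 degrees of freedom, two-sided); zero-variance
differences degenerate to p = 0 (means differ) or p = 1 (equal), with a
warning.

## Synthetic data

The generator emulates the statistical signature the method targets: a
positive pair's CTS contains the exact reverse complement of the miRNA
seed heptamer (positions 2–8) planted at a uniform offset in otherwise
i.i.d. background; a negative pair's CTS is rejection-resampled until it
contains no such match (a fixed heptamer occurs in a random uniform 30-mer
with probability ≈ 0.0015, so rejection almost never iterates; the exact
probability is verified by a dynamic-programming test). miRNA lengths are
uniform on 19–26 nt, CTS lengths on 20–30 nt, base composition uniform by
default and configurable; `label_noise` flips labels independently.
Generation is byte-reproducible given the seed and also emits matched
FASTA corpora so embeddings can be pretrained on the same distribution.

What this emulates — and what it does not: real positive/negative pairs
differ not only in seed complementarity but in base composition, pairing
thermodynamics, conservation and 3'-supplementary pairing. The generator
reproduces *only* the seed rule, on purpose: it makes separability exact
(a hand-coded seed-match detector scores accuracy 1.0 at zero noise, the
ceiling for any classifier) and all structure attributable to one known
mechanism. Consequently, passing tests on synthetic data demonstrate the
pipeline's mechanics — determinism, shapes, metrics, optimisation — not
field performance on curated interaction databases.

## Study conditions for the acceptance script

`scripts/acceptance.py` runs the end-to-end method at a desk-scale
operating point chosen to finish in minutes on one CPU: 2500 generated
pairs (2000 train / 500 held out via one stratified fold), d = 10
embeddings pretrained on 300 matched sequences per corpus, the reduced
classifier (hidden 16/8) trained 30 epochs with the reference optimiser
settings, plus a label-shuffled control trained identically. It reports
the separability ceiling, the learned model's held-out metrics, and the
gain over the shuffled control, all computed at run time.

## Known limitations

* **The exact-seed synthetic task is adversarially hard for the learner.**
  The labeling rule is an OR over offsets of a 7-position equality test
  between the two inputs — a high-degree multiplicative interaction.
  Gradient descent on generic recurrent architectures does not discover
  such matching circuits at desk scale: at the study conditions above the
  learned model stays near chance (~0.5 with near-collinear synthetic
  skip-gram embeddings, ~0.6 with one-hot inputs even after 5× more
  epochs), while the rule-based detector is perfect. This is a property
  of the task/architecture pairing at this sample size, not a defect of
  the optimiser (gradients are finite-difference-verified, and the model
  overfits small training sets). On real interaction data the same
  architecture has lower-order correlates to exploit.
* Skip-gram embeddings trained on structureless (i.i.d.) corpora are
  near-degenerate; see the embeddings section.
* No thermodynamic or conservation modelling; no gene-level scanning of
  full mRNAs; no k-mer (> 1) tokenisation; no attention or pretrained
  language models.
* Embedding fine-tuning through the classifier is not implemented.
* External baseline methods (database scanners, feature-engineered deep
  models) are not reimplemented; their scores can be supplied as TSV for
  comparison via the evaluation module.
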