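# Methods

This note records the modelling conventions, numerical choices and known
limitations of the toolkit, in the spirit of a model-description appendix.

## Encoders

Two encoder families are implemented natively over a small reverse-mode
autodiff core (float64 numpy arrays).

**BERT-style.** Learned absolute position and token-type embeddings are
summed with word embeddings and layer-normalised; each block is the
standard post-layer-norm transformer layer (multi-head self-attention,
residual + LayerNorm, GELU feed-forward, residual + LayerNorm). The MLM
head is a dense `hidden→hidden` transform with GELU and LayerNorm followed
by a decoder tied to the word-embedding table with a free per-token bias.
A forward pass returns `num_layers + 1` hidden-state arrays (the embedding
output is layer 0) and one `(heads × N × N)` attention map per layer.

**Bottleneck (MobileBERT-style).** 128-dimensional word embeddings are
concatenated with their left and right neighbours (trigram input) and
linearly up-projected to the 512-wide inter-block stream. Each of the 24
blocks linearly down-projects to a 128-wide intra-block bottleneck for
attention (key and query read a shared bottleneck; values read the 512-wide
block input) and for a stack of four feed-forward sub-blocks with
intermediate width 512 and ReLU activations, then up-projects back with a
residual from the block input. All normalisation inside this family is the
elementwise affine "NoNorm" (`w·x + b`), matching the original bottleneck
design. These internals reproduce the published ~25 M backbone parameter
count exactly (24,581,888). The family's MLM head here is a simplified
dense `512→128` + activation + LayerNorm + tied decoder; the original
design used a more elaborate concatenated decoder, but the head is excluded
from the backbone budget and never distilled against, so the simple tied
head was preferred.

Parameter shapes are a pure function of the configuration, so exact counts
are available without allocating arrays. The tied decoder is never counted
twice. Counting takes an explicit `include_mlm_head` flag because published
budget figures do not always state whether the head is included; the
6-layer/768 backbone counts 65,192,448 (65 M) without the head, while the
4-layer/312 architecture reaches 13,903,756 (15 M to the nearest five
million) only with the head included — the flag makes both conventions
reproducible.

**Attention maps** are exposed post-softmax (row-stochastic). The
per-layer attention KL of the compact recipe requires probability rows;
for uniformity the layer-to-layer MSE uses the same post-softmax maps by
default. The original transformer-layer distillation method arguably used
pre-softmax scores; a forward-pass option (`keep_scores`) records those as
well and the recipe flag `presoftmax_attention` switches the MSE to them.
The published description does not settle the question, so both variants
are first-class rather than one being guessed.

**Initialisation** of fresh models is truncated normal (std 0.02, clipped
at two standard deviations), seeded; norm gains start at 1 and all biases
at 0. Student initialisation from a teacher copies the embedding tables and
MLM head verbatim and selects teacher layers at a uniform stride — even
0-based indices (0, 2, 4, …) when the teacher is twice as deep. Even-index
selection keeps layer 0 and is the common convention; the starting offset
is configurable. This scheme requires the student's widths to equal the
teacher's, which is enforced with a descriptive error.

## Masking collator

Each eligible position (non-special, non-padding) is selected i.i.d. with
probability 0.15; a selected token becomes the mask token with probability
0.80 and otherwise a uniformly random non-special token. There is **no
keep-unchanged branch by default**: the 80/20 mask/random split is the
convention implemented here, with an optional `keep_prob` making the
classic 80/10/10 scheme reachable. i.i.d. selection (expected rate 15%)
was chosen over exact-count sampling as the simpler standard; an
`exact_count` flag provides the alternative. Masking operates on sub-word
tokens; whole-word masking is not implemented. Labels carry the original
id at selected positions and −100 elsewhere; the 0/1 `mask_weights`
indicator (`labels ≠ −100`) is what restricts the output losses to masked
tokens.

## Distillation losses

All objectives are pure functions of the student/teacher forward outputs
and one masked batch. Conventions:

* **Normalisation.** The MLM, output-KL and output-CE terms are written as
  sums over positions; the implementation averages over masked positions so
  loss values are batch-size invariant (the sum convention is available via
  `reduction="sum"`). All worked examples in the tests use the mean
  convention.
* **KL direction.** The output KL places the *student* distribution first,
  exactly as the objective is written; much of the distillation literature
  uses teacher-first, so a `teacher_first_kl` flag flips it rather than the
  implementation silently "fixing" the direction.
* **Weights.** No published values exist for the λ weights; every default
  is 1.0, declared in the recipe and logged per component. The per-layer
  weights λ_l default to 1 for every layer.
* **Layer map.** `g(l) = ceil(l·T/S)` under 1-based indexing — the exact
  uniform stride ending at the top teacher layer when depths divide, and a
  monotone assignment still ending at the top layer when they do not.
* **Numerics.** Logarithms receive a 1e-12 floor so KL/CE stay finite under
  float arithmetic; cosine norms receive the same floor, which makes the
  cosine of a zero-norm row 0 by convention (loss contribution 1). The
  compact loss validates that attention rows sum to 1 within 1e-3 and
  raises otherwise.
* **Padding.** Positions with attention-mask 0 are excluded from every
  token average (hidden-state MSE and cosine means, attention-map query
  rows, KL/CE masked-position means). Key columns of attention maps are
  kept; padded keys carry ~0 probability on both sides.
* **Wn.** The masked-token coefficient is implemented as a 0/1 indicator
  with mean normalisation, not as a continuous weight.

Correctness is established three ways: plain-loop reference oracles (shared
with nothing in the package) agree to 1e-10 on micro instances; every
distillation term is exactly zero at student–teacher equality (the soft-CE
term bottoms out at the teacher's entropy instead, which is checked as an
identity); and central-difference gradient probes on micro models pass at
1e-4 relative error, with an absolute floor in the denominator for
near-zero gradients (the usual gradcheck convention).

## Training

Both modes — distillation against a frozen teacher and continual MLM
pretraining — share one optimizer: Adam with decoupled weight decay
(0.01), linear warmup over the first 10% of steps then linear decay to
zero, and global-norm gradient clipping at 1.0. Pretraining-scale
hyperparameters are not published for this setting, so the defaults
(lr 5e-4, sequence length 128) are config-declared assumed defaults. The
full-scale step counts (100 K distillation, 200 K continual MLM) ship as
named presets only; tests and examples run desk-scale configurations
(hidden 16–32, vocabularies of ~60–90 tokens, 100–500 steps), which is
sufficient to demonstrate that each recipe moves a student toward its
teacher and that MLM training beats the ln|V| uniform-guessing bound.
Dropout is omitted entirely: at these scales it only adds variance, and
evaluation-mode forward passes are deterministic by contract.

Runs are pure functions of their seed: batch selection and masking derive
per-step seeds from the run seed (all kept below 2³¹), the teacher is
frozen (verified bitwise in tests), and identical configurations reproduce
identical traces and final parameters under single-threaded execution.

## Fine-tuning protocol

Word-level BIO labels are propagated to sub-words by assigning each word's
label verbatim to all of its pieces; fine-tuning trains on the propagated
labels. Evaluation defaults to word level, reading each word's first
sub-word (the inverse of propagation); a sub-word-level mode is provided
since the evaluation granularity is not published. Malformed predicted BIO
runs are repaired by promoting orphan `I-` tags to `B-` (conlleval
behaviour) before entity extraction; entity F1 is micro-averaged over
exactly matched (span, type) pairs. Relation F1 is positive-class (binary)
or unweighted macro over classes — macro by default includes every class
present in the label set, the negative class included; both modes are one
flag apart. The factoid-QA metrics use a top-5 window: strict accuracy is
gold at rank 1, lenient accuracy is gold anywhere in the window, and MRR
averages 1/rank within the window (0 outside), which preserves
S ≤ MRR ≤ L. Span extraction ranks candidate (start, end) pairs by score
sum under start ≤ end and a length cap, breaking ties to the lowest start
then lowest end. The seeded RE split takes `round(fraction·n)` test
examples by seeded permutation (10% of 5330 → 533/4797); both the seed and
the rounding rule are exposed because the originals are unpublished.

The published fine-tuning presets (NER: 5 epochs, batch 16, lr 5e-5 with a
3e-5/batch-32 alternate; RE: 3 epochs; QA: batch 16, lr 5e-5 or 3e-5) ship
verbatim as named configurations for full-size models. Desk-scale
demonstrations use a proportionally larger learning rate (1e-2) — tiny
encoders need it — and the toy RE task uses 10 epochs.

## Synthetic data

The generators emulate the *shapes* of the real inputs, not their
semantics. The corpus draws tokens i.i.d. from a Zipf law (exponent 1.1 —
heavy-tailed like real text; a uniform corpus makes the MLM loss flat) with
one planted bigram rule: after the trigger token, the target follows with
probability 0.9 exactly (the non-rule branch excludes the target so the
conditional is exact). Toy NER entities come from fixed sub-vocabularies
of two-piece words with *distinct stems* for mention-initial and
continuation words, making each token's tag a deterministic function of
the token — a bag-of-tokens baseline solves the task, which is verified as
evidence that planted signal exists. Toy RE labels are a deterministic
function of the template verb; toy QA answers are verbatim context spans.
Special tokens are fixed to `[PAD] [UNK] [CLS] [SEP] [MASK]` with ids 0–4.

Because the synthetic tasks are deliberately easy and the encoders tiny,
passing tests demonstrate that the objectives, gradients, plumbing and
metrics are correct — not that the recipes would rank the same way, or
reach published F1 scores, on real biomedical corpora. Reproducing the
benchmark numbers requires the external datasets and full-scale
pretraining, which are out of scope here.

## Other limitations

* Single-device, single-threaded training only; no mixed precision.
* No temperature-scaled softening (no temperature appears in the
  objectives as implemented), no task-specific distillation stage, no data
  augmentation.
* WordPiece *inference* (greedy longest-match) is implemented;
  vocabulary *training* is not.
* Checkpoints are a named-array `.npz` container with a JSON config
  sidecar; round-trips are bitwise exact.
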