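# Methods

## The model

The span head turns entity recognition into three coupled binary
decisions per entity category over a representation matrix
E ∈ ℝ^{n×d} (one row per character, produced by a pluggable encoder):

1. **Start boundaries.** P_start = softmax_rows(E·T_start) with
   T_start ∈ ℝ^{d×2}. A position is a candidate start when its class-1
   probability strictly exceeds class-0 (row argmax; the exact 0.5/0.5 tie
   resolves to non-boundary, a conservative and deterministic choice).
2. **End boundaries.** The start information is injected before the end
   projection: the n×2 start one-hot cannot be added to an n×d matrix
   directly, so a learned embedding U ∈ ℝ^{2×d} maps each indicator row
   into representation space and P_end = softmax_rows((E + I·U)·T_end).
   During training the indicator I comes from the gold start labels
   (teacher forcing, which stabilizes the end head early in training);
   at inference it is the argmax of the predicted P_start.
3. **Pair matching.** A candidate pair (i, j) with i ≤ j and
   j − i < max_span_len is accepted when
   sigmoid(m · concat(E_i, E_j)) > threshold, m ∈ ℝ^{2d}. All accepted
   pairs are kept, so the decoder emits overlapping and nested spans by
   construction.

One parameter set (T_start, T_end, U, m) is kept per category: the
two-class formulation is inherently per-category, and matching a start of
one category with an end of another is meaningless. The projections carry
no bias terms by default (the formulation is purely multiplicative); a
bias flag would be a one-line extension but is deliberately absent to keep
checkpoints minimal.

**A structural caveat worth knowing.** The matching logit is additive in
its endpoints: score(i, j) = f(i) + g(j). Consequently two same-category
gold pairs with four distinct boundaries, e.g. (0, 4) and (1, 3), force
the crossing pairs (0, 3) and (1, 4) above threshold as well — no setting
of m separates an XOR of boundary pairs. Same-category nesting is exactly
decodable only when the nested pair shares a boundary; cross-category
nesting is always exactly decodable because categories are scored
independently. The length cap (max_span_len) prunes most crossing pairs in
practice. The synthetic generator nests across categories, matching what
this decoder can represent exactly.

## Loss

L = α·L_start + β·L_end + γ·L_span, with α = β = γ = 1 by default (no
component has a principled reason to dominate a priori; the weights are
exposed in `LossConfig`). L_start and L_end are mean cross-entropies over
all (category, position) cells; L_span is mean binary cross-entropy over
the sampled candidate pairs. The loss is zero exactly at perfect
prediction, and L_start = ln 2 under uniform boundary rows — both are
asserted in the test suite and recomputed by the acceptance script.

Candidate pairs for L_span: all gold (start, end) pairs labeled 1, plus
every i ≤ j combination of a gold start with a gold end of the same
category that is not itself a gold pair, labeled 0 — these are precisely
the confusions the decoder must avoid. The sample is capped at 50 pairs
per sentence with seed-deterministic subsampling. Sentences with no
entities contribute no pairs; L_span is then 0 with a warning.

## Training

Hand-written gradients (softmax/sigmoid cross-entropy identities) drive a
plain Adam optimizer. Defaults follow the standard fine-tuning recipe for
this task family — learning rate 2e-5, warmup proportion 0.15, batch size
8, 20 epochs, 9:1 train/test split, 5-fold cross-validation harness — and
live in the committed `defaults.yaml`, so "default" is a reproducible
statement. The schedule ramps the learning-rate multiplier linearly from 0
to 1 over the first warmup fraction of steps, then decays linearly to 0
(configurable to constant); the post-warmup decay is this package's choice
where the recipe is otherwise silent.

The encoder is a contract, not a class: text in, n×d matrix out,
trainable. Production-scale use would plug in a Chinese BERT-family
encoder; the shipped `TinyEncoder` (character embedding plus one width-3
tanh mixing layer) is a genuinely trained component, not a mock — one
window of context is exactly what boundary detection needs on
character-separable text, and it memorizes a 200-sentence corpus to ≥ 99
training F1 in a few CPU-seconds at d = 32 with learning rate 0.02 (the
2e-5 default is calibrated to fine-tuning a large pretrained encoder, not
to training a tiny one from scratch).

Runs are bit-reproducible for a fixed seed: initialization, batch order
and pair subsampling all derive from the configured seed. Sentences longer
than `max_seq_len` are truncated; entities crossing the boundary are
dropped with a logged warning.

Self-training: a trained model pseudo-labels plain-text sentences, which
are appended to the manual corpus tagged `source="model"` (equal weight to
manual data; no confidence filter by default, an optional minimum matching
probability is exposed).

## Evaluation

Exact-match (label, start, end) counting; per-type rows use each type's
own counts and overall rows are micro-averages, labeled as such in every
report. 0/0 conventions: a precision or recall with zero denominator is 0
when the opposite error count is nonzero; F1 = 0 when P + R = 0; a type
with empty gold and empty predictions scores 100 by convention (vacuously
perfect). Percentages are displayed at two decimals; full precision is
kept internally. Inter-annotator agreement reuses the same exact-match
machinery with one annotator as reference; since true positives are
symmetric and FP/FN swap under exchanging annotators, F1 is
swap-invariant. The IAA report micro-averages over types.

The softmax BIO baseline is a single linear per-position projection onto
2·C+1 tags trained with cross-entropy. It shares the encoder and differs
only in decoding structure, which is the point of the comparison: it
cannot emit nested spans, so on nested gold its recall is strictly below
the span decoder's even when both are driven by identical forced boundary
scores.

## Corpus conventions

Offsets are 0-based half-open character positions on the raw sentence
string, so `text[start:end]` is the surface and validation is a string
comparison. The JSON dialect (schema list + sentences with id/text/
entities) is this package's own definition. BIO conversion keeps a maximal
non-overlapping subset (earlier start wins, then the longer span) and
warns per dropped span; orphan I- tags on import are repaired to B- with a
log line rather than rejected, for tolerant ingestion of third-party
files. Annotation-guideline checks (overlap, all-Latin surfaces) warn
rather than fail, because nested annotation is a feature here, not an
error.

## Synthetic data

The generator emulates three structural properties of rehabilitation
corpora — long entities, nested entities, a heavy singleton tail — and
nothing linguistic. Sentences are character strings over per-type CJK
alphabet blocks (disjoint by default, giving a learnable surface→type
mapping; `hard_mode` shares one alphabet and removes separability). Each
sentence draws distinct entity types by default so that same-category
crossing pairs (see the matcher caveat) do not arise in the separable
setting. Defaults: 200 sentences of 20–40 characters, 2 entities per
sentence, entity lengths 2–8, nesting rate 0.1, target singleton
proportion 0.25 (the observed per-type range in rehabilitation corpora is
roughly 17–32%), vocabulary of 80 surfaces per type.

Low-frequency control: surfaces are drawn from a truncated power law
p_k ∝ k^{−s} over vocabulary ranks; the expected singleton proportion of M
i.i.d. mentions is Σ_k p_k(1−p_k)^{M−1}, monotone decreasing in s, and s
is solved by bracketing (clamped to the uniform endpoint when the target
exceeds what the vocabulary size permits). Realized statistics land within
±0.05 of the target at ~1,000 mentions and are recorded in the generation
manifest.

`make_annotator_pair` perturbs each gold span independently with the given
disagreement probability (one-character boundary shift, label swap, or
deletion, in equal thirds), giving an analytically predictable agreement:
R = 1 − rate and P = (1 − rate)/(1 − rate/3) in expectation.

What passing on this data does **not** show: robustness to real Chinese
orthography, segmentation ambiguity, entity-boundary ambiguity between
semantically overlapping categories, or transfer from pretrained
representations — the separable default is a correctness harness, not a
difficulty benchmark.

## Problem sizes and numerical choices

The test suite and acceptance script use 200-sentence corpora, d = 32
encoders, 30 epochs, 1,000 random decoder-oracle instances with n ≤ 12,
and 200 agreement trials — sizes chosen so the full pipeline is exercised
end to end in seconds while every property being checked (memorization,
equivalence, symmetry) is already at its asymptote. Probabilities are
clipped by an ε = 1e-12 inside logs; softmax subtracts the row max;
sigmoid is evaluated in its numerically stable branch form. Decoding ties
(match probability exactly at threshold) are rejected, matching the
strict-inequality boundary rule.

## Known limitations

- The additive pair matcher cannot represent crossing same-category pair
  sets (detailed above).
- Training is single-process CPU NumPy; it is meant for desk-scale
  experiments and encoder-contract development, not for fine-tuning large
  pretrained encoders.
- No chance-corrected agreement coefficients; IAA is exact-match F1 only.
- Relaxed/partial span matching is out of scope; all scoring is exact
  match.
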