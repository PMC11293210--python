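# Methods

## Task and data model

A sentence is a sequence of atomic character tokens (no word segmentation;
Chinese clinical text has no whitespace words). A triple is
`(subject span, relation index, object span)` with 0-based inclusive spans;
a single-character entity has `head == tail`. Equality of triples is
component-wise, which is exactly the strict-match rule used in evaluation:
a predicted triple is correct only if both spans and the relation agree
with a gold triple of the same sentence.

## The single-module global-pointer codec

All `K` relations are tagged in one `L × K × L` tensor. A triple
`(s, k, o)` writes tag 1 at `(s.head, k, o.head)`, tag 2 at
`(s.tail, k, o.tail)` and tag 3 at `(s.head, k, o.tail)`. The tag-3 cell is
the anchor that pairs a head with a tail when a relation matrix contains
several entity pairs.

**Collisions.** Single-character entities collapse cells: a
single-character object merges the tag-1 and tag-3 cells; a
single-character subject merges tag-2 and tag-3; a pair of
single-character entities leaves one cell. Collisions are resolved by the
total priority `1 > 2 > 3 > 0`, applied both within a triple and across
triples. Only the 1-over-3 case is forced by the scheme's published
description; 2-over-3 and 1-over-2 follow from requiring that the
both-single-character case leave exactly one final tag that can be read
off directly. The resolution is a max under a total order, hence
commutative and associative: write order never matters.

**Decoding** applies four cases per relation slice, most specific first,
with absence guards so no tag pattern is consumed twice:

- **A (general)**: tag 3 at `(sh, ot)` joined with tag 1 in the same row
  (`oh ≤ ot`) and tag 2 in the same column (`st ≥ sh`).
- **B (single-char object)**: tag 1 above tag 2 in one column.
- **C (single-char subject)**: tag 1 left of tag 2 in one row.
- **D (both single-char)**: a tag 1 with no tag 2 in its row or column and
  no tag 3 in its row.

Spans are enforced forward (`st ≥ sh`, `ot ≥ oh`). Malformed tensors decode
to fewer triples, never to an error. A brute-force oracle
(`oracle_decode`) enumerates all `O(L⁴K)` candidate triples and checks
their collision-resolved cell patterns against the tensor; the guided
decoder is tested set-equal to it exhaustively at small sizes and on random
tensors.

**Known limitation (inherent to the scheme).** Two triples under the same
relation that share a subject span produce a spurious decodable triple:
the shared tag-1 of one triple cross-joins with the tag-3/tag-2 anchor of
the other. Likewise, one triple's cell can overwrite another's tag across
triples. Neither failure can be repaired at decode time; the synthetic
generator avoids the first by planting SEO pairs under distinct relations,
and exposes `reject_cross_triple_collisions` (on by default) to guarantee
`decode(encode(gold)) == gold` for every emitted sentence.

## Scoring head

For token vectors `e_i, e_j` of width `d`, the pair representation is
`ReLU(drop(W[e_i; e_j] + b))` with `W ∈ R^{d_e×2d}` — an asymmetric
concatenation projection (asymmetry is what distinguishes subject from
object). One projection through `R ∈ R^{d_e×4K}` yields scores for all
`K × 4` (relation, tag) combinations, grouped internally as `(K, 4)`; the
grouping is unobservable after reshaping. The head therefore computes
exactly `L²` pair representations per sentence (`L × 1 × L`), which the
instrumented loop path verifies. Dropout sits inside the ReLU on the
affine output, active only in training. Predicted tags are the per-cell
argmax over the four scores; ties break toward tag 0 (background), so an
untrained all-zero model predicts the empty triple set rather than
hallucinating.

`d_e` is a free width; the default is `d_e = 2d` (64 for the default
`d = 32`), chosen so the pair space is not a bottleneck relative to the
concatenated input.

## Encoder

The encoder is a contract: anything mapping tokens to one aligned
`d`-vector per token. The default desk-scale encoder is a character
embedding table (row 0 reserved for unknown characters) followed by two
centered convolution layers of radius 3 with ReLU — a receptive field of
±6 characters, enough to see entity boundaries and the composition of a
nested run. The method's novelty is downstream of the encoder, so a large
pretrained transformer is deliberately not required; an adapter producing
aligned vectors can be plugged in unchanged. Padded positions are zeroed
around every layer so batch padding cannot leak into windows.

## Training

The loss is per-cell categorical cross-entropy over the four tags — the
natural choice for a per-cell softmax — averaged with weights: background
cells (tag 0) carry `class_weight_background`, all others 1, normalized by
the total weight. Background dominates the tensor (a 30-character K=4
sentence has 3600 cells and typically under a dozen links), so the weight
knob controls the precision/recall balance: weight 1.0 is the neutral
default; the desk-scale experiments use 0.05, which balances the effective
mass of background and link cells at these sentence sizes (lower values
were observed to trade precision away). Optimization is Adam
(β₁ = 0.9, β₂ = 0.999). Gradients are exact analytic backprop through the
whole stack, verified against finite differences.

`TrainConfig` defaults (lr 1e-5, 50 epochs, batch 64, dropout 0.5,
max length 256) mirror the published full-scale recipe for the
transformer-encoder setting. The desk-scale synthetic experiments use
lr 3e-3, 30 epochs, batch 32, dropout 0.1 — a small from-scratch model
needs a larger step and less regularization than a fine-tuned 24-block
encoder. Sentences beyond `max_len` are truncated, dropping (and counting)
triples that touch truncated positions.

Runs are bit-reproducible under a fixed seed: one seeded generator drives
shuffling and dropout, and all kernels are deterministic numpy.

## Synthetic data: what it emulates and what it does not

The generator emulates the *structure* of CMeIE-style corpora: character
sentences up to a configurable length, K relations, 1–5+ triples per
sentence, Normal/SEO/EPO overlap (default mix 0.39/0.60/0.01, mirroring
the rough proportions of real medical IE corpora where overlap-bearing
sentences dominate and entity-pair overlap is rare), nested entities
(object as a marked prefix of its subject, probability 0.10) and
single-character entities (probability 0.15 by default).

To make parameter recovery well-posed, the vocabulary is partitioned into
disjoint character classes carrying (role, relation) assignments: filler;
per-relation subject and object classes; per-relation-pair EPO classes
(the entity pair carries both relations) and SEO subject classes (one
subject serving two relations). Entities are planted first and filler is
sampled around them, with at least one filler character between runs;
surface forms are unique within a sentence by default so substring
anchoring is unambiguous. Gold triples are then a deterministic local
function of the characters — which is precisely what a pair-scoring model
over contextual character vectors can learn.

In the default regime each relation has at most one subject-role and one
object-role run per sentence (capacity: K triples per sentence);
`unique_relation_roles=False` lifts the cap for codec stress tests, where
same-relation multi-pair sentences are kept only if they survive the
round-trip rejection check. Requesting more triples than capacity, EPO
with K = 1, or a vocabulary too small for the class partition fails before
generation.

What passing on this data does **not** show: robustness to real lexical
ambiguity (the same string acting as subject in one sentence and object in
another), segmentation noise, paraphrase, or the semantics of actual
medical relations. The generator is a span-structure emulator, not a
language model.

## Desk-scale experiment sizes

The parameter-recovery experiment trains the default encoder + head on
2000 synthetic sentences (K = 4, vocabulary 60, length ≤ 30, pattern mix
Normal 0.5 / SEO 0.3 / EPO 0.2 so every category is statistically
represented in 200 held-out sentences) for 30 epochs. Strict micro-F1 on
held-out data reaches ≈ 0.98–0.99 with per-category F1 ≥ 0.98; the codec
round-trip rate over generated corpora is 100%, and the decoder agrees
with the brute-force oracle on 100% of random tensors. These numbers are
recomputed, not stored, by `scripts/acceptance.py` and the test suite.

## Numerical and design notes

- Tag tensors serialize to a sparse JSON form (nonzero cells plus
  dimensions), losslessly.
- Checkpoints are single `.npz` files embedding the relation schema and
  encoder vocabulary; a loaded checkpoint reproduces predictions exactly.
- `score_all_pairs` refuses to allocate a score tensor beyond a
  configurable cell budget (default 1e8 cells) instead of exhausting
  memory.
- Anchoring policy for repeated surface strings is "first occurrence" by
  default, "all pairs" selectable; indices count code points.
- Overlap labels per sentence are not mutually exclusive: a sentence can
  be both SEO and EPO, and category breakdowns count it under each label
  it carries; Normal excludes the others. Two triples sharing both spans
  in *swapped* roles are counted as SEO, not EPO.
- Relations with no gold triples and no predictions report zero metrics
  flagged `absent` rather than being silently omitted.
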