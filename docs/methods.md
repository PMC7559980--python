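# Methods

## Problem setting

Emergency-department injury narratives are short (typically 5–25 tokens),
telegraphic, and noisy: abbreviations and acronyms are denser than in
general language, typos are frequent, and clause structure is routinely
broken. This rules out dependency parsing as a preprocessing step; every
stage of `violex` is therefore built from parser-free primitives: regular
expressions, dictionary lookup, shallow tag filters and word embeddings.

The system answers two questions per record: *is this injury
violence-related?* (binary categorization, classes V/NV) and, when yes,
*what does the text say about the event?* (a six-slot violence frame:
AGENT, MODE_INSTRUMENT, TIME, LOCATION, BODY_PART, LESION_TYPE, each with
zero or more token fillers).

## Cleaning

`normalize_punctuation` lowercases, collapses repeated punctuation and
whitespace, and inserts the missing space after sentence punctuation glued
to a following letter. It is total and idempotent; unmatched brackets are
left alone (tokenisation later removes punctuation anyway).

`apply_rewrites` expands a rewrite dictionary (surface → expansion, each
entry tagged abbreviation/acronym/typo) over whole tokens only, case-
insensitively, longest surface first. Validation rejects any dictionary in
which some surface form occurs as a whole token inside *any* expansion;
this is deliberately stronger than forbidding self-containment, because it
is the condition under which single-pass rewriting is idempotent. The
shipped fixture dictionary has 59 entries; the format is a user-editable
TSV, since the dictionary content is inherently deployment-specific.

Tokenisation strips punctuation and splits on whitespace. Curated
multiword locutions are then merged left-to-right, longest match first,
into underscore-joined *extended tokens* (`known_person`): noisy domain
text contains fixed phrases whose parts are meaningless alone, and the
merged token later bypasses the tag filters (its parts would not survive
them) while still needing a vector and a threshold-passing score.

## Tagging

A pluggable `Tagger` interface supplies two signals per token: one PoS tag
from a closed 9-tag set, and the supersenses of the token's most frequent
sense, drawn from the 41 coarse lexicographer categories (26 noun, 15
verb) plus `ADJ_ALL`. The most-frequent-sense heuristic is the standard
strong baseline for coarse word-sense disambiguation and keeps the system
deterministic and fast. The shipped backend is a TSV lexicon
(lemma / PoS / frequency-ranked supersense groups). Choices made where the
design was open:

* **OOV fallback**: unknown tokens are tagged NOUN (clinical OOV terms are
  overwhelmingly nominal) but get an *empty* supersense set, so they can
  never pass a supersense filter by accident. An unexpanded abbreviation
  therefore fails quietly rather than filling a slot wrongly.
* **Sense ties**: when a lemma's top-ranked senses tie across supersenses,
  the union is returned; filters ask for *at least one* compatible
  supersense, so a union only widens candidacy consistently.

## Embeddings and prototypes

Vectors are trained on the cleaned, locution-merged corpus itself with
skip-gram negative sampling: dimension 300, window 5 (dynamic), min-count
2, 5 negative samples from the unigram^0.75 distribution, 10 epochs,
initial learning rate 0.025 with linear decay, frequent-word subsampling at
t = 1e-3, logits clipped to ±6, updates applied in batches of 256 pairs.
The trainer is single-threaded numpy and exactly reproducible under a
seed. Subword n-grams are not used: the deterministic token→vector
contract is what the rest of the system consumes. The subsampling and
clipping are not cosmetic — without them, batched updates let very
frequent tokens blow up the parameter norms on small corpora.

Each frame field carries a seed-term list (defaults: husband, wife,
known_person / punch, aggression, knife / evening, night, today / home,
workplace / arm, head / fracture, contusion, trauma — prototypical fillers
of each role). The field's **prototype vector** is the arithmetic mean of
its in-vocabulary seed vectors; duplicated seeds weight the mean, letting a
user encode frequency by repetition. Missing seeds are recorded; a field
with no in-vocabulary seed is a configuration error.

## Categorization

The classifier is the fixed stack: trainable embedding (initialised from
the corpus skip-gram vectors, random rows for uncovered tokens, zero
padding row) → dropout 0.2 → 1-D convolution with 64 filters of kernel 5
and ReLU → max pooling with window 4 → LSTM with 100 units (forget-gate
bias initialised to 1) → one sigmoid unit. Training uses Adam (1e-3),
binary cross-entropy, batch 32, up to 10 epochs with early stopping on
validation loss (patience 2, best weights restored), on a stratified 80:20
train/validation split that preserves the class ratio to within one
record. The decision threshold on the sigmoid output is 0.5.

Sequences are truncated post to `max_sequence_length` (default 100) and
padded **pre**: with a last-hidden-state readout, post-padding would force
the LSTM to carry the narrative signal across dozens of content-free
steps, and on short narratives the model then collapses to the majority
class; pre-padding (the default in the common deep-learning toolkits'
padding utilities for exactly this reason) places the content next to the
readout. Everything — forward, backpropagation through the conv/pool/LSTM
stack, Adam — is implemented in numpy; the test suite checks the analytic
gradients of every parameter tensor against central differences, keeping
pre-activations away from the ReLU kink where the comparison is
ill-defined.

No class reweighting is applied by default despite the 3.36% prevalence;
the imbalance is part of the study conditions.

## Frame filling

For a record labelled V:

1. **Candidates** — the set of distinct tokens of the record (types, not
   positions), identical for every field.
2. **Pruning** — token kept for field *f* iff its PoS is in PoS_f *and* at
   least one most-frequent-sense supersense is in SST_f. The compatibility
   table: AGENT NOUN/NOUN_PERSON; MODE_INSTRUMENT NOUN/{OBJECT, ARTIFACT,
   STATE, SUBSTANCE, FEELING, ACT}; TIME NOUN/NOUN_TIME; LOCATION
   NOUN/NOUN_LOCATION; BODY_PART NOUN/NOUN_BODY; LESION_TYPE
   NOUN,ADJ/{NOUN_STATE, ADJ_ALL, NOUN_PHENOMENON}. Extended tokens bypass
   pruning.
3. **Ranking** — surviving candidates scored by cosine against the field
   prototype, descending, ties broken lexicographically; tokens without a
   vector are dropped (no similarity is computable).
4. **Resolution** — scores below the threshold (default 0.5) are
   discarded; a token surviving in several fields is kept only where its
   score is highest, cross-field ties going to the earlier field in schema
   order (AGENT first). All of a field's surviving tokens are reported
   (slots legitimately take multiple fillers); resolution order is prune →
   reassign → report.

The greedy per-token resolution provably equals the global
total-score-maximising assignment (token choices are independent), and the
test suite confirms it against exhaustive enumeration on 500 random
instances.

The **baseline** mode skips step 2 only; threshold and resolution are
preserved. Since pruning (with field-compatible gold) can only delete
non-gold candidates from a field's ranking, the filtered algorithm's
per-case AP and S@k are ≥ the baseline's by construction whenever the gold
fillers are tag-compatible with their own fields — the synthetic generator
guarantees that, so on synthetic corpora the main-vs-baseline comparison
is a structural invariant, not a statistical observation.

## Evaluation

Categorization: confusion counts and per-class precision/recall/F1 (NV
metrics come from the mirrored table). Frame filling is scored per field
over the post-prune rankings (not the thresholded output — S@5 needs
lists at least five deep): MAP (precision-at-hits summed over the ranking,
divided by the gold-set size, averaged over records), S@k (any gold filler
in the top k), R@5 (fraction of gold fillers in the top 5). Records whose
gold set for a field is empty are excluded from that field's denominator,
so denominators differ per field. Matching is exact string equality after
lowercasing, with multiword fillers compared in extended-token form.

## Synthetic data

The generator emulates the statistical shape of surveillance narratives:

* exact-quota class allocation at 3.36% violence prevalence (reproducible
  counts rather than Bernoulli noise);
* violence records instantiate slot-bearing templates, each slot filled
  with a probability matching annotated surveillance data (AGENT 0.60,
  MODE_INSTRUMENT 0.97, TIME 0.235, LOCATION 0.08, BODY_PART 0.895,
  LESION_TYPE 0.865) from per-field inventories sampled Zipf-style
  (exponent 1.5) so a few fillers dominate, as in real corpora; the gold
  frame is recorded before noise;
* non-violence records use accident templates sharing the time / location /
  lesion / body-part vocabulary;
* noise: expansions are replaced by their dictionary abbreviations with a
  steep-Zipfian profile over entries (rate 0.3, calibrated to roughly one
  substitution per record, the density reported for real surveillance
  text), character-level typos at rate 0.02 on the noisy side only (logged
  per record so tests can condition on them), and occasional spacing/comma
  damage (rate 0.1).

What it does **not** emulate: real clinical vocabulary breadth, ambiguous
agents (a *father* reporting an assault by a *husband*), multi-filler gold
slots, cross-lingual issues, or genuinely hard class boundaries — every
synthetic violence record contains a violence-marker verb that no accident
record contains, so the classifier benchmark is linearly separable by
construction. Green classifier tests therefore demonstrate that the
architecture, training loop and data plumbing work, not that real-world
F1 would be high; likewise the near-ceiling frame metrics reflect the
generator's clean slot structure, and the meaningful signal is the
main-vs-baseline margin, not the absolute level.

## Numerical and engineering choices

* All randomness flows through explicit integer seeds; training and the
  full pipeline are byte-reproducible single-threaded.
* Cosine similarity rejects zero vectors and dimension mismatches rather
  than guessing.
* Benchmark problem sizes (5,000-record corpora for cleaning and frame
  evaluation, 2,000 records for classifier training, 300 for the
  determinism check) were chosen so the whole suite and the acceptance
  script each run in minutes on one CPU while keeping ≥100 violence
  records in the frame evaluation.
* Model checkpoints are numpy archives plus a JSON sidecar; embeddings
  persist in the word2vec text format.

## Known limitations

* The rewrite dictionary is the only typo defence; out-of-dictionary
  abbreviations survive cleaning and then (correctly but silently) fail
  frame filling — visible in the worked example.
* Competing person mentions cannot be disambiguated without syntax; the
  AGENT slot takes the embedding-closest person, which can be wrong.
* The most-frequent-sense heuristic ignores context entirely; polysemous
  fillers with a non-dominant intended sense are pruned or kept wrongly.
* Rare tokens (below the embedding min-count) can never fill a slot.
* The CLI trains on one CPU; at a few hundred thousand records the numpy
  classifier is workable but slow compared to GPU-backed toolkits.
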