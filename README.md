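# violex

Violence-event detection and frame-based explanation for emergency-room
narratives.

Injury-surveillance systems collect short free-text narratives written by
hospital staff under time pressure: telegraphic clauses, heavy abbreviation,
typos, broken punctuation. Violence-related injuries (domestic violence in
particular) are systematically under-reported in the structured fields, so a
useful surveillance tool must (a) *find* the violence-related records among
overwhelmingly accidental ones, and (b) *explain* each positive call in
terms a public-health analyst can audit: who committed the violence, how,
when, where, which body part was harmed, and what lesion resulted.

`violex` implements that pipeline for researchers and surveillance analysts:

1. **Cleaning** — regex punctuation repair plus whole-token expansion of a
   curated abbreviation/acronym/typo dictionary (TSV, user-replaceable).
2. **Categorization** — a convolutional-recurrent network over the cleaned
   text: embedding layer (300-d skip-gram vectors trained on the corpus
   itself) → 20% dropout → 1-D convolution (64 filters, kernel 5, ReLU) →
   max pooling (window 4) → LSTM (100 units) → sigmoid, trained with Adam on
   binary cross-entropy. Implemented in pure numpy with hand-written
   backpropagation, verified against numerical gradients.
3. **Explanation** — a six-slot *violence frame* (AGENT, MODE_INSTRUMENT,
   TIME, LOCATION, BODY_PART, LESION_TYPE). Every distinct token of a
   violence-labelled record is a candidate for every slot; candidates are
   pruned by part-of-speech and supersense compatibility (a
   most-frequent-sense lexicon over the 41 WordNet lexicographer
   categories), ranked by cosine similarity against each slot's *prototype
   vector* (the mean embedding of its seed filler terms, f̂), thresholded at
   cosine ≥ 0.5, and assigned uniquely to the closest slot. Multiword
   locutions (`known_person`) are merged into extended tokens that bypass
   the filters.
4. **Evaluation** — per-class precision/recall/F1 for categorization;
   per-slot MAP, S@1, S@5 and R@5 for frame filling, including the
   similarity-only (no-filter) baseline comparison.
5. **Synthetic data** — real surveillance narratives are access-restricted,
   so the package ships a generator that emulates their shape: 3.36%
   violence prevalence, per-slot gold fill rates (AGENT 60%, MODE 97%, TIME
   23.5%, LOCATION 8%, BODY_PART 89.5%, LESION_TYPE 86.5%), and a
   steep-Zipfian abbreviation/typo noise layer driven by the rewrite
   dictionary run in reverse — so cleaning is exactly invertible when only
   abbreviation noise is applied.

## Worked example

```bash
python examples/03_explain_with_frames.py
```

trains 100-d skip-gram vectors on a 2,000-record synthetic corpus, then
cleans and explains one noisy narrative:

```
narrative: tngt pt beaten by hsbnd with a btl at hm, suffers fx of the wrst
cleaned:   tngt patient beaten by husband with a bottle at home suffers fracture of the wrist

with PoS/SST filters
  AGENT            husband (1.00)
  MODE_INSTRUMENT  -
  TIME             -
  LOCATION         home (0.97)
  BODY_PART        wrist (0.84)
  LESION_TYPE      fracture (0.98)

baseline (no filters)
  AGENT            husband (1.00), beaten (0.99), with (0.61), a (0.57), of (0.52)
  MODE_INSTRUMENT  by (0.99), suffers (0.96)
  ...
```

Scores in parentheses are cosine similarities to the slot prototype. The
filtered run fills four slots correctly; the baseline lets function words
crowd the rankings. Two realistic failures are visible: `tngt` is missing
from the rewrite dictionary so TIME stays empty, and `bottle` occurs too
rarely in this small corpus to have a vector, so it cannot be ranked.

The other examples cover cleaning (`01`), classifier training (`02` — on the
separable synthetic benchmark it reaches validation F1 of 1.000 for both
classes), and the main-vs-baseline evaluation (`04`), which prints per-slot
rows like:

```
field              n   MAP (base->main)   S@1 (base->main)
AGENT             42   0.83 -> 0.88        0.79 -> 0.88
MODE_INSTRUMENT   62   0.89 -> 0.94        0.84 -> 0.94
```

The command-line interface exposes each stage (`violex synth | clean |
train-embeddings | train-classifier | classify | explain | eval | run`);
`violex run` executes the full pipeline and writes one enriched JSONL row
per record, frames attached only to violence-labelled records.

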