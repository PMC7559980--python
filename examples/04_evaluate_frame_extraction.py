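"""Score frame extraction (main vs baseline) on a synthetic gold corpus with
ranked-retrieval metrics: MAP, S@1, S@5, R@5 per frame field."""

import violex as vx
from violex.frames import build_prototypes
from violex.evaluation import evaluate_frames

records = vx.generate_corpus(vx.GeneratorConfig(n_records=2000, seed=13))
dictionary = vx.default_dictionary()
mwe = vx.default_mwe_list()
sequences = [vx.preprocess(r.text, dictionary, mwe) for r in records]
embeddings = vx.train_embeddings(sequences, dimension=100, seed=2)

schema = vx.default_schema()
tagger = vx.default_tagger()
prototypes = build_prototypes(schema, embeddings)

pred = {True: {}, False: {}}
gold = {}
for rec, seq in zip(records, sequences):
    if rec.label != "V":
        continue
    for use_filters in (True, False):
        frame = vx.extract_frame(seq, schema, embeddings, tagger,
                                 prototypes=prototypes, use_filters=use_filters)
        pred[use_filters][rec.id] = {
            f: [t for t, _ in entries] for f, entries in frame.rankings.items()
        }
    gold[rec.id] = rec.gold_frame

print(f"evaluated violence records: {len(gold)}")
print(f"{'field':16s} {'n':>3s}   MAP (base->main)   S@1 (base->main)")
main = evaluate_frames(pred[True], gold, schema.field_names)
base = evaluate_frames(pred[False], gold, schema.field_names)
for f in schema.field_names:
    m, b = main[f], base[f]
    print(f"{f:16s} {m.n_cases:3d}   {b.map:.2f} -> {m.map:.2f}"
          f"        {b.s_at_1:.2f} -> {m.s_at_1:.2f}")
print()
print("n differs per field because a field only counts records where its gold")
print("slot was actually filled.  The filtered algorithm should match or beat")
print("the similarity-only baseline in every row: pruning removes only")
print("candidates that are grammatically or semantically incompatible.")
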