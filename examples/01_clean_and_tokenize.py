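"""Clean a noisy narrative: punctuation repair, abbreviation expansion,
tokenisation and locution merging."""

import violex as vx

raw = "This afternoon assaulted by known person,suffers  tr dist aass rt occ region ((fist), loss of consciousness denied"

dictionary = vx.default_dictionary()
normalized = vx.normalize_punctuation(raw)
rewritten, n_subs = vx.apply_rewrites(normalized, dictionary)
tokens = vx.mark_extended_tokens(vx.tokenize(rewritten), vx.default_mwe_list())

print("raw:       ", raw)
print("normalized:", normalized)
print("rewritten: ", rewritten, f"({n_subs} substitutions)")
print("tokens:    ", [t.surface + ("*" if t.is_extended else "") for t in tokens])
print()
print("Abbreviations in the dictionary (tr, rt, occ) were expanded; the unknown")
print("abbreviation 'aass' passed through unchanged; 'known person' and 'loss of")
print("consciousness' were merged into extended tokens (marked *).")
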