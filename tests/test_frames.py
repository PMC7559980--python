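import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from violex import (
    ConfigError,
    EmbeddingModel,
    FieldSpec,
    PosTag,
    build_prototype,
    extract_frame,
    generate_candidates,
    prune_candidates,
    rank_candidates,
    resolve_assignments,
)
from violex.frames import FIELD_NAMES, CandidateRanking
from violex.lexicon import LexiconEntry, LexiconTagger
from violex.textprep import Token, TokenSequence, mark_extended_tokens, tokenize


def ranking(field, entries):
    return CandidateRanking(field=field, entries=entries)


class TestGenerateCandidates:
    def test_empty_record(self):
        assert generate_candidates(TokenSequence([])) == {}

    def test_duplicates_collapse(self):
        cands = generate_candidates(TokenSequence(["fist", "fist", "trauma"]))
        assert set(cands) == {"fist", "trauma"}

    def test_identical_for_every_field(self, schema):
        seq = tokenize("husband punch arm evening")
        per_field = [set(generate_candidates(seq, f)) for f in schema.fields]
        assert all(c == per_field[0] for c in per_field)


class TestPruneCandidates:
    def test_agent_keeps_person_nouns(self, schema, tagger):
        spec = schema.field("AGENT")
        cands = {"husband": Token("husband")}
        tags = {"husband": PosTag.NOUN}
        assert "husband" in prune_candidates(cands, spec, tags, tagger)

    def test_body_part_rejects_person(self, schema, tagger):
        spec = schema.field("BODY_PART")
        cands = {"husband": Token("husband")}
        tags = {"husband": PosTag.NOUN}
        assert prune_candidates(cands, spec, tags, tagger) == {}

    def test_oov_token_pruned_everywhere(self, schema, tagger):
        cands = {"aass": Token("aass")}
        tags = {"aass": PosTag.NOUN}
        for spec in schema.fields:
            assert prune_candidates(cands, spec, tags, tagger) == {}

    def test_extended_token_bypasses_filters(self, schema, tagger):
        tok = Token("known_person", is_extended=True)
        cands = {"known_person": tok}
        for spec in schema.fields:
            assert "known_person" in prune_candidates(cands, spec, {}, tagger)

    def test_verbs_fail_noun_only_fields(self, schema, tagger):
        cands = {"denies": Token("denies")}
        tags = {"denies": PosTag.VERB}
        assert prune_candidates(cands, schema.field("AGENT"), tags, tagger) == {}

    def test_adjective_allowed_for_lesion_type(self, schema, tagger):
        cands = {"occipital": Token("occipital")}
        tags = {"occipital": PosTag.ADJECTIVE}
        kept = prune_candidates(cands, schema.field("LESION_TYPE"), tags, tagger)
        assert "occipital" in kept

    def test_matches_bruteforce_filter_on_lexicon(self, schema, tagger):
        """Spot-check the pruning rule against a direct re-statement of it."""
        words = ["husband", "punch", "evening", "home", "arm", "fracture",
                 "stone", "patient", "denies", "occipital", "zzz"]
        seq = TokenSequence(words)
        tags = dict(tagger.pos_tag(seq))
        for spec in schema.fields:
            kept = set(prune_candidates(generate_candidates(seq), spec, tags, tagger))
            expected = {
                w for w in words
                if tags[w] in spec.allowed_pos
                and tagger.most_frequent_supersenses(w) & spec.allowed_sst
            }
            assert kept == expected


class TestRankCandidates:
    def _proto(self, vec):
        from violex.embedding import FieldPrototype

        return FieldPrototype(field="F", seed_terms=["s"], vector=np.asarray(vec, float))

    def test_empty_candidates(self):
        model = EmbeddingModel(["a"], np.array([[1.0, 0.0]]))
        r = rank_candidates({}, self._proto([1.0, 0.0]), model)
        assert r.entries == []

    def test_vector_equal_to_prototype_ranks_first(self):
        model = EmbeddingModel(
            ["same", "other"], np.array([[2.0, 0.0], [1.0, 1.0]])
        )
        r = rank_candidates(
            {"same": Token("same"), "other": Token("other")},
            self._proto([1.0, 0.0]),
            model,
        )
        assert r.entries[0][0] == "same"
        assert r.entries[0][1] == pytest.approx(1.0)

    def test_order_matches_hand_computed_cosines(self):
        vecs = {"a": [1.0, 0.0], "b": [1.0, 1.0], "c": [0.0, 1.0]}
        model = EmbeddingModel(sorted(vecs), np.array([vecs[k] for k in sorted(vecs)]))
        r = rank_candidates(
            {k: Token(k) for k in vecs}, self._proto([1.0, 0.0]), model
        )
        assert [t for t, _ in r.entries] == ["a", "b", "c"]
        assert [round(s, 4) for _, s in r.entries] == [1.0, 0.7071, 0.0]

    def test_tokens_without_vectors_dropped(self):
        model = EmbeddingModel(["a"], np.array([[1.0, 0.0]]))
        r = rank_candidates(
            {"a": Token("a"), "missing": Token("missing")},
            self._proto([1.0, 0.0]),
            model,
        )
        assert [t for t, _ in r.entries] == ["a"]


def bruteforce_resolve(rankings, threshold, field_order=FIELD_NAMES):
    """Independent oracle: enumerate every complete assignment of tokens to
    at-most-one surviving field and pick the total-score maximiser, breaking
    ties toward earlier fields in schema order."""
    surviving = {
        f: {t: s for t, s in r.entries if s >= threshold} for f, r in rankings.items()
    }
    order = [f for f in field_order if f in rankings]
    tokens = sorted({t for f in order for t in surviving[f]})
    options = [[f for f in order if t in surviving[f]] for t in tokens]
    best = None
    for combo in itertools.product(*options):
        score = sum(surviving[f][t] for t, f in zip(tokens, combo))
        # earlier fields preferred on ties: lexicographic on field indices
        tie_key = tuple(order.index(f) for f in combo)
        key = (-score, tie_key)
        if best is None or key < best[0]:
            best = (key, combo)
    assignment = {} if best is None else dict(zip(tokens, best[1]))
    return {
        f: sorted(
            ((t, s) for t, s in surviving[f].items() if assignment.get(t) == f),
            key=lambda e: (-e[1], e[0]),
        )
        for f in order
    }


class TestResolveAssignments:
    def test_all_below_threshold_gives_empty_frame(self):
        rankings = {f: ranking(f, [("tok", 0.2)]) for f in FIELD_NAMES}
        frame = resolve_assignments(rankings, 0.5)
        assert all(v == [] for v in frame.fillers.values())

    def test_below_threshold_token_excluded(self):
        rankings = {f: ranking(f, []) for f in FIELD_NAMES}
        rankings["BODY_PART"] = ranking("BODY_PART", [("occipital", 0.41)])
        frame = resolve_assignments(rankings, 0.5)
        assert frame.fillers["BODY_PART"] == []
        # but the ranking itself is preserved for inspection
        assert frame.rankings["BODY_PART"] == [("occipital", 0.41)]

    def test_token_goes_to_highest_scoring_field(self):
        rankings = {f: ranking(f, []) for f in FIELD_NAMES}
        rankings["AGENT"] = ranking("AGENT", [("tok", 0.7)])
        rankings["MODE_INSTRUMENT"] = ranking("MODE_INSTRUMENT", [("tok", 0.6)])
        frame = resolve_assignments(rankings, 0.5)
        assert frame.fillers["AGENT"] == [("tok", 0.7)]
        assert frame.fillers["MODE_INSTRUMENT"] == []

    def test_cross_field_tie_breaks_by_schema_order(self):
        rankings = {f: ranking(f, []) for f in FIELD_NAMES}
        rankings["TIME"] = ranking("TIME", [("tok", 0.8)])
        rankings["LOCATION"] = ranking("LOCATION", [("tok", 0.8)])
        frame = resolve_assignments(rankings, 0.5)
        assert frame.fillers["TIME"] == [("tok", 0.8)]
        assert frame.fillers["LOCATION"] == []

    def test_agrees_with_exhaustive_enumeration(self):
        """Greedy per-token assignment equals the global brute-force optimum
        on 500 random instances with ≤8 distinct tokens."""
        rng = np.random.default_rng(42)
        for _ in range(500):
            n_tok = int(rng.integers(0, 9))
            tokens = [f"w{i}" for i in range(n_tok)]
            rankings = {}
            for f in FIELD_NAMES:
                entries = []
                for t in tokens:
                    if rng.random() < 0.5:
                        entries.append((t, float(np.round(rng.random(), 3))))
                entries.sort(key=lambda e: (-e[1], e[0]))
                rankings[f] = ranking(f, entries)
            thr = float(rng.choice([0.0, 0.3, 0.5, 0.7]))
            got = resolve_assignments(rankings, thr).fillers
            want = bruteforce_resolve(rankings, thr)
            assert got == want

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 10_000))
    def test_uniqueness_and_threshold_monotonicity(self, case_seed):
        rng = np.random.default_rng(case_seed)
        tokens = [f"w{i}" for i in range(int(rng.integers(1, 7)))]
        rankings = {}
        for f in FIELD_NAMES:
            entries = sorted(
                ((t, float(np.round(rng.random(), 3))) for t in tokens
                 if rng.random() < 0.6),
                key=lambda e: (-e[1], e[0]),
            )
            rankings[f] = ranking(f, entries)
        lo = resolve_assignments(rankings, 0.3)
        hi = resolve_assignments(rankings, 0.6)
        # no token fills two fields
        seen = [t for fillers in lo.fillers.values() for t, _ in fillers]
        assert len(seen) == len(set(seen))
        # raising the threshold never increases the filler count
        assert sum(len(v) for v in hi.fillers.values()) <= sum(
            len(v) for v in lo.fillers.values()
        )


class TestExtractFrame:
    @pytest.fixture
    def crafted_tagger(self):
        """Telegraphic-style lexicon for the worked sentence: every gold
        filler carries the PoS/supersense its field requires."""
        entries = {
            "tonight": LexiconEntry("tonight", PosTag.NOUN, [{"NOUN_TIME"}]),
            "husband": LexiconEntry("husband", PosTag.NOUN, [{"NOUN_PERSON"}]),
            "punched": LexiconEntry("punched", PosTag.NOUN, [{"NOUN_ACT"}]),
            "home": LexiconEntry("home", PosTag.NOUN, [{"NOUN_LOCATION"}]),
            "arm": LexiconEntry("arm", PosTag.NOUN, [{"NOUN_BODY"}]),
            "fracture": LexiconEntry("fracture", PosTag.NOUN, [{"NOUN_STATE"}]),
            "causing": LexiconEntry("causing", PosTag.VERB, [{"VERB_CREATION"}]),
        }
        return LexiconTagger(entries)

    def test_recovers_all_six_slots(self, schema, axis_embedding, crafted_tagger):
        seq = tokenize("tonight husband punched her at home causing a fracture on the arm")
        frame = extract_frame(seq, schema, axis_embedding, crafted_tagger)
        top = {f: fillers[0][0] for f, fillers in frame.fillers.items() if fillers}
        assert top == {
            "TIME": "tonight",
            "AGENT": "husband",
            "MODE_INSTRUMENT": "punched",
            "LOCATION": "home",
            "BODY_PART": "arm",
            "LESION_TYPE": "fracture",
        }

    def test_empty_record_gives_empty_frame(self, schema, axis_embedding, tagger):
        frame = extract_frame(TokenSequence([]), schema, axis_embedding, tagger)
        assert all(v == [] for v in frame.fillers.values())

    def test_baseline_rankings_are_supersets(self, schema, axis_embedding, crafted_tagger):
        seq = tokenize("tonight husband punched her at home causing a fracture on the arm")
        main = extract_frame(seq, schema, axis_embedding, crafted_tagger, use_filters=True)
        base = extract_frame(seq, schema, axis_embedding, crafted_tagger, use_filters=False)
        for f in schema.field_names:
            main_toks = {t for t, _ in main.rankings[f]}
            base_toks = {t for t, _ in base.rankings[f]}
            assert main_toks <= base_toks

    def test_extended_token_can_fill_despite_filters(self, schema, axis_embedding, tagger):
        seq = mark_extended_tokens(tokenize("assaulted by known person"), ["known person"])
        frame = extract_frame(seq, schema, axis_embedding, tagger)
        assert ("known_person", pytest.approx(1.0, abs=0.05)) in [
            (t, s) for t, s in frame.fillers["AGENT"]
        ]

    def test_missing_prototype_raises(self, schema, axis_embedding, tagger):
        with pytest.raises(ConfigError):
            extract_frame(
                tokenize("husband"), schema, axis_embedding, tagger,
                prototypes={},  # no prototype for any field
            )
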