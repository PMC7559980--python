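"""The explanation engine: fill the six-slot violence frame for a record.

A violence event is represented as a frame with six fields — AGENT,
MODE_INSTRUMENT, TIME, LOCATION, BODY_PART, LESION_TYPE.  For a record
categorised as violence-related, each field is filled by:

1. *candidate generation* — every distinct token of the record is a
   candidate for every field;
2. *compatibility pruning* — a candidate survives for field ``f`` only if
   its PoS is allowed for ``f`` AND at least one supersense of its most
   frequent sense is allowed for ``f``; extended tokens (merged locutions
   such as ``known_person``) bypass this filter;
3. *prototype ranking* — surviving candidates are ranked by cosine
   similarity against the field's prototype vector (the mean embedding of
   its seed filler terms);
4. *assignment resolution* — candidates scoring below the similarity
   threshold are discarded, and a token still competing for several fields
   is kept only in the field where it scores highest.

Skipping step 2 gives the similarity-only baseline used for comparison.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError
from .embedding import EmbeddingModel, FieldPrototype, build_prototype, cosine_similarity
from .lexicon import PosTag, SUPERSENSES, Tagger
from .textprep import Token, TokenSequence

__all__ = [
    "FIELD_NAMES",
    "FieldSpec",
    "FrameSchema",
    "CandidateRanking",
    "FilledFrame",
    "default_schema",
    "generate_candidates",
    "prune_candidates",
    "rank_candidates",
    "resolve_assignments",
    "extract_frame",
]

#: schema order; also the tie-break order for cross-field assignment
FIELD_NAMES = (
    "AGENT",
    "MODE_INSTRUMENT",
    "TIME",
    "LOCATION",
    "BODY_PART",
    "LESION_TYPE",
)


@dataclass
class FieldSpec:
    """One frame field with its compatibility sets and prototype seeds."""

    name: str
    allowed_pos: set[PosTag]
    allowed_sst: set[str]
    seed_terms: list[str]

    def __post_init__(self) -> None:
        if not self.allowed_pos or not self.allowed_sst:
            raise ConfigError(f"field {self.name!r}: empty compatibility set")
        self.allowed_pos = {PosTag(p) for p in self.allowed_pos}
        bad = set(self.allowed_sst) - SUPERSENSES
        if bad:
            raise ConfigError(f"field {self.name!r}: unknown supersenses {sorted(bad)}")
        if not self.seed_terms:
            raise ConfigError(f"field {self.name!r}: empty seed-term list")


@dataclass
class FrameSchema:
    """The ordered six-field schema plus the similarity threshold."""

    fields: list[FieldSpec]
    similarity_threshold: float = 0.5

    def __post_init__(self) -> None:
        names = [f.name for f in self.fields]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate field names in frame schema")
        if not (0.0 < self.similarity_threshold <= 1.0):
            raise ConfigError(
                f"similarity threshold must be in (0, 1], got {self.similarity_threshold}"
            )

    @property
    def field_names(self) -> list[str]:
        return [f.name for f in self.fields]

    def field(self, name: str) -> FieldSpec:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)

    # --- serialisation -----------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "FrameSchema":
        fields = []
        for fd in d["fields"]:
            fields.append(
                FieldSpec(
                    name=str(fd["name"]).upper(),
                    allowed_pos={PosTag[p.upper()] for p in fd["allowed_pos"]},
                    allowed_sst={str(s).upper() for s in fd["allowed_sst"]},
                    seed_terms=[str(t).lower() for t in fd["seed_terms"]],
                )
            )
        return cls(fields=fields,
                   similarity_threshold=float(d.get("similarity_threshold", 0.5)))

    def to_dict(self) -> dict:
        return {
            "similarity_threshold": self.similarity_threshold,
            "fields": [
                {
                    "name": f.name,
                    "allowed_pos": sorted(p.value for p in f.allowed_pos),
                    "allowed_sst": sorted(f.allowed_sst),
                    "seed_terms": list(f.seed_terms),
                }
                for f in self.fields
            ],
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FrameSchema":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_schema() -> FrameSchema:
    """The shipped schema: compatibility table and seed terms per field."""
    resource = importlib.resources.files("violex.resources").joinpath("schema.yaml")
    with importlib.resources.as_file(resource) as path:
        return FrameSchema.from_yaml(path)


@dataclass
class CandidateRanking:
    """Filtered candidates of one field, sorted by descending similarity."""

    field: str
    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        tokens = [t for t, _ in self.entries]
        if len(set(tokens)) != len(tokens):
            raise ConfigError(f"duplicate tokens in ranking for {self.field}")

    def top(self, k: int) -> list[str]:
        return [t for t, _ in self.entries[:k]]


@dataclass
class FilledFrame:
    """Per-field fillers (token, score) plus the full rankings they came from."""

    fillers: dict[str, list[tuple[str, float]]] = dc_field(default_factory=dict)
    rankings: dict[str, list[tuple[str, float]]] = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "frame": {
                f: [{"token": t, "score": round(s, 6)} for t, s in fillers]
                for f, fillers in self.fillers.items()
            },
            "rankings": {
                f: [{"token": t, "score": round(s, 6)} for t, s in entries]
                for f, entries in self.rankings.items()
            },
        }


# --- the four stages -------------------------------------------------------


def generate_candidates(seq: TokenSequence, field: FieldSpec | None = None) -> dict[str, Token]:
    """All distinct tokens of the record; identical for every field."""
    out: dict[str, Token] = {}
    for tok in seq:
        out.setdefault(tok.surface, tok)
    return out


def prune_candidates(
    candidates: Mapping[str, Token],
    field: FieldSpec,
    pos_tags: Mapping[str, PosTag],
    tagger: Tagger,
) -> dict[str, Token]:
    """Keep candidates PoS- and supersense-compatible with the field.

    Extended tokens always survive: a merged locution has no lexicon entry,
    and the locution list is curated precisely because its members are known
    good fillers.
    """
    kept: dict[str, Token] = {}
    for surface, tok in candidates.items():
        if tok.is_extended:
            kept[surface] = tok
            continue
        pos = pos_tags.get(surface)
        if pos is None or pos not in field.allowed_pos:
            continue
        ssts = tagger.most_frequent_supersenses(surface)
        if ssts & field.allowed_sst:
            kept[surface] = tok
    return kept


def rank_candidates(
    candidates: Mapping[str, Token],
    prototype: FieldPrototype,
    model: EmbeddingModel,
) -> CandidateRanking:
    """Score candidates by cosine against the field prototype, best first.

    Tokens without a vector cannot be scored and are dropped (the fate of
    unexpanded abbreviations that never reached the embedding vocabulary).
    Ties break lexicographically for determinism.
    """
    scored: list[tuple[str, float]] = []
    for surface in candidates:
        vec = model.get(surface)
        if vec is None:
            continue
        scored.append((surface, cosine_similarity(vec, prototype.vector)))
    scored.sort(key=lambda e: (-e[1], e[0]))
    return CandidateRanking(field=prototype.field, entries=scored)


def resolve_assignments(
    rankings: Mapping[str, CandidateRanking] | Sequence[CandidateRanking],
    threshold: float,
    field_order: Sequence[str] = FIELD_NAMES,
) -> FilledFrame:
    """Threshold then uniquely assign each surviving token to its best field.

    Step 1 drops every entry scoring below ``threshold``.  Step 2: a token
    surviving in several fields is kept only where its score is highest;
    score ties break by schema field order.  Each field keeps all of its
    surviving tokens, sorted by descending score.
    """
    if not isinstance(rankings, Mapping):
        rankings = {r.field: r for r in rankings}
    order = [f for f in field_order if f in rankings] + [
        f for f in rankings if f not in field_order
    ]

    surviving: dict[str, list[tuple[str, float]]] = {
        f: [(t, s) for t, s in rankings[f].entries if s >= threshold] for f in order
    }
    # best field per token: highest score, then earliest field in schema order
    best_field: dict[str, tuple[float, int]] = {}
    for rank_idx, f in enumerate(order):
        for t, s in surviving[f]:
            cur = best_field.get(t)
            if cur is None or (s, -rank_idx) > (cur[0], -cur[1]):
                best_field[t] = (s, rank_idx)

    fillers = {
        f: sorted(
            ((t, s) for t, s in surviving[f] if best_field[t][1] == rank_idx),
            key=lambda e: (-e[1], e[0]),
        )
        for rank_idx, f in enumerate(order)
    }
    return FilledFrame(
        fillers=fillers,
        rankings={f: list(rankings[f].entries) for f in order},
    )


def build_prototypes(
    schema: FrameSchema, model: EmbeddingModel
) -> dict[str, FieldPrototype]:
    return {f.name: build_prototype(f.name, f.seed_terms, model) for f in schema.fields}


def extract_frame(
    seq: TokenSequence,
    schema: FrameSchema,
    model: EmbeddingModel,
    tagger: Tagger,
    prototypes: Mapping[str, FieldPrototype] | None = None,
    use_filters: bool = True,
    threshold: float | None = None,
) -> FilledFrame:
    """Run generate → prune → rank → resolve for one tokenised record.

    With ``use_filters=False`` the PoS/supersense pruning is skipped and the
    ranking relies on semantic similarity alone (the comparison baseline);
    the similarity threshold is kept in both modes.
    """
    if prototypes is None:
        prototypes = build_prototypes(schema, model)
    thr = schema.similarity_threshold if threshold is None else threshold

    pos_tags = dict(tagger.pos_tag(seq))
    candidates = generate_candidates(seq)
    rankings: dict[str, CandidateRanking] = {}
    for spec in schema.fields:
        proto = prototypes.get(spec.name)
        if proto is None:
            raise ConfigError(f"no prototype for field {spec.name!r}")
        cand = (
            prune_candidates(candidates, spec, pos_tags, tagger)
            if use_filters
            else dict(candidates)
        )
        rankings[spec.name] = rank_candidates(cand, proto, model)
    return resolve_assignments(rankings, thr, field_order=schema.field_names)
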