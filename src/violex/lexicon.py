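"""Part-of-speech and supersense tagging through a pluggable backend.

The frame-filling filters need two shallow linguistic signals per token:

* its part of speech (closed 9-tag set), and
* the supersenses of its *most frequent* sense — the classic most-frequent-
  sense baseline over the 41 coarse lexicographer categories (26 noun, 15
  verb) plus ``ADJ_ALL`` for adjectives.

Narrative ER text is too noisy for a parser, so the shipped backend is a
deterministic lexicon lookup loaded from TSV; any contextual tagger can be
plugged in by implementing :class:`Tagger`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Protocol, runtime_checkable

from .errors import ConfigError
from .textprep import Token, TokenSequence


class PosTag(str, Enum):
    NOUN = "NOUN"
    VERB = "VERB"
    ADJECTIVE = "ADJECTIVE"
    ADVERB = "ADVERB"
    PRONOUN = "PRONOUN"
    PREPOSITION = "PREPOSITION"
    CONJUNCTION = "CONJUNCTION"
    ARTICLE = "ARTICLE"
    OTHER = "OTHER"


#: the 26 noun + 15 verb lexicographer categories, plus the adjective catch-all
NOUN_SUPERSENSES = frozenset(
    {
        "NOUN_TOPS", "NOUN_ACT", "NOUN_ANIMAL", "NOUN_ARTIFACT", "NOUN_ATTRIBUTE",
        "NOUN_BODY", "NOUN_COGNITION", "NOUN_COMMUNICATION", "NOUN_EVENT",
        "NOUN_FEELING", "NOUN_FOOD", "NOUN_GROUP", "NOUN_LOCATION", "NOUN_MOTIVE",
        "NOUN_OBJECT", "NOUN_PERSON", "NOUN_PHENOMENON", "NOUN_PLANT",
        "NOUN_POSSESSION", "NOUN_PROCESS", "NOUN_QUANTITY", "NOUN_RELATION",
        "NOUN_SHAPE", "NOUN_STATE", "NOUN_SUBSTANCE", "NOUN_TIME",
    }
)
VERB_SUPERSENSES = frozenset(
    {
        "VERB_BODY", "VERB_CHANGE", "VERB_COGNITION", "VERB_COMMUNICATION",
        "VERB_COMPETITION", "VERB_CONSUMPTION", "VERB_CONTACT", "VERB_CREATION",
        "VERB_EMOTION", "VERB_MOTION", "VERB_PERCEPTION", "VERB_POSSESSION",
        "VERB_SOCIAL", "VERB_STATIVE", "VERB_WEATHER",
    }
)
ADJ_SUPERSENSE = "ADJ_ALL"
SUPERSENSES = NOUN_SUPERSENSES | VERB_SUPERSENSES | {ADJ_SUPERSENSE}

assert len(NOUN_SUPERSENSES) == 26 and len(VERB_SUPERSENSES) == 15


@dataclass
class LexiconEntry:
    """One lemma with its PoS and frequency-ranked supersense groups.

    ``sense_ranks`` is an ordered list of sets: rank 0 holds the supersense(s)
    of the most frequent sense (a set because equally frequent senses tie),
    later ranks the less frequent senses.
    """

    lemma: str
    pos: PosTag
    sense_ranks: list[set[str]]

    def __post_init__(self) -> None:
        if not self.sense_ranks or not any(self.sense_ranks):
            raise ConfigError(f"lexicon entry {self.lemma!r} has no supersenses")
        for group in self.sense_ranks:
            unknown = group - SUPERSENSES
            if unknown:
                raise ConfigError(
                    f"lexicon entry {self.lemma!r}: unknown supersenses {sorted(unknown)}"
                )

    @property
    def supersenses(self) -> list[str]:
        """All supersenses, most frequent first (flattened)."""
        out: list[str] = []
        for group in self.sense_ranks:
            out.extend(sorted(group))
        return out


@runtime_checkable
class Tagger(Protocol):
    """Backend interface: any PoS/supersense provider can stand here."""

    def pos_tag(self, seq: TokenSequence) -> list[tuple[str, PosTag]]: ...

    def most_frequent_supersenses(self, token: str) -> set[str]: ...


class LexiconTagger:
    """Deterministic TSV-lexicon backend.

    Out-of-lexicon tokens fall back to ``NOUN`` (clinical OOV terms are
    overwhelmingly nouns) with an *empty* supersense set, so an unknown word
    never passes the supersense filter by accident; extended tokens are tagged
    ``NOUN`` and handled upstream by the filter-bypass rule.
    """

    #: PoS fallback for tokens absent from the lexicon
    oov_pos: PosTag = PosTag.NOUN

    def __init__(self, entries: dict[str, LexiconEntry]):
        self.entries = {lemma.lower(): e for lemma, e in entries.items()}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LexiconTagger":
        """TSV columns: lemma, pos, supersenses.

        Supersense ranks are ``;``-separated, most frequent first; equally
        frequent senses within one rank are ``,``-separated, e.g.
        ``bank\tNOUN\tNOUN_GROUP;NOUN_LOCATION`` or ``stone\tNOUN\tNOUN_OBJECT,NOUN_SUBSTANCE``.
        """
        entries: dict[str, LexiconEntry] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ConfigError(f"{path}:{lineno}: expected 3 tab-separated columns")
                lemma, pos_s, senses_s = (p.strip() for p in parts)
                try:
                    pos = PosTag[pos_s.upper()]
                except KeyError as exc:
                    raise ConfigError(f"{path}:{lineno}: unknown PoS {pos_s!r}") from exc
                ranks = [
                    {s.strip().upper() for s in grp.split(",") if s.strip()}
                    for grp in senses_s.split(";")
                    if grp.strip()
                ]
                entries[lemma.lower()] = LexiconEntry(lemma.lower(), pos, ranks)
        if not entries:
            raise ConfigError(f"{path}: empty lexicon")
        return cls(entries)

    def lookup(self, token: str) -> LexiconEntry | None:
        return self.entries.get(token.lower())

    def pos_tag(self, seq: TokenSequence) -> list[tuple[str, PosTag]]:
        out: list[tuple[str, PosTag]] = []
        for tok in seq:
            t = tok if isinstance(tok, Token) else Token(str(tok))
            if t.is_extended:
                out.append((t.surface, PosTag.NOUN))
                continue
            entry = self.lookup(t.surface)
            out.append((t.surface, entry.pos if entry else self.oov_pos))
        return out

    def most_frequent_supersenses(self, token: str) -> set[str]:
        """Supersenses of the top-ranked sense(s); empty set when unknown."""
        entry = self.lookup(token)
        if entry is None:
            return set()
        return set(entry.sense_ranks[0])


def default_tagger() -> LexiconTagger:
    """The shipped fixture-lexicon backend."""
    import importlib.resources

    resource = importlib.resources.files("violex.resources").joinpath("lexicon.tsv")
    with importlib.resources.as_file(resource) as path:
        return LexiconTagger.from_tsv(path)
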