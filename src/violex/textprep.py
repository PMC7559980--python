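"""Text normalisation, dictionary rewriting, tokenisation and locution merging.

Emergency-room narratives are written in a hurry: runs of spaces, missing
spaces after punctuation, pervasive abbreviations/acronyms and recurring
typos.  This module implements the cleaning front of the pipeline:

1. :func:`normalize_punctuation` — regex repairs + lowercasing;
2. :func:`apply_rewrites` — whole-token expansion of a curated rewrite
   dictionary (abbreviation/acronym/typo -> expansion);
3. :func:`tokenize` — punctuation removal + whitespace split;
4. :func:`mark_extended_tokens` — merge known multiword locutions
   (e.g. ``known person``) into single underscore-joined *extended tokens*
   that downstream filters treat specially.

All stages are deterministic, total on arbitrary strings, and idempotent
where the contracts promise it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigError

__all__ = [
    "Token",
    "TokenSequence",
    "RewriteDictionary",
    "normalize_punctuation",
    "apply_rewrites",
    "tokenize",
    "mark_extended_tokens",
    "EXTENDED_JOIN",
]

#: join character for extended tokens (multiword locutions)
EXTENDED_JOIN = "_"

ENTRY_KINDS = frozenset({"abbreviation", "acronym", "typo"})


@dataclass(frozen=True)
class Token:
    surface: str
    is_extended: bool = False

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("empty token surface")
        if self.is_extended and EXTENDED_JOIN not in self.surface:
            raise ValueError(f"extended token {self.surface!r} lacks the join character")


class TokenSequence:
    """Ordered token list; extended tokens carry a flag."""

    def __init__(self, tokens: Iterable[Token | str] = ()) -> None:
        self.tokens: list[Token] = [
            t if isinstance(t, Token) else Token(t) for t in tokens
        ]

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __getitem__(self, i):
        return self.tokens[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, TokenSequence) and self.tokens == other.tokens

    def __repr__(self) -> str:
        parts = [t.surface + ("†" if t.is_extended else "") for t in self.tokens]
        return f"TokenSequence([{', '.join(parts)}])"


class RewriteDictionary:
    """Ordered surface-form -> expansion map for abbreviations, acronyms, typos.

    Invariants enforced at construction:

    * surface forms contain no whitespace and are non-empty;
    * no surface form occurs as a whole token inside *any* expansion
      (this makes :func:`apply_rewrites` idempotent);
    * lookups are case-insensitive (everything is stored lowercase).
    """

    def __init__(self, entries: Iterable[tuple[str, str, str]] = ()) -> None:
        self.entries: dict[str, str] = {}
        self.kinds: dict[str, str] = {}
        for surface, expansion, kind in entries:
            self.add(surface, expansion, kind)
        self.validate()

    def add(self, surface: str, expansion: str, kind: str = "abbreviation") -> None:
        surface = surface.strip().lower()
        expansion = expansion.strip().lower()
        if not surface or not expansion:
            raise ConfigError("rewrite entry with empty surface or expansion")
        if re.search(r"\s", surface):
            raise ConfigError(f"surface form {surface!r} contains whitespace")
        if kind not in ENTRY_KINDS:
            raise ConfigError(f"entry kind {kind!r} not in {sorted(ENTRY_KINDS)}")
        self.entries[surface] = expansion
        self.kinds[surface] = kind

    def validate(self) -> None:
        """Reject dictionaries whose expansions contain any surface form as a token."""
        surfaces = set(self.entries)
        for surface, expansion in self.entries.items():
            for word in expansion.split():
                if word in surfaces:
                    raise ConfigError(
                        f"expansion of {surface!r} contains surface form {word!r}: "
                        "rewriting would not be idempotent"
                    )

    def reverse(self) -> dict[str, list[str]]:
        """expansion -> surface forms, used by the noise injector."""
        rev: dict[str, list[str]] = {}
        for surface, expansion in self.entries.items():
            rev.setdefault(expansion, []).append(surface)
        return rev

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, surface: str) -> bool:
        return surface.lower() in self.entries

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RewriteDictionary":
        """TSV columns: surface, expansion, kind; '#' starts a comment line."""
        entries = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ConfigError(f"{path}:{lineno}: expected ≥2 tab-separated columns")
                surface, expansion = parts[0], parts[1]
                kind = parts[2].strip() if len(parts) > 2 and parts[2].strip() else "abbreviation"
                entries.append((surface, expansion, kind))
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# surface\texpansion\tkind\n")
            for surface, expansion in self.entries.items():
                fh.write(f"{surface}\t{expansion}\t{self.kinds[surface]}\n")


# --- normalisation ---------------------------------------------------------

# space after , ; : . ! ? when glued to a following letter ("trauma,head")
_GLUED_PUNCT = re.compile(r"([,;:.!?])(?=[a-zA-Zà-ÿ])")
_MULTI_SPACE = re.compile(r"\s+")
# repeated sentence punctuation ("..", ",,") collapsed to one
_REPEAT_PUNCT = re.compile(r"([,;:!?])\1+")


def normalize_punctuation(text: str) -> str:
    """Lowercase and repair spacing/punctuation; total and idempotent."""
    text = text.lower()
    text = _REPEAT_PUNCT.sub(r"\1", text)
    text = _GLUED_PUNCT.sub(r"\1 ", text)
    text = _MULTI_SPACE.sub(" ", text)
    return text.strip()


def apply_rewrites(text: str, dictionary: RewriteDictionary) -> tuple[str, int]:
    """Expand every whole-token dictionary surface form in ``text``.

    Returns the rewritten text and the number of substitutions.  Matching is
    case-insensitive and on word boundaries only: longer surface forms win on
    overlap, unknown tokens (like the running example's ``aass``) pass through
    verbatim.  Single pass, hence idempotent given the dictionary invariant.
    """
    dictionary.validate()
    if not dictionary.entries or not text:
        return text, 0
    surfaces = sorted(dictionary.entries, key=len, reverse=True)
    pattern = re.compile(
        r"(?<![\w])(?:" + "|".join(re.escape(s) for s in surfaces) + r")(?![\w])",
        re.IGNORECASE,
    )
    count = 0

    def _sub(m: re.Match) -> str:
        nonlocal count
        count += 1
        return dictionary.entries[m.group(0).lower()]

    return pattern.sub(_sub, text), count


_NON_WORD = re.compile(r"[^\w\s]", re.UNICODE)


def tokenize(text: str) -> TokenSequence:
    """Strip punctuation, split on whitespace; never yields empty tokens."""
    cleaned = _NON_WORD.sub(" ", text)
    return TokenSequence(Token(t) for t in cleaned.split() if t)


def mark_extended_tokens(
    seq: TokenSequence, mwe_list: Sequence[str]
) -> TokenSequence:
    """Merge listed multiword expressions into single extended tokens.

    Longest match wins, scanning left to right; merged words are joined with
    ``_`` and flagged.  The concatenation of surfaces is preserved modulo the
    join character.
    """
    mwes: list[tuple[str, ...]] = []
    for m in mwe_list:
        words = tuple(m.lower().split())
        if len(words) < 2:
            raise ConfigError(f"multiword expression {m!r} must have ≥2 words")
        mwes.append(words)
    if not mwes:
        return TokenSequence(seq.tokens)
    mwes.sort(key=len, reverse=True)

    surfaces = seq.surfaces()
    out: list[Token] = []
    i = 0
    while i < len(surfaces):
        matched = None
        for words in mwes:
            if tuple(surfaces[i : i + len(words)]) == words:
                matched = words
                break
        if matched:
            out.append(Token(EXTENDED_JOIN.join(matched), is_extended=True))
            i += len(matched)
        else:
            out.append(seq.tokens[i])
            i += 1
    return TokenSequence(out)


def clean_text(
    text: str,
    dictionary: RewriteDictionary | None = None,
) -> str:
    """normalize + rewrite convenience used by the pipeline's cleaning stage."""
    text = normalize_punctuation(text)
    if dictionary is not None:
        text, _ = apply_rewrites(text, dictionary)
    return text


def preprocess(
    text: str,
    dictionary: RewriteDictionary | None = None,
    mwe_list: Sequence[str] = (),
) -> TokenSequence:
    """Full front-end: normalize → rewrite → tokenize → merge locutions."""
    seq = tokenize(clean_text(text, dictionary))
    return mark_extended_tokens(seq, mwe_list)
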