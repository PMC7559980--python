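"""Corpus records and their JSONL/CSV serialisation.

A record is one emergency-room narrative: an opaque id, the free-text report,
an optional gold label (``"V"`` violence-related / ``"NV"`` not), and — for
synthetic or annotated corpora — an optional gold frame mapping each of the
six violence-frame fields to its list of gold filler tokens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import DataError

LABEL_VIOLENCE = "V"
LABEL_NON_VIOLENCE = "NV"
VALID_LABELS = frozenset({LABEL_VIOLENCE, LABEL_NON_VIOLENCE})


@dataclass
class Record:
    id: str
    text: str
    label: str | None = None
    gold_frame: dict[str, list[str]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in VALID_LABELS:
            raise DataError(
                f"record {self.id!r}: label must be one of {sorted(VALID_LABELS)}, "
                f"got {self.label!r}"
            )

    def to_dict(self) -> dict:
        d: dict = {"id": self.id, "text": self.text}
        if self.label is not None:
            d["label"] = self.label
        if self.gold_frame is not None:
            d["gold_frame"] = self.gold_frame
        if self.meta:
            d["meta"] = self.meta
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Record":
        try:
            rid = str(d["id"])
            text = d.get("text", "") or ""
        except KeyError as exc:
            raise DataError(f"record missing required field: {exc}") from exc
        return cls(
            id=rid,
            text=str(text),
            label=d.get("label"),
            gold_frame=d.get("gold_frame"),
            meta=d.get("meta", {}) or {},
        )


def _check_unique_ids(records: list[Record]) -> list[Record]:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise DataError(f"duplicate record id {rec.id!r} in corpus")
        seen.add(rec.id)
    return records


def read_jsonl(path: str | Path) -> list[Record]:
    """Read one record per line; blank lines are skipped."""
    records: list[Record] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise DataError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            if isinstance(obj, dict) and "_meta" in obj and "id" not in obj:
                continue  # run-metadata header line
            records.append(Record.from_dict(obj))
    return _check_unique_ids(records)


def write_jsonl(records: Iterable[Record], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict(), ensure_ascii=False, sort_keys=True))
            fh.write("\n")


def read_csv(path: str | Path) -> list[Record]:
    """CSV with columns id, text and optionally label, gold_frame (JSON string)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in df.columns or "text" not in df.columns:
        raise DataError(f"{path}: CSV must have 'id' and 'text' columns")
    records = []
    for row in df.to_dict("records"):
        gold = row.get("gold_frame") or None
        if gold:
            gold = json.loads(gold)
        label = row.get("label") or None
        records.append(Record(id=row["id"], text=row["text"], label=label, gold_frame=gold))
    return _check_unique_ids(records)


def write_csv(records: Iterable[Record], path: str | Path) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "id": rec.id,
                "text": rec.text,
                "label": rec.label or "",
                "gold_frame": json.dumps(rec.gold_frame, sort_keys=True) if rec.gold_frame else "",
            }
        )
    pd.DataFrame(rows, columns=["id", "text", "label", "gold_frame"]).to_csv(path, index=False)


def iter_texts(records: Iterable[Record]) -> Iterator[str]:
    for rec in records:
        yield rec.text
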