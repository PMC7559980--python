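"""End-to-end orchestration: clean → categorize → explain violence records.

The pipeline mirrors the deployment flow: every record is cleaned and
categorized; only records labelled as violence-related are run through the
frame-filling explainer, and the output stream carries each record's label,
probability and (for violence records) its filled frame.  Run metadata
(package version, seeds, configuration hash) is embedded so runs are
auditable and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from . import __version__
from .classifier import ViolenceClassifier, predict_records
from .embedding import EmbeddingModel
from .errors import ConfigError
from .frames import FrameSchema, build_prototypes, extract_frame
from .lexicon import Tagger
from .records import LABEL_VIOLENCE, Record
from .textprep import RewriteDictionary, clean_text, mark_extended_tokens, tokenize

__all__ = ["PipelineComponents", "run_pipeline", "write_enriched_jsonl"]


@dataclass
class PipelineComponents:
    """Everything a full run needs, already loaded."""

    dictionary: RewriteDictionary
    mwe_list: list[str]
    tagger: Tagger
    schema: FrameSchema
    embeddings: EmbeddingModel
    classifier: ViolenceClassifier | None = None
    baseline: bool = False
    skip_classifier: bool = False
    threshold: float | None = None

    def config_hash(self) -> str:
        payload = {
            "schema": self.schema.to_dict(),
            "dictionary_size": len(self.dictionary),
            "mwe": sorted(self.mwe_list),
            "baseline": self.baseline,
            "skip_classifier": self.skip_classifier,
            "threshold": self.threshold,
            "embedding_dim": self.embeddings.dimension,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(
    components: PipelineComponents, records: Sequence[Record]
) -> tuple[dict, list[dict]]:
    """Process records in order; returns (run metadata, enriched dicts).

    Violence-labelled records get a ``frame`` (and the underlying per-field
    ``rankings``); others do not.  With ``skip_classifier`` every record is
    explained and labels default to V.
    """
    c = components
    if c.classifier is None and not c.skip_classifier:
        raise ConfigError("pipeline needs a classifier unless skip_classifier is set")

    cleaned = [
        Record(id=r.id, text=clean_text(r.text, c.dictionary), label=r.label,
               gold_frame=r.gold_frame)
        for r in records
    ]

    if c.skip_classifier:
        labels = {r.id: LABEL_VIOLENCE for r in cleaned}
        probs = {r.id: None for r in cleaned}
    else:
        preds = predict_records(c.classifier, cleaned)
        labels = {p.record_id: p.label for p in preds}
        probs = {p.record_id: round(p.probability, 6) for p in preds}

    prototypes = build_prototypes(c.schema, c.embeddings)
    out: list[dict] = []
    n_frames = 0
    for rec in cleaned:
        row: dict = {"id": rec.id, "label": labels[rec.id]}
        if probs[rec.id] is not None:
            row["probability"] = probs[rec.id]
        if labels[rec.id] == LABEL_VIOLENCE:
            seq = mark_extended_tokens(tokenize(rec.text), c.mwe_list)
            frame = extract_frame(
                seq, c.schema, c.embeddings, c.tagger,
                prototypes=prototypes,
                use_filters=not c.baseline,
                threshold=c.threshold,
            )
            row.update(frame.to_dict())
            n_frames += 1
        out.append(row)

    meta = {
        "version": __version__,
        "config_hash": c.config_hash(),
        "classifier_seed": None if c.classifier is None else c.classifier.cfg.seed,
        "baseline": c.baseline,
        "n_records": len(records),
        "n_violence": sum(1 for v in labels.values() if v == LABEL_VIOLENCE),
        "n_frames": n_frames,
    }
    return meta, out


def write_enriched_jsonl(meta: dict, rows: Iterable[dict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"_meta": meta}, sort_keys=True) + "\n")
        for row in rows:
            fh.write(json.dumps(row, ensure_ascii=False, sort_keys=True) + "\n")
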