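"""Scoring: per-class classification metrics and ranked-retrieval frame metrics.

Classification is scored with precision/recall/F1 per class from the
confusion counts.  Frame extraction is scored per field as a ranked-retrieval
problem against the gold filler sets:

* **MAP** — mean over records of the average precision of the field's
  ranking (sum of precision-at-each-hit divided by the gold-set size);
* **S@k** — fraction of records whose top-k list contains at least one gold
  filler;
* **R@k** — mean over records of the fraction of gold fillers retrieved in
  the top k.

Records whose gold set for a field is empty are excluded from that field's
denominator (per-field fill rates differ, so denominators do too).  Matching
is exact string equality after lowercasing; multiword fillers compare in
their underscore-joined extended-token form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import DataError
from .records import LABEL_NON_VIOLENCE, LABEL_VIOLENCE

__all__ = [
    "ClassReport",
    "FieldReport",
    "classification_metrics",
    "average_precision",
    "map_score",
    "success_at_k",
    "recall_at_k",
    "evaluate_frames",
]


@dataclass
class ClassReport:
    """Confusion counts and per-class precision/recall/F1 (positive class V)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        return p, r, f1

    def per_class(self) -> dict[str, dict[str, float]]:
        pv, rv, fv = self._prf(self.tp, self.fp, self.fn)
        # NV is the positive class of the mirrored confusion table
        pn, rn, fn_ = self._prf(self.tn, self.fn, self.fp)
        return {
            LABEL_VIOLENCE: {"precision": pv, "recall": rv, "f1": fv},
            LABEL_NON_VIOLENCE: {"precision": pn, "recall": rn, "f1": fn_},
        }

    def to_dict(self) -> dict:
        return {
            "counts": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "classes": self.per_class(),
        }


def classification_metrics(
    predictions: Mapping[str, str], gold: Mapping[str, str]
) -> ClassReport:
    """Confusion-matrix metrics over aligned ``{record_id: label}`` maps."""
    if set(predictions) != set(gold):
        missing = set(gold) ^ set(predictions)
        raise DataError(
            f"prediction/gold id mismatch ({len(missing)} unmatched ids, "
            f"e.g. {sorted(missing)[:3]})"
        )
    tp = fp = tn = fn = 0
    for rid, pred in predictions.items():
        actual = gold[rid]
        if pred == LABEL_VIOLENCE and actual == LABEL_VIOLENCE:
            tp += 1
        elif pred == LABEL_VIOLENCE:
            fp += 1
        elif actual == LABEL_VIOLENCE:
            fn += 1
        else:
            tn += 1
    return ClassReport(tp=tp, fp=fp, tn=tn, fn=fn)


def _norm(token: str) -> str:
    return token.lower().replace(" ", "_")


def average_precision(ranking: Sequence[str], gold: Sequence[str]) -> float:
    """AP of one ranking against a gold set; 0 when no gold item is returned."""
    gold_set = {_norm(g) for g in gold}
    if not gold_set:
        raise ValueError("average precision undefined for empty gold set")
    hits = 0
    prec_sum = 0.0
    for i, tok in enumerate(ranking, start=1):
        if _norm(tok) in gold_set:
            hits += 1
            prec_sum += hits / i
    return prec_sum / len(gold_set)


def map_score(
    rankings: Sequence[Sequence[str]], golds: Sequence[Sequence[str]]
) -> float:
    """Mean AP over the cases with non-empty gold."""
    cases = [(r, g) for r, g in zip(rankings, golds, strict=True) if g]
    if not cases:
        return 0.0
    return sum(average_precision(r, g) for r, g in cases) / len(cases)


def success_at_k(
    rankings: Sequence[Sequence[str]], golds: Sequence[Sequence[str]], k: int
) -> float:
    """Fraction of non-empty-gold cases with ≥1 gold filler in the top k."""
    if k < 1:
        raise ValueError("k must be ≥ 1")
    cases = [(r, g) for r, g in zip(rankings, golds, strict=True) if g]
    if not cases:
        return 0.0
    hits = 0
    for ranking, gold in cases:
        gold_set = {_norm(g) for g in gold}
        if any(_norm(t) in gold_set for t in ranking[:k]):
            hits += 1
    return hits / len(cases)


def recall_at_k(
    rankings: Sequence[Sequence[str]], golds: Sequence[Sequence[str]], k: int = 5
) -> float:
    """Mean |gold ∩ top-k| / |gold| over non-empty-gold cases."""
    if k < 1:
        raise ValueError("k must be ≥ 1")
    cases = [(r, g) for r, g in zip(rankings, golds, strict=True) if g]
    if not cases:
        return 0.0
    total = 0.0
    for ranking, gold in cases:
        gold_set = {_norm(g) for g in gold}
        top = {_norm(t) for t in ranking[:k]}
        total += len(gold_set & top) / len(gold_set)
    return total / len(cases)


@dataclass
class FieldReport:
    """Ranked-retrieval scores of one frame field over the evaluated records."""

    field: str
    n_cases: int
    map: float
    s_at_1: float
    s_at_5: float
    r_at_5: float

    def to_dict(self) -> dict:
        return {
            "field": self.field,
            "n_cases": self.n_cases,
            "MAP": round(self.map, 4),
            "S@1": round(self.s_at_1, 4),
            "S@5": round(self.s_at_5, 4),
            "R@5": round(self.r_at_5, 4),
        }


def evaluate_frames(
    predicted: Mapping[str, Mapping[str, Sequence[str]]],
    gold: Mapping[str, Mapping[str, Sequence[str]]],
    field_names: Sequence[str],
) -> dict[str, FieldReport]:
    """Per-field MAP/S@1/S@5/R@5.

    ``predicted`` maps record id -> field -> ranked candidate tokens (best
    first); ``gold`` maps record id -> field -> gold filler list.  Only
    records present in ``gold`` are evaluated; a record missing from
    ``predicted`` counts as an empty ranking.
    """
    reports: dict[str, FieldReport] = {}
    for fname in field_names:
        rankings: list[Sequence[str]] = []
        golds: list[Sequence[str]] = []
        for rid, gframe in gold.items():
            gold_fillers = list(gframe.get(fname, []))
            if not gold_fillers:
                continue
            pred_frame = predicted.get(rid, {})
            rankings.append(list(pred_frame.get(fname, [])))
            golds.append(gold_fillers)
        reports[fname] = FieldReport(
            field=fname,
            n_cases=len(golds),
            map=map_score(rankings, golds),
            s_at_1=success_at_k(rankings, golds, 1),
            s_at_5=success_at_k(rankings, golds, 5),
            r_at_5=recall_at_k(rankings, golds, 5),
        )
    return reports
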