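"""Precision / recall / F-measure evaluation at two granularities.

Mention level (recognition): a prediction is a true positive only when its
(start, end) span exactly matches a gold span in the same document.
Document-ID level (normalization): per document, the *set* of predicted
MeSH IDs (predictions of "-1" excluded, duplicates collapsed) is compared
with the gold ID set; TP/FP/FN are summed over documents.

Reported metrics round half-up to two decimals; raw floats are retained on
the counts object.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from dislex.corpus_io import Document


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def rounded(self) -> tuple[float, float, float]:
        """(P, R, F) rounded half-up to 2 decimals, as reported."""
        return (
            _round2(self.precision),
            _round2(self.recall),
            _round2(self.f_measure),
        )

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Rounded (precision, recall, F) from confusion counts.

    Any zero denominator yields 0 for that metric.
    """
    return EvalCounts(tp, fp, fn).rounded()


class PairingError(ValueError):
    """Predicted and gold collections do not cover the same doc_ids."""


def _pair(
    predicted: Sequence[Document], gold: Sequence[Document]
) -> list[tuple[Document, Document]]:
    pred_by_id = {d.doc_id: d for d in predicted}
    gold_by_id = {d.doc_id: d for d in gold}
    if set(pred_by_id) != set(gold_by_id):
        raise PairingError(
            f"doc_id mismatch: only-predicted={sorted(set(pred_by_id) - set(gold_by_id))}, "
            f"only-gold={sorted(set(gold_by_id) - set(pred_by_id))}"
        )
    return [(pred_by_id[i], gold_by_id[i]) for i in sorted(pred_by_id)]


def evaluate_mentions(
    predicted: Sequence[Document], gold: Sequence[Document]
) -> EvalCounts:
    """Mention-level counts under exact (start, end) span matching."""
    tp = fp = fn = 0
    for pred_doc, gold_doc in _pair(predicted, gold):
        pred_spans = {(m.start, m.end) for m in pred_doc.mentions}
        gold_spans = {(m.start, m.end) for m in gold_doc.mentions}
        tp += len(pred_spans & gold_spans)
        fp += len(pred_spans - gold_spans)
        fn += len(gold_spans - pred_spans)
    return EvalCounts(tp, fp, fn)


def evaluate_doc_ids(
    predicted: Sequence[Document], gold: Sequence[Document]
) -> EvalCounts:
    """Document-level concept-ID set comparison ("-1" excluded)."""
    tp = fp = fn = 0
    for pred_doc, gold_doc in _pair(predicted, gold):
        pred_ids = {m.concept_id for m in pred_doc.mentions if m.concept_id != "-1"}
        gold_ids = {m.concept_id for m in gold_doc.mentions if m.concept_id != "-1"}
        tp += len(pred_ids & gold_ids)
        fp += len(pred_ids - gold_ids)
        fn += len(gold_ids - pred_ids)
    return EvalCounts(tp, fp, fn)
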