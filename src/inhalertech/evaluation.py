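"""Document-level evaluation: confusion counts, precision/recall, F-beta.

A note is labeled present iff any of its sentences is present (existential
aggregation), matching how guideline adherence is assessed — per note, not
per sentence.  F2 weighs recall above precision; F0.5 the reverse.
Ratios with zero denominators are reported as ``None`` (undefined), never
silently 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .corpus_io import Label, LabeledSentence


class UndefinedMetricError(ZeroDivisionError):
    """Raised when a metric's denominator is zero."""


def fbeta(precision: float, recall: float, beta: float) -> float:
    """F-beta = (1 + b^2) P R / (b^2 P + R).

    Raises :class:`UndefinedMetricError` when P = R = 0.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    denom = beta * beta * precision + recall
    if denom == 0:
        raise UndefinedMetricError("F-beta undefined for P = R = 0")
    return (1 + beta * beta) * precision * recall / denom


def round_half_up(x: float, digits: int = 3) -> float:
    """Round half away from zero, as the reported tables do."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MetricsReport:
    """Document-level confusion counts and derived metrics."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.total if self.total else None

    def _f(self, beta: float) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None:
            return None
        try:
            return fbeta(p, r, beta)
        except UndefinedMetricError:
            return None

    @property
    def f1(self) -> float | None:
        return self._f(1.0)

    @property
    def f2(self) -> float | None:
        return self._f(2.0)

    @property
    def f0_5(self) -> float | None:
        return self._f(0.5)

    def as_dict(self, digits: int | None = None) -> dict:
        """Report as JSON-serializable dict; metrics optionally rounded."""
        out: dict = {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}
        for name in ("precision", "recall", "f1", "f2", "f0_5", "accuracy"):
            v = getattr(self, name)
            if v is not None and digits is not None:
                v = round_half_up(v, digits)
            out[name] = v
        return out

    def as_table_row(self, model: str = "") -> str:
        """One aligned row mirroring the standard results-table columns."""
        cells = [
            "-" if v is None else f"{round_half_up(v, 3):.3f}"
            for v in (self.precision, self.recall, self.f1, self.f2,
                      self.f0_5, self.accuracy)
        ]
        return f"{model:<12}" + "".join(f"{c:>10}" for c in cells)


TABLE_HEADER = (
    f"{'Model':<12}" + "".join(
        f"{c:>10}" for c in ("P", "R", "F1", "F2", "F0.5", "Acc")
    )
)


def aggregate_document_labels(
    sentence_labels: Sequence[LabeledSentence],
) -> dict[str, Label]:
    """Per note: present iff any sentence is labeled present."""
    out: dict[str, Label] = {}
    for s in sentence_labels:
        prev = out.get(s.note_id, Label.ABSENT)
        if prev is Label.ABSENT and s.label is Label.PRESENT:
            out[s.note_id] = Label.PRESENT
        else:
            out.setdefault(s.note_id, prev)
    return out


def evaluate(
    predicted_docs: Mapping[str, Label],
    gold_docs: Mapping[str, Label],
) -> MetricsReport:
    """Compare predicted vs gold document labels; present is positive."""
    missing = sorted(set(gold_docs) ^ set(predicted_docs))
    if missing:
        raise ValueError(f"document id mismatch between predictions and gold: {missing}")
    tp = fp = fn = tn = 0
    for note_id, gold in gold_docs.items():
        pred = predicted_docs[note_id]
        if gold is Label.PRESENT:
            if pred is Label.PRESENT:
                tp += 1
            else:
                fn += 1
        else:
            if pred is Label.PRESENT:
                fp += 1
            else:
                tn += 1
    return MetricsReport(tp=tp, fp=fp, fn=fn, tn=tn)
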