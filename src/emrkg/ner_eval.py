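"""Exact-match entity evaluation: TP/FP/FN counts and precision/recall/F1.

A predicted entity is a true positive only when a gold entity matches it in
both type and boundary, i.e. (entity_type, start, end) equality.  Anything
else predicted is a false positive and any unmatched gold entity a false
negative, so a right-boundary/wrong-type prediction costs one FP and one FN.

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2 P R / (P + R)

Micro-averaging (pooled counts) is the default aggregate; per-type (macro)
rows are also produced.  Degenerate 0/0 ratios are defined as 0 with a
logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus_io import EntitySpan

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def _keys(spans: Iterable[EntitySpan]) -> set[tuple[str, int, int]]:
    return {(s.entity_type, s.start, s.end) for s in spans}


def match_entities(
    pred: Sequence[EntitySpan], gold: Sequence[EntitySpan]
) -> MatchCounts:
    """Set intersection under (type, start, end) equality for one document."""
    p, g = _keys(pred), _keys(gold)
    tp = len(p & g)
    return MatchCounts(tp=tp, fp=len(p) - tp, fn=len(g) - tp)


def match_entities_by_type(
    pred: Sequence[EntitySpan], gold: Sequence[EntitySpan]
) -> dict[str, MatchCounts]:
    types = {s.entity_type for s in pred} | {s.entity_type for s in gold}
    return {
        t: match_entities(
            [s for s in pred if s.entity_type == t],
            [s for s in gold if s.entity_type == t],
        )
        for t in sorted(types)
    }


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (0/0); reporting 0", what)
        return 0.0
    return num / den


def prf(counts: MatchCounts) -> tuple[float, float, float]:
    """Precision, recall and their harmonic-mean F1, as fractions in [0, 1]."""
    p = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    r = _ratio(counts.tp, counts.tp + counts.fn, "recall")
    f1 = _ratio(2 * p * r, p + r, "F1")
    return p, r, f1


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (same scale as its inputs)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def evaluate(
    pred_docs: Sequence[Sequence[EntitySpan]],
    gold_docs: Sequence[Sequence[EntitySpan]],
) -> dict[str, tuple[float, float, float]]:
    """Corpus-level report: per-type rows plus pooled 'micro' totals."""
    if len(pred_docs) != len(gold_docs):
        raise ValueError("prediction/gold document counts differ")
    per_type: dict[str, MatchCounts] = {}
    total = MatchCounts()
    for pred, gold in zip(pred_docs, gold_docs):
        total = total + match_entities(pred, gold)
        for t, c in match_entities_by_type(pred, gold).items():
            per_type[t] = per_type.get(t, MatchCounts()) + c
    report = {t: prf(c) for t, c in sorted(per_type.items())}
    report["micro"] = prf(total)
    return report


def format_report(report: dict[str, tuple[float, float, float]]) -> str:
    lines = ["type\tprecision\trecall\tf1"]
    for t, (p, r, f) in report.items():
        lines.append(f"{t}\t{100 * p:.2f}\t{100 * r:.2f}\t{100 * f:.2f}")
    return "\n".join(lines)
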