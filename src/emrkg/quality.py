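"""Triple-accuracy quality assessment with stratified sampling.

A stratified random sample of triples (strata = relation types) is drawn
from the graph and each item is labelled Correct, Incorrect or
InsufficientContext (IC) by an annotator — the tool never auto-labels
correctness.  Per stratum and overall,

    n_eff = sampled - IC,      TAcc = correct / n_eff

IC items are excluded from the accuracy denominator and their proportion is
reported separately as a documentation-completeness indicator.  The overall
accuracy is the pooled ratio (sum of correct over sum of n_eff), not the
mean of stratum accuracies.  Reported percentages are rounded half-up to two
decimals; full precision is retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .kg import Triple, TripleStore

LABEL_CORRECT = "Correct"
LABEL_INCORRECT = "Incorrect"
LABEL_IC = "InsufficientContext"
LABELS = (LABEL_CORRECT, LABEL_INCORRECT, LABEL_IC)


@dataclass
class QaItem:
    triple: Triple
    stratum: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")


@dataclass
class QaSample:
    items: list[QaItem] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    def strata(self) -> list[str]:
        seen: dict[str, None] = {}
        for it in self.items:
            seen.setdefault(it.stratum)
        return list(seen)


@dataclass(frozen=True)
class StratumResult:
    stratum: str
    sampled: int
    ic: int
    n_eff: int
    correct: int
    incorrect: int
    accuracy: float | None  # fraction; None when n_eff == 0

    @property
    def accuracy_pct(self) -> float | None:
        return None if self.accuracy is None else round_pct(self.accuracy)

    @property
    def ic_proportion(self) -> float:
        return self.ic / self.sampled if self.sampled else 0.0


@dataclass
class QaResult:
    per_stratum: dict[str, StratumResult]
    overall: StratumResult


def round_pct(fraction: float, digits: int = 2) -> float:
    """Half-up percentage rounding (printed-table convention)."""
    q = Decimal(10) ** -digits
    return float(
        (Decimal(repr(fraction)) * 100).quantize(q, rounding=ROUND_HALF_UP)
    )


def stratified_sample(
    store: TripleStore, strata_sizes: Mapping[str, int], seed: int = 0
) -> QaSample:
    """Uniform without-replacement sample of the requested size per relation
    stratum; seed-deterministic.  A zero-size stratum is simply absent."""
    rng = np.random.default_rng(seed)
    items: list[QaItem] = []
    by_rel: dict[str, list[Triple]] = {}
    for t in sorted(store.triples, key=Triple.key):
        by_rel.setdefault(t.relation, []).append(t)
    for relation in sorted(strata_sizes):
        size = strata_sizes[relation]
        if size == 0:
            continue
        pool = by_rel.get(relation, [])
        if len(pool) < size:
            raise ValueError(
                f"stratum {relation!r} has {len(pool)} triples, "
                f"cannot sample {size}"
            )
        chosen = rng.choice(len(pool), size=size, replace=False)
        items.extend(QaItem(pool[int(i)], relation) for i in chosen)
    return QaSample(items=items)


def _summarise(stratum: str, items: Sequence[QaItem]) -> StratumResult:
    sampled = len(items)
    ic = sum(1 for it in items if it.label == LABEL_IC)
    correct = sum(1 for it in items if it.label == LABEL_CORRECT)
    incorrect = sum(1 for it in items if it.label == LABEL_INCORRECT)
    n_eff = sampled - ic
    acc = correct / n_eff if n_eff > 0 else None
    return StratumResult(stratum, sampled, ic, n_eff, correct, incorrect, acc)


def triple_accuracy(sample: QaSample) -> QaResult:
    """Per-stratum and pooled overall triple accuracy of a labelled sample."""
    unlabeled = [it for it in sample.items if it.label is None]
    if unlabeled:
        raise ValueError(f"{len(unlabeled)} items have no label")
    per: dict[str, StratumResult] = {}
    for stratum in sample.strata():
        per[stratum] = _summarise(
            stratum, [it for it in sample.items if it.stratum == stratum]
        )
    overall = _summarise("Overall", sample.items)
    return QaResult(per_stratum=per, overall=overall)


def format_result(result: QaResult) -> str:
    """TSV mirroring the audit-table layout."""
    lines = ["relation\tsampled\tic\tn_eff\tcorrect\tincorrect\taccuracy_pct"]

    def row(r: StratumResult) -> str:
        acc = "NA" if r.accuracy_pct is None else f"{r.accuracy_pct:.2f}"
        return (
            f"{r.stratum}\t{r.sampled}\t{r.ic}\t{r.n_eff}\t{r.correct}"
            f"\t{r.incorrect}\t{acc}"
        )

    for r in result.per_stratum.values():
        lines.append(row(r))
    lines.append(row(result.overall))
    return "\n".join(lines)


def write_sample_tsv(sample: QaSample, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tsubject_type\tsubject\trelation\tobject_type\tobject\tstratum\tlabel\n")
        for i, it in enumerate(sample.items):
            t = it.triple
            fh.write(
                f"{i}\t{t.subject[0]}\t{t.subject[1]}\t{t.relation}"
                f"\t{t.object[0]}\t{t.object[1]}\t{it.stratum}\t{it.label or ''}\n"
            )


def read_sample_tsv(path) -> QaSample:
    items: list[QaItem] = []
    with open(path, "r", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            _, st, sn, rel, ot, on, stratum, label = parts
            items.append(
                QaItem(
                    Triple((st, sn), rel, (ot, on)),
                    stratum,
                    label or None,
                )
            )
    return QaSample(items=items)


def labeled_sample_from_counts(
    counts: Mapping[str, tuple[int, int, int]], schema=None
) -> QaSample:
    """Construct a labelled sample from per-stratum (sampled, ic, correct)
    counts — the form audit tables are printed in."""
    from .schema import KgSchema

    schema = schema or KgSchema.default()
    items: list[QaItem] = []
    for relation, (sampled, ic, correct) in counts.items():
        rel = schema.relation(relation)
        incorrect = sampled - ic - correct
        if incorrect < 0:
            raise ValueError(f"stratum {relation!r}: correct + ic exceeds sampled")
        labels = (
            [LABEL_CORRECT] * correct
            + [LABEL_INCORRECT] * incorrect
            + [LABEL_IC] * ic
        )
        subj_t = rel.domain if rel.domain != "*" else "diseases"
        obj_t = rel.range if rel.range != "*" else "symptom"
        for i, label in enumerate(labels):
            items.append(
                QaItem(
                    Triple(
                        (subj_t, f"{subj_t}_{i:05d}"),
                        rel.name,
                        (obj_t, f"{obj_t}_{i + 1:05d}"),
                        provenance="audit",
                    ),
                    rel.name,
                    label,
                )
            )
    return QaSample(items=items)
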