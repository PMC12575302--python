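"""Corpus I/O: BRAT standoff annotations, BIO tag sequences, text cleanup.

Clinical notes arrive as plain text plus a standoff ``.ann`` file of typed
character-offset entity records (``T1<TAB>disease 280 291<TAB>surface``).
This module parses and writes that format, converts between span annotations
and token-level BIO labels (the unit consumed by the sequence labeler),
normalises raw text with ordered regex rules, applies rule-based
de-identification, and performs seeded document-level dataset splits.

Offsets are 0-based, end-exclusive character positions (BRAT convention).
The default tokenizer is per-character, the standard choice for Chinese
sequence labeling; any callable returning token boundaries may be plugged in.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .schema import ENTITY_TYPES

logger = logging.getLogger(__name__)

Tokenizer = Callable[[str], list[tuple[int, int]]]


class ConfigurationError(ValueError):
    pass


class AnnParseError(ValueError):
    pass


class OverlapError(ValueError):
    pass


class BioValidityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntitySpan:
    """A typed entity mention anchored to character offsets in a document."""

    span_id: str
    entity_type: str
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"span {self.span_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )


@dataclass
class AnnotatedDocument:
    """A note's text plus its entity spans, sorted and non-overlapping."""

    doc_id: str
    text: str
    spans: list[EntitySpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spans = sorted(self.spans, key=lambda s: (s.start, s.end))
        for s in self.spans:
            if s.end > len(self.text):
                raise AnnParseError(
                    f"span {s.span_id}: end {s.end} beyond text length "
                    f"{len(self.text)} in doc {self.doc_id!r}"
                )
        for a, b in zip(self.spans, self.spans[1:]):
            if b.start < a.end:
                raise OverlapError(
                    f"doc {self.doc_id!r}: overlapping spans "
                    f"{a.span_id} [{a.start},{a.end}) and "
                    f"{b.span_id} [{b.start},{b.end})"
                )


@dataclass
class TagSequence:
    """Tokenized sentence with aligned BIO labels and character offsets."""

    tokens: list[str]
    labels: list[str]
    char_offsets: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise ValueError(
                f"{len(self.tokens)} tokens but {len(self.labels)} labels"
            )
        if self.char_offsets is not None and len(self.char_offsets) != len(
            self.tokens
        ):
            raise ValueError("char_offsets length differs from tokens")

    def __len__(self) -> int:
        return len(self.tokens)


def is_bio_valid(labels: Sequence[str]) -> bool:
    """A label sequence is BIO-valid when every I-x follows B-x or I-x."""
    prev = "O"
    for lab in labels:
        if lab.startswith("I-"):
            t = lab[2:]
            if prev not in (f"B-{t}", f"I-{t}"):
                return False
        prev = lab
    return True


# ---------------------------------------------------------------------------
# text normalisation and de-identification
# ---------------------------------------------------------------------------

Rule = tuple[str, "str | Callable[[re.Match], str]"]


def _pad_date(m: re.Match) -> str:
    return f"{m.group(1)}-{int(m.group(2)):02d}-{int(m.group(3)):02d}"


#: Applied in order: collapse runs of whitespace, then unify CJK-style dates
#: (``2015年3月5日`` -> ``2015-03-05``).
DEFAULT_NORMALIZATION_RULES: list[Rule] = [
    (r"[ \t　]+", " "),
    (r"(\d{4})年\s*(\d{1,2})月\s*(\d{1,2})日", _pad_date),
]


def normalize_text(raw: str, rules: Iterable[Rule] | None = None) -> str:
    """Apply ordered pattern -> replacement rules; idempotent by design.

    Each rule is ``(regex, replacement)`` where replacement is a string or a
    match callable.  A malformed pattern raises :class:`ConfigurationError`.
    """
    if rules is None:
        rules = DEFAULT_NORMALIZATION_RULES
    out = raw
    for pattern, repl in rules:
        try:
            out = re.sub(pattern, repl, out)
        except re.error as exc:
            raise ConfigurationError(f"bad rule pattern {pattern!r}: {exc}") from exc
    return out


def make_deidentifier(
    patterns: Iterable[str], prefix: str = "PT", seed: int = 0
) -> Callable[[str], str]:
    """Rule-based PHI replacement: each distinct match of any configured
    identifier pattern is replaced by a stable generated patient ID."""
    compiled = [re.compile(p) for p in patterns]
    rng = np.random.default_rng(seed)
    mapping: dict[str, str] = {}

    def _deidentify(text: str) -> str:
        for pat in compiled:
            for m in set(pat.findall(text)):
                if m not in mapping:
                    mapping[m] = f"{prefix}{rng.integers(10**6, 10**7)}"
            text = pat.sub(lambda mm: mapping[mm.group(0)], text)
        return text

    return _deidentify


# ---------------------------------------------------------------------------
# BRAT standoff
# ---------------------------------------------------------------------------

_ANN_LINE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")


def parse_ann(
    text: str,
    ann_lines: Iterable[str],
    doc_id: str = "",
    strict: bool = True,
    allowed_types: Sequence[str] | None = None,
    repair_overlaps: bool = False,
) -> AnnotatedDocument:
    """Parse BRAT entity lines against their document text.

    Only ``T`` (entity) records are consumed; relation/attribute records are
    ignored.  Offsets outside the text raise :class:`AnnParseError` naming the
    span id.  A surface string that disagrees with the text substring is an
    error in strict mode and a logged warning otherwise (the substring wins).
    Overlapping spans are rejected unless ``repair_overlaps`` keeps the
    longest span of each overlapping group.
    """
    if allowed_types is None:
        allowed_types = ENTITY_TYPES
    spans: list[EntitySpan] = []
    for line in ann_lines:
        line = line.rstrip("\n")
        if not line or not line.startswith("T"):
            continue
        m = _ANN_LINE.match(line)
        if m is None:
            raise AnnParseError(f"malformed entity line: {line!r}")
        span_id, etype, start_s, end_s, surface = m.groups()
        start, end = int(start_s), int(end_s)
        if etype not in allowed_types:
            raise AnnParseError(f"span {span_id}: unregistered type {etype!r}")
        if not (0 <= start < end <= len(text)):
            raise AnnParseError(
                f"span {span_id}: offsets [{start},{end}) outside text of "
                f"length {len(text)}"
            )
        actual = text[start:end]
        if surface != actual:
            msg = (
                f"span {span_id}: surface {surface!r} does not match "
                f"text substring {actual!r}"
            )
            if strict:
                raise AnnParseError(msg)
            logger.warning(msg)
            surface = actual
        spans.append(EntitySpan(span_id, etype, start, end, surface))

    if repair_overlaps:
        spans = _keep_longest(spans)
    return AnnotatedDocument(doc_id=doc_id, text=text, spans=spans)


def _keep_longest(spans: list[EntitySpan]) -> list[EntitySpan]:
    kept: list[EntitySpan] = []
    for s in sorted(spans, key=lambda s: (s.end - s.start, -s.start), reverse=True):
        if all(s.end <= k.start or s.start >= k.end for k in kept):
            kept.append(s)
    return sorted(kept, key=lambda s: s.start)


def write_ann(doc: AnnotatedDocument) -> list[str]:
    """Serialise spans back to BRAT entity lines (inverse of parse_ann)."""
    return [
        f"{s.span_id}\t{s.entity_type} {s.start} {s.end}\t{s.surface}"
        for s in doc.spans
    ]


def read_brat(directory) -> list[AnnotatedDocument]:
    """Read paired ``<doc>.txt`` / ``<doc>.ann`` files from a directory."""
    directory = Path(directory)
    docs = []
    for txt_path in sorted(directory.glob("*.txt")):
        text = txt_path.read_text("utf-8")
        ann_path = txt_path.with_suffix(".ann")
        lines = ann_path.read_text("utf-8").splitlines() if ann_path.exists() else []
        docs.append(parse_ann(text, lines, doc_id=txt_path.stem))
    return docs


def write_brat(docs: Iterable[AnnotatedDocument], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (directory / f"{doc.doc_id}.txt").write_text(doc.text, "utf-8")
        (directory / f"{doc.doc_id}.ann").write_text(
            "\n".join(write_ann(doc)) + ("\n" if doc.spans else ""), "utf-8"
        )


# ---------------------------------------------------------------------------
# spans <-> BIO
# ---------------------------------------------------------------------------


def char_tokenizer(text: str) -> list[tuple[int, int]]:
    """One token per character (skipping nothing)."""
    return [(i, i + 1) for i in range(len(text))]


def _sentence_segments(text: str, seps: str = "\n。") -> list[tuple[int, int]]:
    """Contiguous [start, end) segments, each ending at (and including) a
    separator character; separators stay inside the preceding segment."""
    segments = []
    start = 0
    for i, ch in enumerate(text):
        if ch in seps:
            segments.append((start, i + 1))
            start = i + 1
    if start < len(text):
        segments.append((start, len(text)))
    return segments


def spans_to_bio(
    doc: AnnotatedDocument,
    tokenizer: Tokenizer = char_tokenizer,
    split_sentences: bool = True,
) -> list[TagSequence]:
    """Project entity spans onto tokens: first overlapping token gets
    ``B-<type>``, later overlapping tokens ``I-<type>``, all others ``O``.

    A span crossing a sentence boundary is an error naming the span.
    """
    segments = (
        _sentence_segments(doc.text) if split_sentences else [(0, len(doc.text))]
    )
    for s in doc.spans:
        for seg_start, seg_end in segments:
            if s.start < seg_end and s.end > seg_start:
                if not (seg_start <= s.start and s.end <= seg_end):
                    raise ValueError(
                        f"span {s.span_id} [{s.start},{s.end}) crosses a "
                        f"sentence boundary at segment [{seg_start},{seg_end})"
                    )

    sequences = []
    for seg_start, seg_end in segments:
        seg_text = doc.text[seg_start:seg_end]
        bounds = [(a + seg_start, b + seg_start) for a, b in tokenizer(seg_text)]
        tokens = [doc.text[a:b] for a, b in bounds]
        labels = ["O"] * len(tokens)
        for span in doc.spans:
            if span.end <= seg_start or span.start >= seg_end:
                continue
            first = True
            for i, (a, b) in enumerate(bounds):
                if a < span.end and b > span.start:
                    labels[i] = ("B-" if first else "I-") + span.entity_type
                    first = False
        sequences.append(TagSequence(tokens, labels, bounds))
    return sequences


def bio_to_spans(
    seq: TagSequence, strict: bool = True, id_prefix: str = "T", id_start: int = 1
) -> list[EntitySpan]:
    """Recover entity spans from a BIO-labelled sequence.

    In strict mode an invalid transition raises :class:`BioValidityError`
    with its position; otherwise a dangling ``I-x`` opens a new span.
    """
    offsets = seq.char_offsets or [(i, i + 1) for i in range(len(seq))]
    spans: list[EntitySpan] = []
    cur_type: str | None = None
    cur_start = cur_end = 0

    def _close() -> None:
        nonlocal cur_type
        if cur_type is not None:
            spans.append(
                EntitySpan(
                    f"{id_prefix}{id_start + len(spans)}",
                    cur_type,
                    cur_start,
                    cur_end,
                    "".join(
                        seq.tokens[i]
                        for i in range(len(seq))
                        if offsets[i][0] >= cur_start and offsets[i][1] <= cur_end
                    ),
                )
            )
            cur_type = None

    for i, lab in enumerate(seq.labels):
        if lab == "O":
            _close()
        elif lab.startswith("B-"):
            _close()
            cur_type = lab[2:]
            cur_start, cur_end = offsets[i]
        elif lab.startswith("I-"):
            if cur_type != lab[2:]:
                if strict:
                    raise BioValidityError(
                        f"invalid transition into {lab!r} at position {i}"
                    )
                _close()
                cur_type = lab[2:]
                cur_start, cur_end = offsets[i]
            else:
                cur_end = offsets[i][1]
        else:
            raise BioValidityError(f"unknown label {lab!r} at position {i}")
    _close()
    return spans


# ---------------------------------------------------------------------------
# BIO corpus files (CoNLL-style TSV)
# ---------------------------------------------------------------------------


def write_bio(seqs: Iterable[TagSequence], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for seq in seqs:
            for tok, lab in zip(seq.tokens, seq.labels):
                fh.write(f"{tok}\t{lab}\n")
            fh.write("\n")


def read_bio(path) -> list[TagSequence]:
    seqs: list[TagSequence] = []
    tokens: list[str] = []
    labels: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                if tokens:
                    seqs.append(TagSequence(tokens, labels))
                    tokens, labels = [], []
                continue
            tok, lab = line.split("\t")
            tokens.append(tok)
            labels.append(lab)
    if tokens:
        seqs.append(TagSequence(tokens, labels))
    return seqs


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------


def split_dataset(
    docs: Sequence,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Seeded document-level split into train/dev/test.

    Base sizes are floors of ``ratio * n``; leftover documents go to the
    partitions with the largest fractional remainders (ties toward earlier
    partitions).  The three lists partition the input exactly.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    n = len(docs)
    nonzero = sum(1 for r in ratios if r > 0)
    if n < nonzero:
        raise ValueError(f"{n} documents cannot fill {nonzero} partitions")

    exact = [r * n for r in ratios]
    sizes = [int(np.floor(e)) for e in exact]
    remainder = n - sum(sizes)
    order = sorted(range(3), key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in order[:remainder]:
        sizes[i] += 1
    # a nonzero-ratio partition must not come out empty when avoidable
    for i in range(3):
        if ratios[i] > 0 and sizes[i] == 0:
            donor = max(range(3), key=lambda j: sizes[j])
            sizes[donor] -= 1
            sizes[i] += 1

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    idx = [perm[: sizes[0]], perm[sizes[0] : sizes[0] + sizes[1]],
           perm[sizes[0] + sizes[1] :]]
    return tuple([docs[i] for i in part] for part in idx)  # type: ignore[return-value]
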