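"""Dynamic Entity Replacement and Masking (DERM) training augmentation.

For every training sequence one random number RN in (0, 1) selects a branch:

* RN < ``replace_threshold`` (default 0.3): every entity mention's surface is
  replaced by a uniformly drawn same-type dictionary term, with tokens and
  BIO labels re-aligned to the new length;
* ``replace_threshold`` <= RN < ``mask_threshold`` (default 0.6): every
  entity token is replaced by the mask token, labels unchanged;
* RN >= ``mask_threshold``: the sequence is left as is.

Non-entity tokens are never modified and outputs are always BIO-valid.
The per-sequence RN governs all mentions in that sequence uniformly; a
per-mention mode draws one RN per mention instead.  Expected branch rates
under the defaults are (0.3, 0.3, 0.4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import TagSequence, is_bio_valid

BRANCH_REPLACE = "replace"
BRANCH_MASK = "mask"
BRANCH_KEEP = "keep"


class DictionaryError(KeyError):
    """Raised when the replace branch needs a dictionary that is empty."""


@dataclass
class DermConfig:
    replace_threshold: float = 0.3
    mask_threshold: float = 0.6
    mask_token: str = "[MASK]"
    dictionaries: dict[str, list[str]] = field(default_factory=dict)
    per_mention: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.replace_threshold <= self.mask_threshold <= 1.0:
            raise ValueError(
                "require 0 <= replace_threshold <= mask_threshold <= 1, got "
                f"({self.replace_threshold}, {self.mask_threshold})"
            )


def _mentions(labels: list[str]) -> list[tuple[int, int, str]]:
    """(start, end, type) token index ranges of contiguous B/I groups."""
    out = []
    i = 0
    while i < len(labels):
        if labels[i].startswith("B-"):
            etype = labels[i][2:]
            j = i + 1
            while j < len(labels) and labels[j] == f"I-{etype}":
                j += 1
            out.append((i, j, etype))
            i = j
        else:
            i += 1
    return out


def _branch(rn: float, cfg: DermConfig) -> str:
    if rn < cfg.replace_threshold:
        return BRANCH_REPLACE
    if rn < cfg.mask_threshold:
        return BRANCH_MASK
    return BRANCH_KEEP


def _draw_replacement(
    etype: str, original: str, cfg: DermConfig, rng: np.random.Generator
) -> str:
    terms = cfg.dictionaries.get(etype)
    if not terms:
        raise DictionaryError(f"no dictionary terms for entity type {etype!r}")
    # exclude the original surface when alternatives exist (no-op avoidance)
    candidates = [t for t in terms if t != original] or terms
    return candidates[int(rng.integers(len(candidates)))]


def derm_transform(
    seq: TagSequence,
    cfg: DermConfig,
    rng_value: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TagSequence, str]:
    """Apply one DERM draw to a sequence; returns (sequence, branch taken).

    ``rng_value`` injects the branch-selecting random number so every branch
    is unit-testable deterministically; term choice still uses ``rng``.
    In per-mention mode the returned branch is ``replace``/``mask`` if any
    mention took that branch, ``keep`` otherwise, and ``rng_value`` applies
    to every mention.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if not is_bio_valid(seq.labels):
        raise ValueError("input sequence is not BIO-valid")

    mentions = _mentions(seq.labels)
    if not mentions:
        rn = rng_value if rng_value is not None else float(rng.random())
        return seq, _branch(rn, cfg)

    if cfg.per_mention:
        branches = [
            _branch(rng_value if rng_value is not None else float(rng.random()), cfg)
            for _ in mentions
        ]
    else:
        rn = rng_value if rng_value is not None else float(rng.random())
        branches = [_branch(rn, cfg)] * len(mentions)

    tokens: list[str] = []
    labels: list[str] = []
    cursor = 0
    for (start, end, etype), branch in zip(mentions, branches):
        tokens.extend(seq.tokens[cursor:start])
        labels.extend(seq.labels[cursor:start])
        if branch == BRANCH_REPLACE:
            term = _draw_replacement(etype, "".join(seq.tokens[start:end]), cfg, rng)
            tokens.extend(term)  # per-character tokens of the new surface
            labels.append(f"B-{etype}")
            labels.extend([f"I-{etype}"] * (len(term) - 1))
        elif branch == BRANCH_MASK:
            tokens.extend([cfg.mask_token] * (end - start))
            labels.extend(seq.labels[start:end])
        else:
            tokens.extend(seq.tokens[start:end])
            labels.extend(seq.labels[start:end])
        cursor = end
    tokens.extend(seq.tokens[cursor:])
    labels.extend(seq.labels[cursor:])

    if tokens == seq.tokens and labels == seq.labels:
        out = seq
    else:
        offsets, pos = [], 0
        for tok in tokens:
            step = 1 if tok == cfg.mask_token else len(tok)
            offsets.append((pos, pos + step))
            pos += step
        out = TagSequence(tokens, labels, offsets)

    if BRANCH_REPLACE in branches:
        overall = BRANCH_REPLACE
    elif BRANCH_MASK in branches:
        overall = BRANCH_MASK
    else:
        overall = BRANCH_KEEP
    return out, overall


def augment_corpus(
    seqs: list[TagSequence], cfg: DermConfig
) -> tuple[list[TagSequence], list[str]]:
    """One RN per sequence per pass; returns augmented sequences + branch log."""
    rng = np.random.default_rng(cfg.seed)
    out: list[TagSequence] = []
    log: list[str] = []
    for seq in seqs:
        aug, branch = derm_transform(seq, cfg, rng=rng)
        out.append(aug)
        log.append(branch)
    return out, log
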