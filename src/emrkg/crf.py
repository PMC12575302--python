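"""Linear-chain CRF: sequence scoring, partition, decoding, marginals.

The score of a label sequence y for an n-token input is

    Score(X, y) = sum_i S[i, y_i] + sum_i T[y_i, y_{i+1}]

with S the (n, k) emission matrix and T the (k, k) transition matrix;
optional start/end vectors add boundary scores.  The sequence probability is
exp(Score) normalised over all k^n label sequences; the normaliser is
computed by the forward algorithm in log space (log-sum-exp stabilised,
never by enumeration).  Decoding is exact Viterbi with deterministic
tie-breaking toward the lowest label index.

Transition constraints (BIO validity: I-x may only follow B-x or I-x) are
applied as additive -inf masks, so disallowed sequences carry zero
probability mass and decoded sequences are always BIO-valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NEG_INF = -np.inf


class NoValidPathError(ValueError):
    """All label sequences are disallowed by the constraints."""


@dataclass
class LabelScheme:
    """Ordered BIO label set with transition/boundary constraint masks."""

    labels: list[str]
    constrained: bool = True
    allowed_transitions: np.ndarray = field(init=False)
    allowed_starts: np.ndarray = field(init=False)
    allowed_ends: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        k = len(self.labels)
        if len(set(self.labels)) != k:
            raise ValueError("duplicate labels")
        allowed = np.ones((k, k), dtype=bool)
        starts = np.ones(k, dtype=bool)
        ends = np.ones(k, dtype=bool)
        if self.constrained:
            for j, to in enumerate(self.labels):
                if to.startswith("I-"):
                    etype = to[2:]
                    starts[j] = False
                    for i, frm in enumerate(self.labels):
                        allowed[i, j] = frm in (f"B-{etype}", f"I-{etype}")
        self.allowed_transitions = allowed
        self.allowed_starts = starts
        self.allowed_ends = ends

    @classmethod
    def from_entity_types(cls, entity_types, constrained: bool = True) -> "LabelScheme":
        labels = ["O"]
        for t in entity_types:
            labels.extend([f"B-{t}", f"I-{t}"])
        return cls(labels=labels, constrained=constrained)

    @property
    def k(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def transition_penalty(self) -> np.ndarray:
        return np.where(self.allowed_transitions, 0.0, NEG_INF)

    def start_penalty(self) -> np.ndarray:
        return np.where(self.allowed_starts, 0.0, NEG_INF)

    def end_penalty(self) -> np.ndarray:
        return np.where(self.allowed_ends, 0.0, NEG_INF)


def _boundary(vec: np.ndarray | None, k: int) -> np.ndarray:
    return np.zeros(k) if vec is None else np.asarray(vec, dtype=float)


def _masked(S, T, scheme, start, end):
    S = np.asarray(S, dtype=float)
    T = np.asarray(T, dtype=float)
    n, k = S.shape
    start = _boundary(start, k)
    end = _boundary(end, k)
    if scheme is not None and scheme.constrained:
        T = T + scheme.transition_penalty()
        start = start + scheme.start_penalty()
        end = end + scheme.end_penalty()
    return S, T, start, end, n, k


def _logsumexp(a: np.ndarray, axis=None) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True)) + m
    return np.squeeze(out, axis=axis) if axis is not None else out.reshape(())


def sequence_score(
    S: np.ndarray,
    T: np.ndarray,
    y,
    start: np.ndarray | None = None,
    end: np.ndarray | None = None,
) -> float:
    """Emission + transition score of one label-index sequence."""
    S = np.asarray(S, dtype=float)
    T = np.asarray(T, dtype=float)
    y = np.asarray(y, dtype=np.intp)
    n, k = S.shape
    if len(y) != n or (n > 0 and (y.min() < 0 or y.max() >= k)):
        raise IndexError(f"label sequence invalid for {n} positions, {k} labels")
    score = float(S[np.arange(n), y].sum())
    if n > 1:
        score += float(T[y[:-1], y[1:]].sum())
    if start is not None:
        score += float(np.asarray(start)[y[0]])
    if end is not None:
        score += float(np.asarray(end)[y[-1]])
    return score


def log_partition(
    S: np.ndarray,
    T: np.ndarray,
    scheme: LabelScheme | None = None,
    start: np.ndarray | None = None,
    end: np.ndarray | None = None,
) -> float:
    """log sum over all (allowed) label sequences of exp(Score), via the
    forward algorithm in log space."""
    S, T, start, end, n, k = _masked(S, T, scheme, start, end)
    alpha = S[0] + start
    for t in range(1, n):
        alpha = _logsumexp(alpha[:, None] + T + S[t][None, :], axis=0)
    logz = float(_logsumexp(alpha + end))
    if not np.isfinite(logz):
        raise NoValidPathError("all label sequences are disallowed")
    return logz


def nll_loss(
    S: np.ndarray,
    T: np.ndarray,
    y,
    scheme: LabelScheme | None = None,
    start: np.ndarray | None = None,
    end: np.ndarray | None = None,
) -> float:
    """Negative log-probability of y: log Z - Score(X, y).  Always >= 0 for
    allowed y, and exp(-loss) sums to 1 over all sequences."""
    s_start = start
    s_end = end
    if scheme is not None and scheme.constrained:
        k = S.shape[1]
        s_start = _boundary(start, k) + scheme.start_penalty()
        s_end = _boundary(end, k) + scheme.end_penalty()
        T_eff = np.asarray(T, float) + scheme.transition_penalty()
        score = sequence_score(S, T_eff, y, s_start, s_end)
    else:
        score = sequence_score(S, T, y, start, end)
    return log_partition(S, T, scheme, start, end) - score


def viterbi_decode(
    S: np.ndarray,
    T: np.ndarray,
    scheme: LabelScheme | None = None,
    start: np.ndarray | None = None,
    end: np.ndarray | None = None,
) -> tuple[list[int], float]:
    """Exact argmax label sequence and its score.

    Ties are broken toward the lowest label index at every backtrack step
    (np.argmax returns the first maximiser), so decoding is reproducible.
    """
    S, T, start, end, n, k = _masked(S, T, scheme, start, end)
    delta = S[0] + start
    back = np.zeros((n, k), dtype=np.intp)
    for t in range(1, n):
        cand = delta[:, None] + T  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(k)] + S[t]
    delta = delta + end
    best_last = int(np.argmax(delta))
    best_score = float(delta[best_last])
    if not np.isfinite(best_score):
        raise NoValidPathError("all label sequences are disallowed")
    path = [best_last]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    return path[::-1], best_score


# ---------------------------------------------------------------------------
# batched training pass (forward-backward marginals)
# ---------------------------------------------------------------------------


def nll_and_grads_batch(
    S: np.ndarray,
    T: np.ndarray,
    tags: np.ndarray,
    scheme: LabelScheme | None = None,
    start: np.ndarray | None = None,
    end: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Total NLL over a batch of same-length sequences plus its analytic
    gradients: dS (B,n,k), dT (k,k), dstart (k,), dend (k,).

    Gradients are expectation-minus-observation: unary/pairwise marginals
    from the forward-backward recursions minus the gold one-hot counts.
    """
    S = np.asarray(S, dtype=float)
    B, n, k = S.shape
    tags = np.asarray(tags, dtype=np.intp)
    T_eff = np.asarray(T, dtype=float)
    start_eff = _boundary(start, k)
    end_eff = _boundary(end, k)
    if scheme is not None and scheme.constrained:
        T_eff = T_eff + scheme.transition_penalty()
        start_eff = start_eff + scheme.start_penalty()
        end_eff = end_eff + scheme.end_penalty()

    def _lse(a: np.ndarray, axis: int) -> np.ndarray:
        m = a.max(axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        with np.errstate(divide="ignore"):
            return np.log(np.exp(a - m).sum(axis=axis)) + np.squeeze(m, axis=axis)

    # forward
    alpha = np.empty((B, n, k))
    alpha[:, 0] = S[:, 0] + start_eff
    for t in range(1, n):
        prev = alpha[:, t - 1][:, :, None] + T_eff[None, :, :]
        alpha[:, t] = _lse(prev, axis=1) + S[:, t]
    logz = _lse(alpha[:, n - 1] + end_eff, axis=1)
    if not np.all(np.isfinite(logz)):
        raise NoValidPathError("all label sequences are disallowed")

    # backward
    beta = np.empty((B, n, k))
    beta[:, n - 1] = end_eff
    for t in range(n - 2, -1, -1):
        nxt = T_eff[None, :, :] + (S[:, t + 1] + beta[:, t + 1])[:, None, :]
        beta[:, t] = _lse(nxt, axis=2)

    # unary marginals and gradients
    log_unary = alpha + beta - logz[:, None, None]
    unary = np.exp(log_unary)
    dS = unary.copy()
    rows = np.arange(B)[:, None], np.arange(n)[None, :]
    dS[rows[0], rows[1], tags] -= 1.0

    # pairwise marginals summed over batch and time
    dT = np.zeros((k, k))
    for t in range(n - 1):
        lp = (
            alpha[:, t][:, :, None]
            + T_eff[None, :, :]
            + (S[:, t + 1] + beta[:, t + 1])[:, None, :]
            - logz[:, None, None]
        )
        dT += np.exp(lp).sum(axis=0)
    if n > 1:
        idx_from = tags[:, :-1].ravel()
        idx_to = tags[:, 1:].ravel()
        np.subtract.at(dT, (idx_from, idx_to), 1.0)

    dstart = np.exp(log_unary[:, 0]).sum(axis=0)
    np.subtract.at(dstart, tags[:, 0], 1.0)
    dend = np.exp(alpha[:, n - 1] + end_eff - logz[:, None]).sum(axis=0)
    np.subtract.at(dend, tags[:, n - 1], 1.0)

    # total NLL = sum(logz) - sum(gold scores)
    gold = S[rows[0], rows[1], tags].sum()
    if n > 1:
        gold += T_eff[tags[:, :-1], tags[:, 1:]].sum()
    gold += start_eff[tags[:, 0]].sum() + end_eff[tags[:, n - 1]].sum()
    loss = float(logz.sum() - gold)
    return loss, dS, dT, dstart, dend
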