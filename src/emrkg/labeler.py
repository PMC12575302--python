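"""BiLSTM-CRF sequence labeler over pluggable encoders.

Pipeline per sequence: encoder context vectors H (excluding the [CLS]/[SEP]
positions, which carry no labels) -> forward and backward LSTM passes whose
states are concatenated per position, h_i = [h_fwd_i ; h_bwd_i] of width 2h
-> affine emission scores S_i = W h_i + b over the k BIO labels -> CRF loss
(negative log-likelihood with the forward-algorithm normaliser) for training
and constrained Viterbi decoding for prediction.

Training is plain mini-batch Adam on the exact CRF likelihood; sequences are
bucketed by length so batches need no padding.  Optimiser settings are
package defaults (documented in the config), chosen for the desk-scale
synthetic corpus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import autograd as ag
from . import crf
from .autograd import Tensor
from .corpus_io import TagSequence
from .crf import LabelScheme
from .encoder import EncoderConfig, make_encoder, tokens_to_ids, wrap_tokens


@dataclass
class LstmParams:
    """One direction's cell: gates = x W_x + h W_h + b, gate order i,f,g,o."""

    W_x: Tensor
    W_h: Tensor
    b: Tensor

    @property
    def hidden(self) -> int:
        return self.W_h.shape[0]


def init_lstm(d_in: int, hidden: int, rng: np.random.Generator) -> LstmParams:
    s = 1.0 / np.sqrt(hidden)
    return LstmParams(
        W_x=ag.parameter((d_in, 4 * hidden), rng, s),
        W_h=ag.parameter((hidden, 4 * hidden), rng, s),
        b=ag.parameter(np.zeros(4 * hidden)),
    )


def _lstm_pass(x: Tensor, p: LstmParams, reverse: bool = False) -> list[Tensor]:
    """Run one direction over x (B, L, d); returns per-step states (B, h),
    indexed by original position regardless of direction."""
    B, L, _ = x.shape
    h = p.hidden
    h_t = Tensor(np.zeros((B, h)))
    c_t = Tensor(np.zeros((B, h)))
    states: list[Tensor] = [None] * L  # type: ignore[list-item]
    steps = range(L - 1, -1, -1) if reverse else range(L)
    for t in steps:
        xt = x[:, t, :]
        gates = ag.matmul(xt, p.W_x) + ag.matmul(h_t, p.W_h) + p.b
        i = ag.sigmoid(gates[:, 0 * h : 1 * h])
        f = ag.sigmoid(gates[:, 1 * h : 2 * h])
        g = ag.tanh(gates[:, 2 * h : 3 * h])
        o = ag.sigmoid(gates[:, 3 * h : 4 * h])
        c_t = f * c_t + i * g
        h_t = o * ag.tanh(c_t)
        states[t] = h_t
    return states


def bilstm_hidden_batch(x: Tensor, fwd: LstmParams, bwd: LstmParams) -> Tensor:
    """Concatenated bidirectional states, (B, L, 2h)."""
    f_states = _lstm_pass(x, fwd, reverse=False)
    b_states = _lstm_pass(x, bwd, reverse=True)
    per_t = [ag.concat([f, b], axis=-1) for f, b in zip(f_states, b_states)]
    return ag.stack(per_t, axis=1)


def bilstm_hidden(H: np.ndarray, fwd: LstmParams, bwd: LstmParams) -> np.ndarray:
    """Functional form on a single (n, d) context matrix -> (n, 2h)."""
    with ag.no_grad():
        return bilstm_hidden_batch(Tensor(H[None]), fwd, bwd).data[0]


def emission_scores(h_seq: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """S[i] = W h_i + b; h_seq (n, 2h), W (k, 2h), b (k) -> S (n, k)."""
    h_seq = np.asarray(h_seq, float)
    W = np.asarray(W, float)
    if h_seq.shape[1] != W.shape[1]:
        raise ValueError(
            f"hidden width {h_seq.shape[1]} does not match W width {W.shape[1]}"
        )
    return h_seq @ W.T + np.asarray(b, float)


class _CrfLoss:
    """Bridges the analytic CRF gradients into the autograd graph."""

    @staticmethod
    def apply(
        S: Tensor, T: Tensor, start: Tensor, end: Tensor,
        tags: np.ndarray, scheme: LabelScheme,
    ) -> Tensor:
        loss, dS, dT, dstart, dend = crf.nll_and_grads_batch(
            S.data, T.data, tags, scheme, start.data, end.data
        )
        out = Tensor(np.float64(loss))
        out._parents = (S, T, start, end)
        out._backward = lambda g: [
            (S, g * dS), (T, g * dT), (start, g * dstart), (end, g * dend)
        ]
        return out


@dataclass
class TrainConfig:
    epochs: int = 12
    lr: float = 0.01
    batch_size: int = 32
    grad_clip: float = 5.0
    seed: int = 0
    #: re-augment the corpus every epoch (per-epoch DERM) when an augmenter
    #: callable is supplied to fit(); set False to augment once up front
    augment_each_epoch: bool = True


class NerTagger:
    """Encoder + BiLSTM + CRF named-entity tagger."""

    def __init__(
        self,
        encoder_cfg: EncoderConfig,
        scheme: LabelScheme,
        hidden: int = 16,
        encoder_kind: str = "transformer",
        seed: int = 0,
    ):
        self.scheme = scheme
        self.encoder = make_encoder(encoder_cfg, encoder_kind)
        rng = np.random.default_rng(seed + 17)
        d = encoder_cfg.d_model
        k = scheme.k
        self.fwd = init_lstm(d, hidden, rng)
        self.bwd = init_lstm(d, hidden, rng)
        s = 1.0 / np.sqrt(2 * hidden)
        self.W = ag.parameter((2 * hidden, k), rng, s)  # stored transposed
        self.b = ag.parameter(np.zeros(k))
        self.T = ag.parameter(np.zeros((k, k)))
        self.start = ag.parameter(np.zeros(k))
        self.end = ag.parameter(np.zeros(k))
        self.history: list[float] = []

    def params(self) -> list[Tensor]:
        return [
            *self.encoder.params(),
            self.fwd.W_x, self.fwd.W_h, self.fwd.b,
            self.bwd.W_x, self.bwd.W_h, self.bwd.b,
            self.W, self.b, self.T, self.start, self.end,
        ]

    # -- forward ------------------------------------------------------------

    def _emissions_batch(self, ids: np.ndarray) -> Tensor:
        """ids (B, L+2) wrapped -> emission Tensor (B, L, k)."""
        H = self.encoder.forward_batch(ids)
        H_tokens = H[:, 1:-1, :]  # [CLS]/[SEP] carry no labels
        h_seq = bilstm_hidden_batch(H_tokens, self.fwd, self.bwd)
        B, L, _ = h_seq.shape
        flat = h_seq.reshape((B * L, h_seq.shape[-1]))
        S = ag.matmul(flat, self.W) + self.b
        return S.reshape((B, L, self.scheme.k))

    def _ids(self, seqs: Sequence[TagSequence]) -> np.ndarray:
        return np.stack(
            [tokens_to_ids(wrap_tokens(s.tokens), self.encoder.vocab) for s in seqs]
        )

    def batch_loss(self, seqs: Sequence[TagSequence]) -> Tensor:
        tags = np.stack(
            [[self.scheme.index(lab) for lab in s.labels] for s in seqs]
        )
        S = self._emissions_batch(self._ids(seqs))
        return _CrfLoss.apply(S, self.T, self.start, self.end, tags, self.scheme)

    def emissions(self, seq: TagSequence) -> np.ndarray:
        with ag.no_grad():
            return self._emissions_batch(self._ids([seq])).data[0]

    def predict(self, seqs: Sequence[TagSequence]) -> list[TagSequence]:
        """Viterbi-decoded copies of the input sequences (input order kept)."""
        out: list[TagSequence | None] = [None] * len(seqs)
        for group in _buckets(list(enumerate(seqs)), 256, key=lambda p: len(p[1])):
            batch = [seq for _, seq in group]
            with ag.no_grad():
                S = self._emissions_batch(self._ids(batch)).data
            for (idx, seq), emissions in zip(group, S):
                path, _ = crf.viterbi_decode(
                    emissions, self.T.data, self.scheme,
                    self.start.data, self.end.data,
                )
                out[idx] = TagSequence(
                    list(seq.tokens),
                    [self.scheme.labels[i] for i in path],
                    seq.char_offsets,
                )
        return out  # type: ignore[return-value]

    def mean_nll(self, seqs: Sequence[TagSequence]) -> float:
        total = 0.0
        for group in _buckets(seqs, 256):
            total += float(self.batch_loss(group).data)
        return total / len(seqs)


def _buckets(seqs: Sequence, batch_size: int, key=len) -> list[list]:
    """Group items of equal sequence length into batches (no padding needed)."""
    by_len: dict[int, list] = {}
    for s in seqs:
        by_len.setdefault(key(s), []).append(s)
    batches = []
    for length in sorted(by_len):
        group = by_len[length]
        for i in range(0, len(group), batch_size):
            batches.append(group[i : i + batch_size])
    return batches


def fit(
    corpus: Sequence[TagSequence],
    encoder_cfg: EncoderConfig,
    scheme: LabelScheme | None = None,
    train_cfg: TrainConfig | None = None,
    hidden: int = 16,
    encoder_kind: str = "transformer",
    augmenter: Callable[[Sequence[TagSequence], int], list[TagSequence]] | None = None,
    dev: Sequence[TagSequence] | None = None,
) -> NerTagger:
    """Train a BiLSTM-CRF tagger by mini-batch gradient descent on the CRF
    negative log-likelihood.  Deterministic given the config seeds.

    ``augmenter(seqs, epoch)`` (e.g. a DERM pass) is re-applied every epoch
    when ``train_cfg.augment_each_epoch``, else once before training.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    train_cfg = train_cfg or TrainConfig()
    if scheme is None:
        types = sorted(
            {lab[2:] for s in corpus for lab in s.labels if lab != "O"}
        )
        scheme = LabelScheme.from_entity_types(types)

    model = NerTagger(encoder_cfg, scheme, hidden, encoder_kind, seed=train_cfg.seed)
    opt = ag.Adam(model.params(), lr=train_cfg.lr)
    rng = np.random.default_rng(train_cfg.seed + 101)

    base = list(corpus)
    if augmenter is not None and not train_cfg.augment_each_epoch:
        base = augmenter(base, 0)

    model.history.append(model.mean_nll(base))
    for epoch in range(train_cfg.epochs):
        seqs = (
            augmenter(list(corpus), epoch)
            if augmenter is not None and train_cfg.augment_each_epoch
            else base
        )
        batches = _buckets(seqs, train_cfg.batch_size)
        order = rng.permutation(len(batches))
        total = 0.0
        for bi in order:
            batch = batches[bi]
            opt.zero_grad()
            loss = model.batch_loss(batch) * (1.0 / len(batch))
            loss.backward()
            if train_cfg.grad_clip:
                for p in opt.params:
                    if p.grad is not None:
                        norm = np.linalg.norm(p.grad)
                        if norm > train_cfg.grad_clip:
                            p.grad *= train_cfg.grad_clip / norm
            opt.step()
            total += float(loss.data) * len(batch)
        epoch_loss = total / len(seqs)
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: loss={epoch_loss}"
            )
        model.history.append(epoch_loss)
    return model
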