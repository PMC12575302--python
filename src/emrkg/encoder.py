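"""Token embedding and transformer encoding of clinical sequences.

The contract is ``token sequence -> contextual vectors H = [H_CLS, H_1..H_n,
H_SEP]``, each of width ``d_model``.  Input vectors are the elementwise sum
of token, position and segment embeddings; each encoder layer applies
multi-head scaled dot-product attention, ``softmax(Q K^T / sqrt(d_k)) V``,
followed by a position-wise feed-forward sublayer.  Residual connections and
layer normalisation are included: attention and feed-forward maps alone do
not train stably, so the blocks follow the standard post-norm transformer
layout.

Two interchangeable encoders satisfy the contract:

* :class:`TransformerEncoder` — the trainable stack, at configurable depth
  (desk-scale default: 2 layers, 16-dim, 2 heads; a production analogue
  would stack 24 wide layers on pretrained weights);
* :class:`LookupEncoder` — embedding lookup only, for fast tests and as an
  adapter point for externally supplied vectors.

Functional NumPy forms of the building blocks (:func:`embed_input`,
:func:`attention`, :func:`multi_head`) are exposed for direct verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autograd as ag
from .autograd import Tensor

PAD, UNK, CLS, SEP, MASK = "[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"
SPECIAL_TOKENS = (PAD, UNK, CLS, SEP, MASK)


def build_vocab(sequences: Sequence[Sequence[str]]) -> dict[str, int]:
    """Token -> index map with the special tokens at fixed low indices."""
    vocab = {tok: i for i, tok in enumerate(SPECIAL_TOKENS)}
    for seq in sequences:
        for tok in seq:
            if tok not in vocab:
                vocab[tok] = len(vocab)
    return vocab


def write_vocab(vocab: dict[str, int], path) -> None:
    ordered = sorted(vocab, key=vocab.get)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(ordered) + "\n")


def read_vocab(path) -> dict[str, int]:
    with open(path, "r", encoding="utf-8") as fh:
        return {line.rstrip("\n"): i for i, line in enumerate(fh) if line.rstrip("\n")}


@dataclass
class EncoderConfig:
    vocab: dict[str, int]
    d_model: int = 16
    n_layers: int = 2
    n_heads: int = 2
    d_ff: int = 32
    max_len: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model {self.d_model} must be a multiple of n_heads {self.n_heads}"
            )
        for tok in SPECIAL_TOKENS:
            if tok not in self.vocab:
                raise ValueError(f"vocab missing special token {tok}")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


@dataclass
class EmbeddingTables:
    """Token/position/segment lookup tables, all of width d_model."""

    vocab: dict[str, int]
    token_table: np.ndarray
    position_table: np.ndarray
    segment_table: np.ndarray

    def __post_init__(self) -> None:
        d = self.token_table.shape[1]
        if self.position_table.shape[1] != d or self.segment_table.shape[1] != d:
            raise ValueError("all embedding tables must share width d_model")


@dataclass
class ContextVectors:
    """Encoder output: one d-dim vector per position incl. [CLS]/[SEP]."""

    tokens: list[str]  # wrapped sequence, [CLS] ... [SEP]
    H: np.ndarray  # (len(tokens), d_model)


def wrap_tokens(tokens: Sequence[str]) -> list[str]:
    return [CLS, *tokens, SEP]


def tokens_to_ids(tokens: Sequence[str], vocab: dict[str, int]) -> np.ndarray:
    unk = vocab[UNK]
    return np.array([vocab.get(t, unk) for t in tokens], dtype=np.intp)


# ---------------------------------------------------------------------------
# functional building blocks (NumPy)
# ---------------------------------------------------------------------------


def embed_input(
    tokens: Sequence[str],
    tables: EmbeddingTables,
    segment_ids: Sequence[int] | None = None,
) -> np.ndarray:
    """E_input = E_t + E_p + E_s for an already-wrapped token sequence.

    Inputs are single sentences, so the segment id defaults to 0 everywhere.
    """
    n = len(tokens)
    if n > tables.position_table.shape[0]:
        raise ValueError(
            f"sequence length {n} exceeds positional table size "
            f"{tables.position_table.shape[0]}"
        )
    ids = tokens_to_ids(tokens, tables.vocab)
    seg = np.zeros(n, dtype=np.intp) if segment_ids is None else np.asarray(segment_ids)
    return (
        tables.token_table[ids]
        + tables.position_table[:n]
        + tables.segment_table[seg]
    )


def attention(
    Q: np.ndarray,
    K: np.ndarray,
    V: np.ndarray,
    d_k: int | None = None,
    return_weights: bool = False,
):
    """Scaled dot-product attention: softmax(Q K^T / sqrt(d_k)) V."""
    Q, K, V = np.asarray(Q, float), np.asarray(K, float), np.asarray(V, float)
    if d_k is None:
        d_k = Q.shape[-1]
    if d_k <= 0:
        raise ValueError(f"d_k must be positive, got {d_k}")
    logits = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    logits -= logits.max(axis=-1, keepdims=True)
    w = np.exp(logits)
    w /= w.sum(axis=-1, keepdims=True)
    out = w @ V
    return (out, w) if return_weights else out


@dataclass
class AttentionHead:
    """Per-head projections of Q, K and V."""

    W_q: np.ndarray
    W_k: np.ndarray
    W_v: np.ndarray


def multi_head(
    Q: np.ndarray,
    K: np.ndarray,
    V: np.ndarray,
    heads: Sequence[AttentionHead],
    W_o: np.ndarray,
) -> np.ndarray:
    """Concat(head_1, ..., head_n) W_o with head_i = attention(QW_q, KW_k, VW_v)."""
    outs = [
        attention(Q @ h.W_q, K @ h.W_k, V @ h.W_v, d_k=h.W_k.shape[1]) for h in heads
    ]
    concat = np.concatenate(outs, axis=-1)
    if concat.shape[-1] != W_o.shape[0]:
        raise ValueError(
            f"concatenated head width {concat.shape[-1]} does not match "
            f"W_o input width {W_o.shape[0]}"
        )
    return concat @ W_o


# ---------------------------------------------------------------------------
# trainable encoders
# ---------------------------------------------------------------------------


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    m = x.mean(axis=-1, keepdims=True)
    centered = x - m
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * ((var + eps) ** -0.5) * gamma + beta


class TransformerEncoder:
    """Trainable toy transformer implementing the encoder contract."""

    def __init__(self, cfg: EncoderConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d, V = cfg.d_model, len(cfg.vocab)
        s = 1.0 / np.sqrt(d)
        self.token_table = ag.parameter((V, d), rng, s)
        self.position_table = ag.parameter((cfg.max_len, d), rng, s)
        self.segment_table = ag.parameter((2, d), rng, s)
        self.layers: list[dict[str, Tensor]] = []
        for _ in range(cfg.n_layers):
            layer = {
                "W_q": ag.parameter((d, d), rng, s),
                "W_k": ag.parameter((d, d), rng, s),
                "W_v": ag.parameter((d, d), rng, s),
                "W_o": ag.parameter((d, d), rng, s),
                "W_ff1": ag.parameter((d, cfg.d_ff), rng, s),
                "b_ff1": ag.parameter(np.zeros(cfg.d_ff)),
                "W_ff2": ag.parameter((cfg.d_ff, d), rng, 1.0 / np.sqrt(cfg.d_ff)),
                "b_ff2": ag.parameter(np.zeros(d)),
                "ln1_g": ag.parameter(np.ones(d)),
                "ln1_b": ag.parameter(np.zeros(d)),
                "ln2_g": ag.parameter(np.ones(d)),
                "ln2_b": ag.parameter(np.zeros(d)),
            }
            self.layers.append(layer)

    @property
    def vocab(self) -> dict[str, int]:
        return self.cfg.vocab

    @property
    def d_out(self) -> int:
        return self.cfg.d_model

    def params(self) -> list[Tensor]:
        out = [self.token_table, self.position_table, self.segment_table]
        for layer in self.layers:
            out.extend(layer.values())
        return out

    def tables(self) -> EmbeddingTables:
        return EmbeddingTables(
            self.cfg.vocab,
            self.token_table.data,
            self.position_table.data,
            self.segment_table.data,
        )

    def forward_batch(self, ids: np.ndarray) -> Tensor:
        """ids: (B, L) wrapped token ids -> contextual Tensor (B, L, d)."""
        B, L = ids.shape
        if L > self.cfg.max_len:
            raise ValueError(f"length {L} exceeds max_len {self.cfg.max_len}")
        x = (
            self.token_table[ids]
            + self.position_table[:L]
            + self.segment_table[np.zeros(L, dtype=np.intp)]
        )
        n_heads, d_k, d = self.cfg.n_heads, self.cfg.d_k, self.cfg.d_model
        for layer in self.layers:
            q = ag.matmul(x, layer["W_q"])
            k = ag.matmul(x, layer["W_k"])
            v = ag.matmul(x, layer["W_v"])

            def split_heads(t: Tensor) -> Tensor:
                return ag.swapaxes(t.reshape((B, L, n_heads, d_k)), 1, 2)

            qh, kh, vh = split_heads(q), split_heads(k), split_heads(v)
            logits = ag.matmul(qh, ag.swapaxes(kh, -1, -2)) * (1.0 / np.sqrt(d_k))
            weights = ag.softmax(logits, axis=-1)
            ctx = ag.matmul(weights, vh)  # (B, h, L, d_k)
            ctx = ag.swapaxes(ctx, 1, 2).reshape((B, L, d))
            attn_out = ag.matmul(ctx, layer["W_o"])
            x = _layer_norm(x + attn_out, layer["ln1_g"], layer["ln1_b"])
            ff = ag.matmul(
                ag.relu(ag.matmul(x, layer["W_ff1"]) + layer["b_ff1"]),
                layer["W_ff2"],
            ) + layer["b_ff2"]
            x = _layer_norm(x + ff, layer["ln2_g"], layer["ln2_b"])
        return x

    def encode(self, tokens: Sequence[str]) -> ContextVectors:
        """Single-sequence inference: wraps with [CLS]/[SEP]."""
        wrapped = wrap_tokens(tokens)
        ids = tokens_to_ids(wrapped, self.cfg.vocab)[None, :]
        with ag.no_grad():
            H = self.forward_batch(ids).data[0]
        return ContextVectors(tokens=wrapped, H=H)


class LookupEncoder:
    """Embedding-only encoder: H equals E_input (a zero-layer stack)."""

    def __init__(self, cfg: EncoderConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d, V = cfg.d_model, len(cfg.vocab)
        s = 1.0 / np.sqrt(d)
        self.token_table = ag.parameter((V, d), rng, s)
        self.position_table = ag.parameter((cfg.max_len, d), rng, s)
        self.segment_table = ag.parameter((2, d), rng, s)

    vocab = TransformerEncoder.vocab
    d_out = TransformerEncoder.d_out
    tables = TransformerEncoder.tables

    def params(self) -> list[Tensor]:
        return [self.token_table, self.position_table, self.segment_table]

    def forward_batch(self, ids: np.ndarray) -> Tensor:
        B, L = ids.shape
        if L > self.cfg.max_len:
            raise ValueError(f"length {L} exceeds max_len {self.cfg.max_len}")
        return (
            self.token_table[ids]
            + self.position_table[:L]
            + self.segment_table[np.zeros(L, dtype=np.intp)]
        )

    encode = TransformerEncoder.encode


def make_encoder(cfg: EncoderConfig, kind: str = "transformer"):
    if kind == "transformer":
        return TransformerEncoder(cfg)
    if kind == "lookup":
        return LookupEncoder(cfg)
    raise ValueError(f"unknown encoder kind {kind!r}")
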