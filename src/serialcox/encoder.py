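"""Report encoding: tokens -> token embeddings -> one vector per report.

The encoder mirrors the first two stages of the pipeline: a pluggable
embedding backbone maps each token of a report to a d-dimensional vector,
and additive (Bahdanau-style) attention pools the token embeddings into a
single report vector, returning the attention weights for inspection.

Two backbones ship with the package: a desk-scale trainable lookup-table
embedding (position-free, out-of-vocabulary tokens collapse to a shared
UNK vector), and a thin adapter for any external encoder object exposing
``encode(tokens) -> (n, d)`` (e.g. a transformer pipeline loaded from a
local path).  The lookup backbone is the default and the only one the
test-suite exercises.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .corpus import Report

__all__ = [
    "TokenSequence",
    "tokenize",
    "EmbeddingBackbone",
    "LookupEmbeddingBackbone",
    "ExternalEncoderBackbone",
    "build_vocab",
    "AttentionParams",
    "ReportVector",
    "attention_pool",
    "embed_tokens",
    "encode_report",
    "UNK_TOKEN",
]

UNK_TOKEN = "<unk>"

# words and alphanumeric codes, keeping internal hyphens ("m-rectum", "t3")
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")

DEFAULT_MAX_TOKENS = 512


@dataclass(frozen=True)
class TokenSequence:
    tokens: tuple[str, ...]
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize(text: str, max_tokens: int = DEFAULT_MAX_TOKENS) -> TokenSequence:
    """Lowercase and split on whitespace/punctuation, keeping hyphenated codes.

    Truncation keeps the head of the report (findings precede the
    impression in radiology reports); the flag records whether tokens
    were dropped.
    """
    if text is None or not text.strip():
        raise ValueError("cannot tokenize empty or whitespace-only text")
    tokens = _TOKEN_RE.findall(text.lower())
    if not tokens:
        raise ValueError(f"text has no tokens after tokenization: {text!r}")
    truncated = len(tokens) > max_tokens
    return TokenSequence(tuple(tokens[:max_tokens]), truncated=truncated)


@runtime_checkable
class EmbeddingBackbone(Protocol):
    """Maps a token sequence to an (n, d) array, deterministically."""

    dim: int
    context_sensitive: bool

    def encode(self, tokens: tuple[str, ...]) -> np.ndarray: ...


def build_vocab(texts, max_tokens: int = DEFAULT_MAX_TOKENS) -> dict[str, int]:
    """Token -> index map over an iterable of texts; index 0 is the UNK slot."""
    vocab: dict[str, int] = {UNK_TOKEN: 0}
    for text in texts:
        for tok in tokenize(text, max_tokens).tokens:
            if tok not in vocab:
                vocab[tok] = len(vocab)
    return vocab


class LookupEmbeddingBackbone:
    """Trainable lookup-table embedding; position-free; OOV -> shared UNK row."""

    context_sensitive = False

    def __init__(self, vocab: dict[str, int], dim: int = 32, seed: int = 0,
                 table: np.ndarray | None = None):
        self.vocab = dict(vocab)
        self.dim = int(dim)
        if table is not None:
            table = np.asarray(table, dtype=float)
            if table.shape != (len(self.vocab), self.dim):
                raise ValueError(
                    f"table shape {table.shape} != ({len(self.vocab)}, {self.dim})"
                )
            self.table = table
        else:
            rng = np.random.default_rng(seed)
            self.table = rng.normal(0.0, 0.1, size=(len(self.vocab), self.dim))

    def token_ids(self, tokens) -> np.ndarray:
        unk = self.vocab[UNK_TOKEN]
        return np.array([self.vocab.get(t, unk) for t in tokens], dtype=np.int64)

    def encode(self, tokens) -> np.ndarray:
        if len(tokens) == 0:
            raise ValueError("cannot embed an empty token sequence")
        return self.table[self.token_ids(tokens)]


class ExternalEncoderBackbone:
    """Adapter for an external (possibly context-sensitive) encoder object.

    The wrapped object must expose ``encode(list_of_tokens) -> (n, d)``;
    this covers transformer pipelines loaded from a local checkpoint.
    """

    context_sensitive = True

    def __init__(self, encoder, dim: int):
        self._encoder = encoder
        self.dim = int(dim)

    def encode(self, tokens) -> np.ndarray:
        if len(tokens) == 0:
            raise ValueError("cannot embed an empty token sequence")
        out = np.asarray(self._encoder.encode(list(tokens)), dtype=float)
        if out.shape != (len(tokens), self.dim):
            raise ValueError(f"external encoder returned shape {out.shape}")
        return out


def embed_tokens(tokens: TokenSequence | tuple[str, ...],
                 backbone: EmbeddingBackbone) -> np.ndarray:
    """(n, d) token-embedding matrix for one report."""
    toks = tokens.tokens if isinstance(tokens, TokenSequence) else tuple(tokens)
    if len(toks) == 0:
        raise ValueError("cannot embed an empty token sequence")
    return np.asarray(backbone.encode(toks), dtype=float)


@dataclass
class AttentionParams:
    """Additive attention: score(h) = v . tanh(W h)."""

    W: np.ndarray  # (d_a, d)
    v: np.ndarray  # (d_a,)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.W.ndim != 2 or self.v.ndim != 1 or self.W.shape[0] != self.v.shape[0]:
            raise ValueError(f"inconsistent attention shapes {self.W.shape}, {self.v.shape}")
        if not (np.isfinite(self.W).all() and np.isfinite(self.v).all()):
            raise ValueError("attention parameters must be finite")

    @classmethod
    def init(cls, d: int, d_a: int | None = None, seed: int = 0) -> "AttentionParams":
        d_a = d if d_a is None else d_a
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(d)
        return cls(W=rng.uniform(-scale, scale, size=(d_a, d)),
                   v=rng.uniform(-scale, scale, size=d_a))


@dataclass(frozen=True)
class ReportVector:
    """Pooled report embedding plus the attention weights that produced it."""

    values: np.ndarray  # (d,)
    attention_weights: np.ndarray  # (n,), non-negative, sums to 1

    def __post_init__(self) -> None:
        w = np.asarray(self.attention_weights, dtype=float)
        if (w < -1e-12).any() or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("attention weights must be a probability vector")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "attention_weights", w)


def attention_pool(H: np.ndarray, params: AttentionParams) -> ReportVector:
    """Pool token embeddings: a = softmax(v . tanh(W h_i)); out = sum a_i h_i."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError(f"H must be (n, d) with n >= 1, got {H.shape}")
    if params.W.shape[1] != H.shape[1]:
        raise ValueError(
            f"attention W expects d={params.W.shape[1]}, H has d={H.shape[1]}"
        )
    scores = np.tanh(H @ params.W.T) @ params.v
    scores = scores - scores.max()
    weights = np.exp(scores)
    weights /= weights.sum()
    return ReportVector(values=weights @ H, attention_weights=weights)


def encode_report(report: Report, backbone: EmbeddingBackbone,
                  attn: AttentionParams,
                  max_tokens: int = DEFAULT_MAX_TOKENS) -> ReportVector:
    """tokenize -> embed -> attention-pool one report."""
    seq = tokenize(report.text, max_tokens=max_tokens)
    H = embed_tokens(seq, backbone)
    return attention_pool(H, attn)
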