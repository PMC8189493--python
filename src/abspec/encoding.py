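"""Tokenization and the token-level encoder behind the classifiers.

The classifiers in this package treat the encoder as a black box mapping a
token-id sequence ``([CLS], s, [SEP], t)`` to one contextual vector per token.
Any object implementing :class:`TokenEncoder` can be plugged in; the bundled
implementation is :class:`TinyTransformerEncoder`, a small seeded transformer
(2 layers, 32 dimensions by default) whose weights are drawn once from a fixed
RNG and then frozen.  It provides deterministic, training-free contextual
features so the full pipeline runs offline and reproducibly; swapping in a
pretrained scientific-text transformer only requires honouring the same
protocol.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "HashTokenizer",
    "AspectInstance",
    "EncoderOutput",
    "TokenEncoder",
    "TinyTransformerEncoder",
    "build_input",
    "encode_instance",
]

CLS_ID = 0
SEP_ID = 1
_RESERVED = 2

_TOKEN_RE = re.compile(r"[A-Za-z0-9_~µα-ωΑ-Ω-]+")


@dataclass(frozen=True)
class HashTokenizer:
    """Word tokenizer with a stable hashed vocabulary.

    Tokens are lowercased alphanumeric runs (hyphen/underscore kept, so clone
    names like ``anti-Panx1`` stay whole).  Ids come from a cryptographic hash
    of the token, so the mapping is stable across runs and machines without a
    fitted vocabulary file.
    """

    vocab_size: int = 4096

    def tokenize(self, text: str) -> list[str]:
        return [t.lower() for t in _TOKEN_RE.findall(text)]

    def token_id(self, token: str) -> int:
        h = hashlib.blake2s(token.encode("utf-8"), digest_size=4).digest()
        return _RESERVED + int.from_bytes(h, "little") % (self.vocab_size - _RESERVED)

    def ids(self, tokens: Sequence[str]) -> list[int]:
        return [self.token_id(t) for t in tokens]


@dataclass
class AspectInstance:
    """A snippet/aspect token pair, optionally labeled.

    ``token_ids`` is the assembled encoder input ``[CLS] s [SEP] t``; the
    snippet occupies positions ``1..n`` and the aspect ``n+2..n+m+1``.
    """

    snippet_tokens: list[str]
    aspect_tokens: list[str]
    token_ids: list[int]
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.snippet_tokens or not self.aspect_tokens:
            raise ValueError("snippet and aspect must each have at least one token")
        expect = 2 + len(self.snippet_tokens) + len(self.aspect_tokens)
        if len(self.token_ids) != expect:
            raise ValueError("token_ids must be [CLS] + snippet + [SEP] + aspect")

    @property
    def n(self) -> int:
        return len(self.snippet_tokens)

    @property
    def m(self) -> int:
        return len(self.aspect_tokens)


def build_input(
    snippet: str,
    aspect: str,
    tokenizer: HashTokenizer,
    max_len: int = 256,
    label: str | None = None,
) -> AspectInstance:
    """Assemble the ``[CLS] s [SEP] t`` encoder input for one snippet/aspect.

    When the combined length exceeds ``max_len``, snippet tokens are dropped
    from the end first; aspect tokens are never truncated.
    """
    if not snippet or not snippet.strip():
        raise ValueError("empty snippet")
    if not aspect or not aspect.strip():
        raise ValueError("empty aspect")
    s = tokenizer.tokenize(snippet)
    t = tokenizer.tokenize(aspect)
    if not s or not t:
        raise ValueError("snippet/aspect contained no tokens")
    if len(t) > max_len // 2:
        raise ValueError(f"aspect of {len(t)} tokens exceeds max_len/2 = {max_len // 2}")
    budget = max_len - 2 - len(t)
    if len(s) > budget:
        s = s[:budget]
    ids = [CLS_ID] + tokenizer.ids(s) + [SEP_ID] + tokenizer.ids(t)
    return AspectInstance(snippet_tokens=s, aspect_tokens=t, token_ids=ids, label=label)


@dataclass(frozen=True)
class EncoderOutput:
    """Last-layer contextual vectors with the slices the AOA head consumes."""

    H: np.ndarray  # (n+m+2, d)
    L: int
    n: int
    m: int

    @property
    def h0(self) -> np.ndarray:
        return self.H[0]

    @property
    def a(self) -> np.ndarray:
        """Snippet slice h_1..h_n."""
        return self.H[1 : 1 + self.n]

    @property
    def b(self) -> np.ndarray:
        """Aspect slice h_{n+2}..h_{n+m+1}."""
        return self.H[2 + self.n : 2 + self.n + self.m]


class TokenEncoder(Protocol):
    dim: int
    n_layers: int

    def forward(self, token_ids: Sequence[int]) -> np.ndarray:
        """Map token ids to an (len, dim) matrix of contextual vectors."""
        ...


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _layer_norm(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


@dataclass
class TinyTransformerEncoder:
    """Seeded, frozen multi-head self-attention encoder.

    All weights are drawn once from ``numpy.random.default_rng(seed)`` and
    never updated: the encoder is a deterministic contextual feature map.
    Positions enter through sinusoidal encodings damped by ``positional_scale``
    — snippet classification is largely order-insensitive, and at full strength
    position dominates token identity in a random (untrained) embedding space.
    """

    vocab_size: int = 4096
    dim: int = 32
    n_layers: int = 2
    n_heads: int = 4
    ffn_dim: int = 64
    seed: int = 0
    positional_scale: float = 0.1
    _params: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.dim % self.n_heads:
            raise ValueError("dim must be divisible by n_heads")
        rng = np.random.default_rng(self.seed)
        scale = 1.0 / np.sqrt(self.dim)
        p: dict[str, np.ndarray] = {
            "emb": rng.normal(0.0, 1.0, size=(self.vocab_size, self.dim))
        }
        for l in range(self.n_layers):
            for name in ("wq", "wk", "wv", "wo"):
                p[f"{l}.{name}"] = rng.normal(0.0, scale, size=(self.dim, self.dim))
            p[f"{l}.w1"] = rng.normal(0.0, scale, size=(self.dim, self.ffn_dim))
            p[f"{l}.w2"] = rng.normal(0.0, scale, size=(self.ffn_dim, self.dim))
        self._params = p

    def _positional(self, length: int) -> np.ndarray:
        pos = np.arange(length)[:, None]
        i = np.arange(self.dim)[None, :]
        angle = pos / np.power(10000.0, (2 * (i // 2)) / self.dim)
        pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
        return self.positional_scale * pe

    def _attention(self, x: np.ndarray, layer: int) -> np.ndarray:
        p = self._params
        dk = self.dim // self.n_heads
        q = x @ p[f"{layer}.wq"]
        k = x @ p[f"{layer}.wk"]
        v = x @ p[f"{layer}.wv"]
        heads = []
        for h in range(self.n_heads):
            sl = slice(h * dk, (h + 1) * dk)
            scores = q[:, sl] @ k[:, sl].T / np.sqrt(dk)
            heads.append(_softmax(scores, axis=-1) @ v[:, sl])
        return np.concatenate(heads, axis=-1) @ p[f"{layer}.wo"]

    def forward(self, token_ids: Sequence[int]) -> np.ndarray:
        ids = np.asarray(token_ids, dtype=np.int64)
        if ids.ndim != 1 or ids.size == 0:
            raise ValueError("token_ids must be a non-empty 1-D sequence")
        if (ids < 0).any() or (ids >= self.vocab_size).any():
            raise ValueError("token id out of vocabulary range")
        x = self._params["emb"][ids] + self._positional(len(ids))
        for l in range(self.n_layers):
            x = _layer_norm(x + self._attention(x, l))
            ff = np.maximum(x @ self._params[f"{l}.w1"], 0.0) @ self._params[f"{l}.w2"]
            x = _layer_norm(x + ff)
        return x


def encode_instance(encoder: TokenEncoder, instance: AspectInstance) -> EncoderOutput:
    """Run the encoder over one assembled instance."""
    H = encoder.forward(instance.token_ids)
    return EncoderOutput(H=H, L=encoder.n_layers, n=instance.n, m=instance.m)
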