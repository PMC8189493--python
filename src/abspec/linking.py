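"""Linking specificity snippets to antibody RRID snippets.

Three routes decide whether a specificity statement refers to the antibody
described in a single-RRID context snippet from the same article:

* :func:`pair_classify` — a sentence-pair classifier: the two snippets are
  joined as ``[CLS] spec [SEP] rrid`` and a binary logistic head reads the
  pooled output vector.

* :func:`baseline_link` — a string-similarity baseline that counts common
  *non-dictionary* words (clone names like "6E10", catalog tokens, hyphenated
  reagent names) between the two snippets, matching words by Jaro-Winkler
  similarity at a configurable threshold (1.0, 0.9 or 0.8).

* :class:`SiameseLinker` — two weight-shared recurrent encoders; the pair is
  linked when ``exp(-distance)`` between the pooled encodings is >= 0.5, with
  Manhattan or Euclidean distance.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .encoding import CLS_ID, SEP_ID, HashTokenizer, TinyTransformerEncoder, TokenEncoder

__all__ = [
    "SnippetPair",
    "LinkPrediction",
    "BaselineConfig",
    "jaro_similarity",
    "jaro_winkler",
    "extract_candidate_words",
    "baseline_link",
    "load_default_dictionary",
    "PairLinker",
    "train_linker",
    "pair_classify",
    "SiameseLinker",
    "train_siamese",
    "siamese_similarity",
    "read_pairs_csv",
    "write_pairs_csv",
]

# the identifier itself, with or without its prefix, and the bare prefix token
_RRID_TOKEN = re.compile(r"^((RRID:?)?AB_[0-9]+|RRID)$", re.IGNORECASE)
_WORD = re.compile(r"[A-Za-z0-9][A-Za-z0-9_\-]*")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SnippetPair:
    """A (specificity snippet, RRID snippet) candidate with optional gold label."""

    spec_text: str
    rrid_text: str
    rrid: str
    label: str | None = None  # "yes" | "no"

    def __post_init__(self) -> None:
        if self.label not in (None, "yes", "no"):
            raise ValueError(f"label must be yes/no, got {self.label!r}")


@dataclass(frozen=True)
class LinkPrediction:
    probability_yes: float
    decision: str  # "yes" | "no"
    evidence: tuple[tuple[str, str], ...] | None = None


# ---------------------------------------------------------------------------
# Jaro-Winkler
# ---------------------------------------------------------------------------


def jaro_similarity(s1: str, s2: str) -> float:
    """Jaro similarity: matches within a sliding window plus transpositions."""
    if s1 == s2:
        return 1.0
    len1, len2 = len(s1), len(s2)
    if len1 == 0 or len2 == 0:
        return 0.0
    window = max(max(len1, len2) // 2 - 1, 0)
    match1 = [False] * len1
    match2 = [False] * len2
    matches = 0
    for i, c in enumerate(s1):
        lo = max(0, i - window)
        hi = min(len2, i + window + 1)
        for j in range(lo, hi):
            if not match2[j] and s2[j] == c:
                match1[i] = match2[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    t = 0
    j = 0
    for i in range(len1):
        if match1[i]:
            while not match2[j]:
                j += 1
            if s1[i] != s2[j]:
                t += 1
            j += 1
    t //= 2
    m = matches
    return (m / len1 + m / len2 + (m - t) / m) / 3.0


def jaro_winkler(s1: str, s2: str, prefix_weight: float = 0.1, max_prefix: int = 4) -> float:
    """Jaro similarity with the Winkler boost for a shared prefix (<= 4 chars)."""
    j = jaro_similarity(s1, s2)
    prefix = 0
    for c1, c2 in zip(s1, s2):
        if c1 != c2 or prefix >= max_prefix:
            break
        prefix += 1
    return j + prefix * prefix_weight * (1.0 - j)


# ---------------------------------------------------------------------------
# Common non-dictionary-word baseline
# ---------------------------------------------------------------------------


def load_default_dictionary() -> frozenset[str]:
    """The bundled common-word lexicon (lowercased)."""
    text = resources.files("abspec").joinpath("data/words.txt").read_text("utf-8")
    return frozenset(w.strip().lower() for w in text.splitlines() if w.strip())


@dataclass(frozen=True)
class BaselineConfig:
    jw_threshold: float = 1.0
    dictionary: frozenset[str] = field(default_factory=load_default_dictionary)
    min_common: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.jw_threshold <= 1:
            raise ConfigurationError("jw_threshold must be in (0, 1]")
        if self.min_common < 1:
            raise ConfigurationError("min_common must be >= 1")


def _has_internal_capital(token: str) -> bool:
    return any(c.isupper() for c in token[1:])


def extract_candidate_words(snippet: str, dictionary: frozenset[str]) -> set[str]:
    """Non-dictionary words of a snippet: the linking signal of the baseline.

    A token is a candidate when it bears a digit or an internal capital
    (clone/catalog-style tokens such as "6E10" or "anti-Panx1"), or when it is
    absent from the dictionary (case-insensitively).  RRID tokens themselves
    are excluded — sharing the identifier is what we are trying to predict.
    """
    out: set[str] = set()
    for token in _WORD.findall(snippet):
        if _RRID_TOKEN.match(token):
            continue
        if any(c.isdigit() for c in token) or _has_internal_capital(token):
            out.add(token)
        elif token.lower() not in dictionary:
            out.add(token)
    return out


def baseline_link(
    spec_text: str, rrid_text: str, config: BaselineConfig | None = None
) -> LinkPrediction:
    """Count Jaro-Winkler-matched common candidate words; link iff count >= min_common.

    Matching is greedy best-first: candidate pairs are ranked by similarity and
    each word is used at most once.
    """
    config = config or BaselineConfig()
    cand_spec = sorted(extract_candidate_words(spec_text, config.dictionary))
    cand_rrid = sorted(extract_candidate_words(rrid_text, config.dictionary))
    scored = [
        (jaro_winkler(u, v), u, v)
        for u in cand_spec
        for v in cand_rrid
    ]
    scored.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_u: set[str] = set()
    used_v: set[str] = set()
    evidence: list[tuple[str, str]] = []
    for sim, u, v in scored:
        if sim < config.jw_threshold:
            break
        if u in used_u or v in used_v:
            continue
        used_u.add(u)
        used_v.add(v)
        evidence.append((u, v))
    count = len(evidence)
    decision = "yes" if count >= config.min_common else "no"
    return LinkPrediction(
        probability_yes=1.0 if decision == "yes" else 0.0,
        decision=decision,
        evidence=tuple(evidence),
    )


# ---------------------------------------------------------------------------
# Sentence-pair classifier
# ---------------------------------------------------------------------------


@dataclass
class LinkerConfig:
    l2_lambda: float = 0.01
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 16
    max_len: int = 256
    seed: int = 0
    encoder_dim: int = 32
    encoder_layers: int = 2
    threshold: float = 0.5


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _adam_step(param, grad, m, v, t, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    m[:] = beta1 * m + (1 - beta1) * grad
    v[:] = beta2 * v + (1 - beta2) * grad ** 2
    param -= lr * (m / (1 - beta1 ** t)) / (np.sqrt(v / (1 - beta2 ** t)) + eps)


@dataclass
class PairLinker:
    """Binary sentence-pair classifier on the pooled [CLS] vector."""

    encoder: TokenEncoder
    tokenizer: HashTokenizer
    w: np.ndarray
    b: float
    config: LinkerConfig
    training_log: list[dict] = field(default_factory=list)

    def _pair_ids(self, spec_text: str, rrid_text: str) -> list[int]:
        if not spec_text.strip() or not rrid_text.strip():
            raise ValueError("empty snippet text in pair")
        s = self.tokenizer.tokenize(spec_text)
        t = self.tokenizer.tokenize(rrid_text)
        budget = self.config.max_len - 2
        # trim the longer side first until the pair fits
        while len(s) + len(t) > budget:
            if len(s) >= len(t):
                s = s[:-1]
            else:
                t = t[:-1]
        return [CLS_ID] + self.tokenizer.ids(s) + [SEP_ID] + self.tokenizer.ids(t)

    def featurize(self, pair: SnippetPair) -> np.ndarray:
        return self.encoder.forward(self._pair_ids(pair.spec_text, pair.rrid_text))[0]

    def predict(self, pair: SnippetPair) -> LinkPrediction:
        h0 = self.featurize(pair)
        p = float(_sigmoid(h0 @ self.w + self.b))
        return LinkPrediction(
            probability_yes=p,
            decision="yes" if p >= self.config.threshold else "no",
        )

    def fit(self, pairs: Sequence[SnippetPair]) -> "PairLinker":
        labels = {p.label for p in pairs}
        if None in labels:
            raise ValueError("all pairs must be labeled")
        if labels != {"yes", "no"}:
            raise ConfigurationError(f"need both yes and no pairs, got {sorted(labels)}")
        X = np.stack([self.featurize(p) for p in pairs])
        y = np.array([1.0 if p.label == "yes" else 0.0 for p in pairs])
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        mw, vw = np.zeros_like(self.w), np.zeros_like(self.w)
        mb = vb = 0.0
        t = 0
        self.training_log = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(y))
            for start in range(0, len(y), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                p = _sigmoid(X[idx] @ self.w + self.b)
                g = p - y[idx]
                gw = X[idx].T @ g / len(idx) + 2 * cfg.l2_lambda * self.w
                gb = float(g.mean()) + 2 * cfg.l2_lambda * self.b
                t += 1
                _adam_step(self.w, gw, mw, vw, t, cfg.learning_rate)
                mb = 0.9 * mb + 0.1 * gb
                vb = 0.999 * vb + 0.001 * gb ** 2
                self.b -= cfg.learning_rate * (mb / (1 - 0.9 ** t)) / (
                    np.sqrt(vb / (1 - 0.999 ** t)) + 1e-8
                )
            p_all = _sigmoid(X @ self.w + self.b)
            nll = -(y * np.log(np.clip(p_all, 1e-12, None))
                    + (1 - y) * np.log(np.clip(1 - p_all, 1e-12, None))).mean()
            self.training_log.append(
                {"epoch": epoch + 1,
                 "loss": float(nll + cfg.l2_lambda * ((self.w ** 2).sum() + self.b ** 2))}
            )
        return self

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cfg = {k: getattr(self.config, k) for k in vars(self.config)}
        cfg["kind"] = "pair"
        cfg["vocab_size"] = self.tokenizer.vocab_size
        (d / "config.json").write_text(json.dumps(cfg, indent=2))
        np.savez(d / "head.npz", w=self.w, b=np.array([self.b]))
        with open(d / "training_log.jsonl", "w") as fh:
            for rec in self.training_log:
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "PairLinker":
        d = Path(directory)
        raw = json.loads((d / "config.json").read_text())
        vocab = raw.pop("vocab_size", 4096)
        raw.pop("kind", None)
        config = LinkerConfig(**raw)
        weights = np.load(d / "head.npz")
        return cls(
            encoder=TinyTransformerEncoder(
                vocab_size=vocab,
                dim=config.encoder_dim,
                n_layers=config.encoder_layers,
                seed=config.seed,
            ),
            tokenizer=HashTokenizer(vocab_size=vocab),
            w=weights["w"].copy(),
            b=float(weights["b"][0]),
            config=config,
        )


def train_linker(pairs: Sequence[SnippetPair], config: LinkerConfig | None = None) -> PairLinker:
    config = config or LinkerConfig()
    model = PairLinker(
        encoder=TinyTransformerEncoder(
            dim=config.encoder_dim, n_layers=config.encoder_layers, seed=config.seed
        ),
        tokenizer=HashTokenizer(),
        w=np.zeros(config.encoder_dim),
        b=0.0,
        config=config,
    )
    return model.fit(pairs)


def pair_classify(model: PairLinker, pair: SnippetPair) -> LinkPrediction:
    """[CLS] spec [SEP] rrid -> binary head on the pooled vector, threshold 0.5."""
    return model.predict(pair)


# ---------------------------------------------------------------------------
# Siamese recurrent baseline
# ---------------------------------------------------------------------------


@dataclass
class SiameseConfig:
    hidden_dim: int = 16
    embed_dim: int = 16
    metric: str = "manhattan"  # or "euclidean"
    learning_rate: float = 0.05
    epochs: int = 5
    max_len: int = 64
    seed: int = 0
    threshold: float = 0.5


class SiameseLinker:
    """Two weight-shared recurrent encoders scored by exp(-distance).

    A single tanh recurrent cell (one parameter set) reads both snippets —
    sharing is by construction, not by synchronisation.  Pooled hidden states
    are compared with Manhattan or Euclidean distance and the similarity
    ``exp(-d)`` in (0, 1] is thresholded at 0.5 for the link decision.
    """

    def __init__(self, config: SiameseConfig | None = None):
        self.config = config or SiameseConfig()
        if self.config.metric not in ("manhattan", "euclidean"):
            raise ValueError(f"unknown metric {self.config.metric!r}")
        rng = np.random.default_rng(self.config.seed)
        e, h = self.config.embed_dim, self.config.hidden_dim
        self.tokenizer = HashTokenizer()
        self.embeddings = rng.normal(0, 0.5, size=(self.tokenizer.vocab_size, e))
        self.Wxh = rng.normal(0, 1 / np.sqrt(e), size=(e, h))
        self.Whh = rng.normal(0, 1 / np.sqrt(h), size=(h, h))
        self.bh = np.zeros(h)
        self.training_log: list[dict] = []

    # Both branches are literally the same cell: the weight-sharing invariant.
    @property
    def encoder_left(self):
        return (self.Wxh, self.Whh, self.bh)

    @property
    def encoder_right(self):
        return (self.Wxh, self.Whh, self.bh)

    def _ids(self, text: str) -> list[int]:
        toks = self.tokenizer.tokenize(text)[: self.config.max_len]
        if not toks:
            raise ValueError("text contained no tokens")
        return self.tokenizer.ids(toks)

    def _encode(self, ids: Sequence[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (pooled, hidden states T x h, inputs T x e)."""
        X = self.embeddings[np.asarray(ids)]
        T = len(ids)
        Hs = np.zeros((T, self.config.hidden_dim))
        h = np.zeros(self.config.hidden_dim)
        for t in range(T):
            h = np.tanh(X[t] @ self.Wxh + h @ self.Whh + self.bh)
            Hs[t] = h
        return Hs.mean(axis=0), Hs, X

    def encode(self, text: str) -> np.ndarray:
        return self._encode(self._ids(text))[0]

    def _distance(self, u: np.ndarray, v: np.ndarray) -> float:
        if self.config.metric == "manhattan":
            return float(np.abs(u - v).sum())
        return float(np.sqrt(((u - v) ** 2).sum()))

    def similarity(self, s1: str, s2: str) -> float:
        return float(np.exp(-self._distance(self.encode(s1), self.encode(s2))))

    def predict(self, pair: SnippetPair) -> LinkPrediction:
        p = self.similarity(pair.spec_text, pair.rrid_text)
        return LinkPrediction(
            probability_yes=p, decision="yes" if p >= self.config.threshold else "no"
        )

    # -- training (BPTT through both branches of the shared cell) -----------

    def _bptt(self, Hs: np.ndarray, X: np.ndarray, g_pool: np.ndarray, grads: dict) -> None:
        T = len(Hs)
        g_h = np.zeros_like(self.bh)
        for t in range(T - 1, -1, -1):
            g = g_pool / T + g_h
            pre = g * (1 - Hs[t] ** 2)  # tanh'
            grads["Wxh"] += np.outer(X[t], pre)
            h_prev = Hs[t - 1] if t > 0 else np.zeros_like(self.bh)
            grads["Whh"] += np.outer(h_prev, pre)
            grads["bh"] += pre
            g_h = pre @ self.Whh.T

    def fit(self, pairs: Sequence[SnippetPair]) -> "SiameseLinker":
        labels = {p.label for p in pairs}
        if None in labels or labels != {"yes", "no"}:
            raise ConfigurationError("need labeled pairs with both yes and no present")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.training_log = []
        data = [
            (self._ids(p.spec_text), self._ids(p.rrid_text), 1.0 if p.label == "yes" else 0.0)
            for p in pairs
        ]
        for epoch in range(cfg.epochs):
            total = 0.0
            for i in rng.permutation(len(data)):
                ids1, ids2, y = data[i]
                u, H1, X1 = self._encode(ids1)
                v, H2, X2 = self._encode(ids2)
                d = self._distance(u, v)
                s = np.exp(-d)
                total += (y - s) ** 2
                dL_ds = -2.0 * (y - s)
                dL_dd = dL_ds * (-s)
                diff = u - v
                if cfg.metric == "manhattan":
                    dd_du = np.sign(diff)
                else:
                    dd_du = diff / d if d > 1e-12 else np.zeros_like(diff)
                g_u = dL_dd * dd_du
                grads = {
                    "Wxh": np.zeros_like(self.Wxh),
                    "Whh": np.zeros_like(self.Whh),
                    "bh": np.zeros_like(self.bh),
                }
                self._bptt(H1, X1, g_u, grads)
                self._bptt(H2, X2, -g_u, grads)
                for name in grads:
                    np.clip(grads[name], -1.0, 1.0, out=grads[name])
                self.Wxh -= cfg.learning_rate * grads["Wxh"]
                self.Whh -= cfg.learning_rate * grads["Whh"]
                self.bh -= cfg.learning_rate * grads["bh"]
            self.training_log.append({"epoch": epoch + 1, "loss": total / len(data)})
        return self


def train_siamese(pairs: Sequence[SnippetPair], config: SiameseConfig | None = None) -> SiameseLinker:
    return SiameseLinker(config).fit(pairs)


def siamese_similarity(model: SiameseLinker, s1: str, s2: str, metric: str | None = None) -> float:
    """exp(-distance) similarity in (0, 1]; decision threshold is 0.5."""
    if metric is not None:
        if metric not in ("manhattan", "euclidean"):
            raise ValueError(f"unknown metric {metric!r}")
        model.config.metric = metric
    return model.similarity(s1, s2)


# ---------------------------------------------------------------------------
# Pairs file interchange
# ---------------------------------------------------------------------------


def read_pairs_csv(path: str | Path, delimiter: str = ",") -> list[SnippetPair]:
    pairs = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter=delimiter):
            pairs.append(
                SnippetPair(
                    spec_text=row["spec_text"],
                    rrid_text=row["rrid_text"],
                    rrid=row["rrid"],
                    label=row.get("label") or None,
                )
            )
    return pairs


def write_pairs_csv(pairs: Iterable[SnippetPair], path: str | Path, delimiter: str = ",") -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["spec_text", "rrid_text", "rrid", "label"])
        for p in pairs:
            writer.writerow([p.spec_text, p.rrid_text, p.rrid, p.label or ""])
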