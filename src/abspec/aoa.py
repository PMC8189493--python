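"""Aspect-based specificity classification with attention over attention.

Given a snippet ``s = (w_1..w_n)`` and a target aspect ``t = (x_1..x_m)`` (the
antibody mention the statement is about), the encoder yields last-layer vectors
``a`` (n x d, snippet slice) and ``b`` (m x d, aspect slice).  The AOA head is
parameter-free:

    I      = a . b^T                 pair-wise interaction, n x m
    alpha  = column-wise softmax(I)  target-to-snippet attention
    beta   = row-wise softmax(I)     snippet-to-target attention
    beta_bar_j = mean_i beta_ij      averaged aspect attention
    gamma  = alpha . beta_bar        one weight per snippet token
    r_AOA  = a^T . gamma             attention-weighted snippet representation

Optionally ``r_CLS = concat(h_0, r_AOA)`` augments the pooled [CLS] vector.  A
linear layer with softmax over the three ordered classes (nonspecific <
neutral < specific) gives the class-conditional probabilities; training
minimises cross-entropy plus an l2 penalty on the head parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import (
    AspectInstance,
    EncoderOutput,
    HashTokenizer,
    TinyTransformerEncoder,
    TokenEncoder,
    build_input,
    encode_instance,
)
from .snippets import find_antibody_mentions

__all__ = [
    "LABELS",
    "AOAState",
    "ClassifierConfig",
    "aoa_attention",
    "snippet_representation",
    "predict_class",
    "SpecificityClassifier",
    "train_classifier",
    "classify_snippet",
]

LABELS: tuple[str, str, str] = ("nonspecific", "neutral", "specific")
_LABEL_INDEX = {lab: i for i, lab in enumerate(LABELS)}


class ConfigurationError(ValueError):
    pass


def _softmax(x: np.ndarray, axis: int) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass(frozen=True)
class AOAState:
    """All intermediate tensors of one attention-over-attention pass."""

    I: np.ndarray          # n x m
    alpha: np.ndarray      # n x m, columns sum to 1
    beta: np.ndarray       # n x m, rows sum to 1
    beta_bar: np.ndarray   # m
    gamma: np.ndarray      # n, non-negative, sums to 1
    r_aoa: np.ndarray      # d


def aoa_attention(a: np.ndarray, b: np.ndarray) -> AOAState:
    """Run the AOA head on snippet vectors ``a`` (n x d) and aspect ``b`` (m x d)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError(f"shape mismatch: a {a.shape}, b {b.shape}")
    if a.shape[0] < 1 or b.shape[0] < 1:
        raise ValueError("need at least one snippet and one aspect vector")
    I = a @ b.T
    alpha = _softmax(I, axis=0)
    beta = _softmax(I, axis=1)
    beta_bar = beta.mean(axis=0)
    gamma = alpha @ beta_bar
    r_aoa = a.T @ gamma
    return AOAState(I=I, alpha=alpha, beta=beta, beta_bar=beta_bar, gamma=gamma, r_aoa=r_aoa)


def snippet_representation(state: AOAState, h0: np.ndarray, use_cls: bool) -> np.ndarray:
    """Final snippet vector: ``concat(h0, r_AOA)`` when ``use_cls`` else ``r_AOA``."""
    if use_cls:
        return np.concatenate([np.asarray(h0, dtype=float), state.r_aoa])
    return state.r_aoa


@dataclass
class LinearHead:
    """Linear layer + softmax over the fixed label order."""

    W: np.ndarray  # K x D
    b: np.ndarray  # K

    @classmethod
    def zeros(cls, dim: int, n_classes: int = len(LABELS)) -> "LinearHead":
        return cls(W=np.zeros((n_classes, dim)), b=np.zeros(n_classes))

    def logits(self, reprs: np.ndarray) -> np.ndarray:
        return np.atleast_2d(reprs) @ self.W.T + self.b

    def sq_norm(self) -> float:
        return float((self.W ** 2).sum() + (self.b ** 2).sum())


def predict_class(repr_vec: np.ndarray, head: LinearHead) -> tuple[np.ndarray, str]:
    """Class probabilities and the argmax label (ties -> first in label order)."""
    probs = _softmax(head.logits(repr_vec), axis=-1)[0]
    return probs, LABELS[int(np.argmax(probs))]


@dataclass
class ClassifierConfig:
    use_cls: bool = True
    l2_lambda: float = 1e-4
    learning_rate: float = 1e-2
    epochs: int = 300
    batch_size: int = 16
    max_len: int = 256
    seed: int = 0
    encoder_dim: int = 32
    encoder_layers: int = 2
    class_weighting: bool = False

    def __post_init__(self) -> None:
        if self.l2_lambda < 0:
            raise ConfigurationError("l2_lambda must be >= 0")


def _adam_step(param, grad, m, v, t, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    m[:] = beta1 * m + (1 - beta1) * grad
    v[:] = beta2 * v + (1 - beta2) * grad ** 2
    mhat = m / (1 - beta1 ** t)
    vhat = v / (1 - beta2 ** t)
    param -= lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class SpecificityClassifier:
    """Encoder + AOA head + linear output layer.

    With the bundled tiny encoder the contextual features are a frozen seeded
    map and training fits the output layer; the encoder protocol admits
    fine-tunable encoders without changing this class's surface.
    """

    encoder: TokenEncoder
    tokenizer: HashTokenizer
    head: LinearHead
    config: ClassifierConfig
    use_aoa: bool = True          # False -> plain sequence baseline on h0
    training_log: list[dict] = field(default_factory=list)

    # -- feature path ------------------------------------------------------

    def featurize(self, instance: AspectInstance) -> np.ndarray:
        out = encode_instance(self.encoder, instance)
        if not self.use_aoa:
            return out.h0
        state = aoa_attention(out.a, out.b)
        return snippet_representation(state, out.h0, self.config.use_cls)

    def aoa_state(self, instance: AspectInstance) -> tuple[EncoderOutput, AOAState]:
        out = encode_instance(self.encoder, instance)
        return out, aoa_attention(out.a, out.b)

    # -- loss --------------------------------------------------------------

    def loss(self, instances: Sequence[AspectInstance]) -> float:
        """Mean cross-entropy over the batch plus the l2 head penalty."""
        if not instances:
            raise ValueError("empty batch")
        X, y = self._design(instances)
        return self._loss_from(X, y)

    def _design(self, instances: Sequence[AspectInstance]) -> tuple[np.ndarray, np.ndarray]:
        for inst in instances:
            if inst.label is None:
                raise ValueError("all instances must be labeled")
            if inst.label not in _LABEL_INDEX:
                raise ValueError(f"unknown label {inst.label!r}")
        X = np.stack([self.featurize(inst) for inst in instances])
        y = np.array([_LABEL_INDEX[inst.label] for inst in instances])
        return X, y

    def _loss_from(self, X: np.ndarray, y: np.ndarray, sample_w: np.ndarray | None = None) -> float:
        probs = _softmax(self.head.logits(X), axis=-1)
        nll = -np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None))
        if sample_w is not None:
            nll = nll * sample_w
        return float(nll.mean() + self.config.l2_lambda * self.head.sq_norm())

    # -- training ----------------------------------------------------------

    def fit(self, instances: Sequence[AspectInstance]) -> "SpecificityClassifier":
        cfg = self.config
        X, y = self._design(instances)
        present = set(int(c) for c in np.unique(y))
        if present != set(range(len(LABELS))):
            missing = [LABELS[i] for i in range(len(LABELS)) if i not in present]
            raise ConfigurationError(f"training data missing class(es): {missing}")
        sample_w = None
        if cfg.class_weighting:
            counts = np.bincount(y, minlength=len(LABELS)).astype(float)
            w = counts.sum() / (len(LABELS) * counts)
            sample_w = w[y]
        rng = np.random.default_rng(cfg.seed)
        mW, vW = np.zeros_like(self.head.W), np.zeros_like(self.head.W)
        mb, vb = np.zeros_like(self.head.b), np.zeros_like(self.head.b)
        t = 0
        self.training_log = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(y))
            for start in range(0, len(y), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                Xb, yb = X[idx], y[idx]
                probs = _softmax(self.head.logits(Xb), axis=-1)
                G = probs.copy()
                G[np.arange(len(yb)), yb] -= 1.0
                if sample_w is not None:
                    G = G * sample_w[idx][:, None]
                gW = G.T @ Xb / len(yb) + 2 * cfg.l2_lambda * self.head.W
                gb = G.mean(axis=0) + 2 * cfg.l2_lambda * self.head.b
                t += 1
                _adam_step(self.head.W, gW, mW, vW, t, cfg.learning_rate)
                _adam_step(self.head.b, gb, mb, vb, t, cfg.learning_rate)
            self.training_log.append(
                {"epoch": epoch + 1, "loss": self._loss_from(X, y, sample_w)}
            )
        return self

    # -- inference ---------------------------------------------------------

    def build_instance(self, snippet: str, aspect: str | None, label: str | None = None) -> AspectInstance:
        if aspect is None:
            mentions = find_antibody_mentions(snippet)
            aspect = mentions[0] if mentions else "antibody"
        return build_input(snippet, aspect, self.tokenizer, self.config.max_len, label=label)

    def classify(self, snippet: str, aspect: str | None = None) -> tuple[str, np.ndarray]:
        if not snippet or not snippet.strip():
            raise ValueError("empty snippet")
        inst = self.build_instance(snippet, aspect)
        probs, label = predict_class(self.featurize(inst), self.head)
        return label, probs

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cfg = {
            "kind": "aoa" if self.use_aoa else "sequence",
            "use_cls": self.config.use_cls,
            "l2_lambda": self.config.l2_lambda,
            "learning_rate": self.config.learning_rate,
            "epochs": self.config.epochs,
            "batch_size": self.config.batch_size,
            "max_len": self.config.max_len,
            "seed": self.config.seed,
            "encoder_dim": self.config.encoder_dim,
            "encoder_layers": self.config.encoder_layers,
            "class_weighting": self.config.class_weighting,
            "vocab_size": self.tokenizer.vocab_size,
        }
        (d / "config.json").write_text(json.dumps(cfg, indent=2))
        np.savez(d / "head.npz", W=self.head.W, b=self.head.b)
        with open(d / "training_log.jsonl", "w") as fh:
            for rec in self.training_log:
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "SpecificityClassifier":
        d = Path(directory)
        cfg = json.loads((d / "config.json").read_text())
        config = ClassifierConfig(
            use_cls=cfg["use_cls"],
            l2_lambda=cfg["l2_lambda"],
            learning_rate=cfg["learning_rate"],
            epochs=cfg["epochs"],
            batch_size=cfg["batch_size"],
            max_len=cfg["max_len"],
            seed=cfg["seed"],
            encoder_dim=cfg["encoder_dim"],
            encoder_layers=cfg["encoder_layers"],
            class_weighting=cfg["class_weighting"],
        )
        weights = np.load(d / "head.npz")
        model = cls(
            encoder=TinyTransformerEncoder(
                vocab_size=cfg["vocab_size"],
                dim=cfg["encoder_dim"],
                n_layers=cfg["encoder_layers"],
                seed=cfg["seed"],
            ),
            tokenizer=HashTokenizer(vocab_size=cfg["vocab_size"]),
            head=LinearHead(W=weights["W"].copy(), b=weights["b"].copy()),
            config=config,
            use_aoa=cfg["kind"] == "aoa",
        )
        log_path = d / "training_log.jsonl"
        if log_path.exists():
            model.training_log = [
                json.loads(line) for line in log_path.read_text().splitlines() if line
            ]
        return model


def _new_model(config: ClassifierConfig, use_aoa: bool) -> SpecificityClassifier:
    encoder = TinyTransformerEncoder(
        dim=config.encoder_dim, n_layers=config.encoder_layers, seed=config.seed
    )
    tokenizer = HashTokenizer()
    if use_aoa:
        feat_dim = config.encoder_dim * (2 if config.use_cls else 1)
    else:
        feat_dim = config.encoder_dim
    return SpecificityClassifier(
        encoder=encoder,
        tokenizer=tokenizer,
        head=LinearHead.zeros(feat_dim),
        config=config,
        use_aoa=use_aoa,
    )


def train_classifier(
    dataset: Sequence[AspectInstance],
    config: ClassifierConfig | None = None,
    use_aoa: bool = True,
) -> SpecificityClassifier:
    """Train a specificity classifier (AOA head by default).

    ``use_aoa=False`` gives the plain sequence baseline that classifies from
    the pooled [CLS] vector alone; it accepts the same ([CLS], s, [SEP], t)
    or aspect-free ([CLS], s) inputs.
    """
    config = config or ClassifierConfig()
    return _new_model(config, use_aoa).fit(dataset)


def classify_snippet(
    model: SpecificityClassifier, snippet: str, aspect: str | None = None
) -> tuple[str, np.ndarray]:
    """End-to-end: build input, encode, AOA, linear head -> (label, probs)."""
    return model.classify(snippet, aspect)


def baseline_sequence_classify(
    model: SpecificityClassifier, snippet: str, aspect: str | None = None
) -> str:
    """Classify from the pooled vector alone (sequence / sentence-pair baseline)."""
    if model.use_aoa:
        raise ConfigurationError("model was trained with the AOA head; use classify_snippet")
    if not snippet or not snippet.strip():
        raise ValueError("empty snippet")
    if aspect is None:
        inst = build_input(snippet, "[none]", model.tokenizer, model.config.max_len)
        # aspect-free form ([CLS], s): drop the [SEP]+aspect tail before encoding
        ids = inst.token_ids[: 1 + inst.n]
        H = model.encoder.forward(ids)
        probs, label = predict_class(H[0], model.head)
        return label
    inst = model.build_instance(snippet, aspect)
    probs, label = predict_class(model.featurize(inst), model.head)
    return label
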