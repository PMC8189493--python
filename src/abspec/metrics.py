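"""Evaluation: per-class P/R/F1, macro and support-weighted aggregates,
stratified cross-validation folds, the joint-workflow true-positive rule, and
chance-corrected annotator agreement.

Conventions: zero denominators yield 0; macro aggregates are unweighted class
means; weighted aggregates use gold-class supports as weights; reports print
to three decimal places while internal values stay unrounded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "FoldSplit",
    "AgreementReport",
    "confusion",
    "class_metrics",
    "f1_score",
    "aggregate",
    "aggregate_from_class_f1",
    "weighted_mean",
    "kfold_split",
    "joint_evaluate",
    "cohen_kappa",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Rows are gold classes, columns are predictions."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        k = len(self.class_order)
        if c.shape != (k, k) or (c < 0).any():
            raise ValueError("counts must be a KxK non-negative matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def support(self, label: str) -> int:
        return int(self.counts[self.class_order.index(label)].sum())


@dataclass(frozen=True)
class EvalReport:
    per_class: Mapping[str, dict]
    macro_f1: float
    macro_precision: float
    macro_recall: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    accuracy: float
    support: Mapping[str, int]
    empty: bool = False

    def rounded(self, ndigits: int = 3) -> dict:
        """Printable report rounded to three decimals, as comparison tables print."""
        return {
            "per_class": {
                lab: {k: round(v, ndigits) for k, v in m.items()}
                for lab, m in self.per_class.items()
            },
            "macro": {
                "precision": round(self.macro_precision, ndigits),
                "recall": round(self.macro_recall, ndigits),
                "f1": round(self.macro_f1, ndigits),
            },
            "weighted": {
                "precision": round(self.weighted_precision, ndigits),
                "recall": round(self.weighted_recall, ndigits),
                "f1": round(self.weighted_f1, ndigits),
            },
            "accuracy": round(self.accuracy, ndigits),
            "support": dict(self.support),
        }


def confusion(
    gold: Sequence[str], pred: Sequence[str], class_order: Sequence[str]
) -> ConfusionMatrix:
    if len(gold) != len(pred):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(pred)} predictions")
    index = {lab: i for i, lab in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for g, p in zip(gold, pred):
        if g not in index or p not in index:
            raise ValueError(f"label outside class_order: {g!r}/{p!r}")
        counts[index[g], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=tuple(class_order))


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def class_metrics(cm: ConfusionMatrix, label: str) -> tuple[float, float, float]:
    """(precision, recall, F1) of one class; zero denominators give 0."""
    i = cm.class_order.index(label)
    tp = float(cm.counts[i, i])
    fp = float(cm.counts[:, i].sum() - tp)
    fn = float(cm.counts[i, :].sum() - tp)
    return _prf(tp, fp, fn)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    return 2 * precision * recall / (precision + recall) if precision + recall else 0.0


def weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    w = np.asarray(weights, dtype=float)
    return float(np.asarray(values, dtype=float) @ w / w.sum())


def aggregate_from_class_f1(
    class_f1: Sequence[float], supports: Sequence[float] | None = None
) -> dict:
    """Macro (and, given supports, weighted) aggregates of per-class F1 values.

    This is the arithmetic used by published comparison tables: macro F1 is the
    plain mean of class F1s; weighted F1 weights each class by its instance
    count.
    """
    out = {"macro_f1": float(np.mean(class_f1))}
    if supports is not None:
        out["weighted_f1"] = weighted_mean(class_f1, supports)
    return out


def aggregate(cm: ConfusionMatrix) -> EvalReport:
    if cm.total == 0:
        warnings.warn("empty confusion matrix: all metrics reported as 0")
        zero = {lab: {"precision": 0.0, "recall": 0.0, "f1": 0.0} for lab in cm.class_order}
        return EvalReport(
            per_class=zero,
            macro_f1=0.0, macro_precision=0.0, macro_recall=0.0,
            weighted_precision=0.0, weighted_recall=0.0, weighted_f1=0.0,
            accuracy=0.0,
            support={lab: 0 for lab in cm.class_order},
            empty=True,
        )
    per_class = {}
    supports = []
    for lab in cm.class_order:
        p, r, f = class_metrics(cm, lab)
        per_class[lab] = {"precision": p, "recall": r, "f1": f}
        supports.append(cm.support(lab))
    ps = [per_class[l]["precision"] for l in cm.class_order]
    rs = [per_class[l]["recall"] for l in cm.class_order]
    fs = [per_class[l]["f1"] for l in cm.class_order]
    w = np.asarray(supports, dtype=float)
    w = w / w.sum() if w.sum() else w
    return EvalReport(
        per_class=per_class,
        macro_precision=float(np.mean(ps)),
        macro_recall=float(np.mean(rs)),
        macro_f1=float(np.mean(fs)),
        weighted_precision=float(np.asarray(ps) @ w),
        weighted_recall=float(np.asarray(rs) @ w),
        weighted_f1=float(np.asarray(fs) @ w),
        accuracy=float(np.trace(cm.counts) / cm.total),
        support={lab: s for lab, s in zip(cm.class_order, supports)},
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldSplit:
    folds: tuple[tuple[int, ...], ...]
    seed: int

    def train_test(self, fold: int) -> tuple[list[int], list[int]]:
        test = list(self.folds[fold])
        train = [i for k, f in enumerate(self.folds) if k != fold for i in f]
        return train, test


def kfold_split(
    labels: Sequence[Hashable],
    k: int = 5,
    seed: int = 0,
    groups: Sequence[Hashable] | None = None,
) -> FoldSplit:
    """Stratified, seeded k-fold partition of instance indices.

    ``groups`` (e.g. article ids) switches to group-aware assignment: whole
    groups are dealt round-robin to folds by shuffled order, trading exact
    stratification for leakage control.
    """
    n = len(labels)
    if n < k:
        raise ValueError(f"need at least k={k} instances, got {n}")
    if groups is not None:
        if len(groups) != n:
            raise ValueError("groups must align with labels")
        rng = np.random.default_rng(seed)
        uniq = sorted(set(groups), key=str)
        order = rng.permutation(len(uniq))
        fold_of_group = {uniq[g]: int(i % k) for i, g in enumerate(order)}
        folds: list[list[int]] = [[] for _ in range(k)]
        for i, g in enumerate(groups):
            folds[fold_of_group[g]].append(i)
        return FoldSplit(folds=tuple(tuple(f) for f in folds), seed=seed)
    counts: dict[Hashable, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    if min(counts.values()) < k:
        warnings.warn(
            f"some class has fewer than k={k} instances; stratification is best-effort"
        )
    y = np.asarray([str(lab) for lab in labels])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = tuple(tuple(int(i) for i in test) for _, test in skf.split(np.zeros(n), y))
    return FoldSplit(folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# Joint-workflow evaluation
# ---------------------------------------------------------------------------


def joint_evaluate(
    gold: Sequence[tuple[Hashable, str, str]],
    pred: Sequence[tuple[Hashable, str, str]],
    class_order: Sequence[str],
) -> dict:
    """Score (pair-id, link, class) triples by the joint true-positive rule.

    A true positive for class C is a pair linked "yes" with class C by *both*
    gold and prediction.  Predicted-positives for C are pairs predicted
    (yes, C); gold-positives are pairs annotated (yes, C).  Pairs with link
    "no" on both sides never enter any class tally.
    """
    def index(items, who):
        seen = {}
        for pid, link, cls in items:
            if pid in seen:
                raise ValueError(f"duplicate pair-id in {who}: {pid!r}")
            if link not in ("yes", "no"):
                raise ValueError(f"link must be yes/no, got {link!r}")
            seen[pid] = (link, cls)
        return seen

    g = index(gold, "gold")
    p = index(pred, "pred")
    if set(g) != set(p):
        raise ValueError("gold and pred must cover the same pair-ids")

    per_class = {}
    truth_total = pred_total = 0
    fs, ps_, rs, supports = [], [], [], []
    for cls in class_order:
        tp = sum(
            1 for pid in g
            if g[pid] == ("yes", cls) and p[pid] == ("yes", cls)
        )
        n_pred = sum(1 for pid in p if p[pid] == ("yes", cls))
        n_gold = sum(1 for pid in g if g[pid] == ("yes", cls))
        prec, rec, f1 = _prf(tp, n_pred - tp, n_gold - tp)
        per_class[cls] = {
            "truth": n_gold, "predicted": n_pred,
            "precision": prec, "recall": rec, "f1": f1,
        }
        truth_total += n_gold
        pred_total += n_pred
        ps_.append(prec)
        rs.append(rec)
        fs.append(f1)
        supports.append(n_gold)
    w = np.asarray(supports, dtype=float)
    w = w / w.sum() if w.sum() else w
    return {
        "per_class": per_class,
        "truth_total": truth_total,
        "predicted_total": pred_total,
        "macro": {
            "precision": float(np.mean(ps_)),
            "recall": float(np.mean(rs)),
            "f1": float(np.mean(fs)),
        },
        "weighted": {
            "precision": float(np.asarray(ps_) @ w),
            "recall": float(np.asarray(rs) @ w),
            "f1": float(np.asarray(fs) @ w),
        },
    }


# ---------------------------------------------------------------------------
# Annotator agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementReport:
    kappa: float
    n_items: int
    weighted: bool


def cohen_kappa(
    ann1: Sequence[str],
    ann2: Sequence[str],
    class_order: Sequence[str],
    weights: str = "none",
) -> AgreementReport:
    """Cohen's kappa, optionally with linear ordinal disagreement weights.

    kappa = (p_o - p_e) / (1 - p_e); the weighted variant replaces observed
    and expected agreement with weighted disagreement over the ordered classes
    (w_ij = |i - j| / (K - 1)).  Identical constant annotations (p_e = 1) are
    defined as perfect agreement.
    """
    if weights not in ("none", "linear"):
        raise ValueError(f"weights must be 'none' or 'linear', got {weights!r}")
    if len(ann1) != len(ann2):
        raise ValueError("annotation vectors must have equal length")
    k = len(class_order)
    cm = confusion(ann1, ann2, class_order).counts.astype(float)
    n = cm.sum()
    if n == 0:
        raise ValueError("no items to compare")
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if weights == "linear":
        w = np.abs(i - j) / (k - 1) if k > 1 else np.zeros((1, 1))
    else:
        w = (i != j).astype(float)
    obs = cm / n
    expected = np.outer(cm.sum(axis=1), cm.sum(axis=0)) / (n * n)
    d_o = float((w * obs).sum())
    d_e = float((w * expected).sum())
    if d_e == 0.0:
        kappa = 1.0 if d_o == 0.0 else 0.0
    else:
        kappa = 1.0 - d_o / d_e
    return AgreementReport(kappa=kappa, n_items=int(n), weighted=weights == "linear")
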