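"""Evaluation arithmetic: per-class metrics, aggregates, joint scoring, kappa.

Shows how per-class F1 values and class supports combine into macro and
support-weighted aggregates, how the joint workflow counts a true positive
(link = yes AND matching class), and how ordinal disagreement is scored with
weighted kappa.
"""

from abspec import (
    aggregate,
    aggregate_from_class_f1,
    cohen_kappa,
    confusion,
    f1_score,
    joint_evaluate,
)

ORDER = ("nonspecific", "neutral", "specific")

# macro vs support-weighted aggregation of per-class F1
agg = aggregate_from_class_f1([0.958, 0.832, 0.750], supports=[2110, 266, 263])
print(f"per-class F1 (0.958, 0.832, 0.750), supports (2110, 266, 263):")
print(f"  macro F1    = {agg['macro_f1']:.3f}  (plain mean)")
print(f"  weighted F1 = {agg['weighted_f1']:.3f}  (support-weighted mean)")
print(f"  F1 from P=0.802, R=0.931 -> {f1_score(0.802, 0.931):.3f}")

# a small confusion matrix end to end
gold = ["specific"] * 8 + ["nonspecific"] * 2 + ["neutral"] * 2
pred = ["specific"] * 7 + ["neutral"] + ["nonspecific", "specific"] + ["neutral"] * 2
rep = aggregate(confusion(gold, pred, ORDER))
print(f"\n12-snippet example: accuracy {rep.accuracy:.3f}, macro F1 {rep.macro_f1:.3f}")

# joint scoring: a link with the wrong class is both a FP and a FN
gold_triples = [(0, "yes", "nonspecific"), (1, "yes", "specific"), (2, "no", "neutral")]
pred_triples = [(0, "yes", "specific"), (1, "yes", "specific"), (2, "no", "neutral")]
joint = joint_evaluate(gold_triples, pred_triples, ORDER)
print(f"joint example: specific P={joint['per_class']['specific']['precision']:.2f} "
      f"R={joint['per_class']['specific']['recall']:.2f}; "
      f"nonspecific R={joint['per_class']['nonspecific']['recall']:.2f}")

# annotator agreement on the ordered classes
a1 = ["specific"] * 6 + ["neutral", "neutral", "nonspecific", "nonspecific"]
a2 = ["specific"] * 5 + ["neutral"] + ["neutral", "specific", "nonspecific", "neutral"]
plain = cohen_kappa(a1, a2, ORDER).kappa
weighted = cohen_kappa(a1, a2, ORDER, weights="linear").kappa
print(f"\nagreement: kappa = {plain:.3f}, linear weighted kappa = {weighted:.3f}")
# The weighted variant penalises neutral/specific confusions less than
# nonspecific/specific ones because the classes are ordered.
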