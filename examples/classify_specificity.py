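"""Train the attention-over-attention specificity classifier on synthetic data.

A seeded corpus provides labeled snippets (nonspecific / neutral / specific).
The classifier encodes ([CLS], snippet, [SEP], aspect) with a tiny frozen
transformer, runs the attention-over-attention head to pool snippet tokens by
their interaction with the antibody aspect, and fits a linear softmax head.
Held-out accuracy is printed from a stratified 5-fold split.
"""

import numpy as np

from abspec import ClassifierConfig, kfold_split, predict_class, train_classifier
from abspec.synthetic import CorpusSpec, corpus_to_datasets, generate_corpus

corpus = generate_corpus(CorpusSpec(n_articles=60, seed=0))
ds = corpus_to_datasets(corpus)
labels = [lab for *_, lab in ds.spec_examples]
insts = ds.to_aspect_instances()
print(f"{len(insts)} labeled snippets "
      f"({labels.count('nonspecific')} nonspecific / {labels.count('neutral')} neutral / "
      f"{labels.count('specific')} specific)")

train_idx, test_idx = kfold_split(labels, k=5, seed=0).train_test(0)
model = train_classifier([insts[i] for i in train_idx], ClassifierConfig(seed=0))
print(f"final training loss: {model.training_log[-1]['loss']:.4f}")

acc = np.mean([predict_class(model.featurize(insts[i]), model.head)[1] == labels[i]
               for i in test_idx])
print(f"held-out accuracy on fold 0: {acc:.3f} (n={len(test_idx)})")

label, probs = model.classify(
    "Some non-specific bands were detected at ~55 kDa in both wild-type and "
    "mutant lysates probed with the 9Z41 antibody."
)
print(f"worked example -> {label} "
      f"(p_nonspecific={probs[0]:.2f}, p_neutral={probs[1]:.2f}, p_specific={probs[2]:.2f})")
# The statement reports off-target bands, so the nonspecific class should win.
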