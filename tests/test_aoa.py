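"""Attention-over-attention head: oracle equivalence, invariants, training."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abspec.aoa import (
    LABELS,
    ClassifierConfig,
    ConfigurationError,
    LinearHead,
    SpecificityClassifier,
    aoa_attention,
    baseline_sequence_classify,
    predict_class,
    snippet_representation,
    train_classifier,
)
from abspec.encoding import HashTokenizer, TinyTransformerEncoder, build_input


def aoa_reference(a, b):
    """Independent nested-loop implementation of the AOA head."""
    n, d = len(a), len(a[0])
    m = len(b)
    I = [[sum(a[i][k] * b[j][k] for k in range(d)) for j in range(m)] for i in range(n)]
    alpha = [[0.0] * m for _ in range(n)]
    for j in range(m):
        col = [math.exp(I[i][j] - max(I[r][j] for r in range(n))) for i in range(n)]
        z = sum(col)
        for i in range(n):
            alpha[i][j] = col[i] / z
    beta = [[0.0] * m for _ in range(n)]
    for i in range(n):
        row = [math.exp(I[i][j] - max(I[i][c] for c in range(m))) for j in range(m)]
        z = sum(row)
        for j in range(m):
            beta[i][j] = row[j] / z
    beta_bar = [sum(beta[i][j] for i in range(n)) / n for j in range(m)]
    gamma = [sum(alpha[i][j] * beta_bar[j] for j in range(m)) for i in range(n)]
    r = [sum(a[i][k] * gamma[i] for i in range(n)) for k in range(d)]
    return I, alpha, beta, beta_bar, gamma, r


class TestAOAAttention:
    def test_agrees_with_nested_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n, m, d = rng.integers(1, 9), rng.integers(1, 9), rng.integers(2, 9)
            a = rng.normal(size=(n, d))
            b = rng.normal(size=(m, d))
            state = aoa_attention(a, b)
            I, alpha, beta, beta_bar, gamma, r = aoa_reference(a.tolist(), b.tolist())
            np.testing.assert_allclose(state.I, I, atol=1e-6)
            np.testing.assert_allclose(state.alpha, alpha, atol=1e-6)
            np.testing.assert_allclose(state.beta, beta, atol=1e-6)
            np.testing.assert_allclose(state.beta_bar, beta_bar, atol=1e-6)
            np.testing.assert_allclose(state.gamma, gamma, atol=1e-6)
            np.testing.assert_allclose(state.r_aoa, r, atol=1e-6)

    def test_frozen_worked_example(self):
        # single aspect vector: beta is all ones, gamma = softmax of a.b
        state = aoa_attention(np.array([[1.0, 0], [0, 1], [1, 1]]), np.array([[1.0, 0]]))
        np.testing.assert_allclose(state.I, [[1.0], [0.0], [1.0]])
        np.testing.assert_allclose(state.beta, np.ones((3, 1)))
        np.testing.assert_allclose(state.beta_bar, [1.0])
        np.testing.assert_allclose(state.gamma, [0.42231879, 0.15536242, 0.42231879], atol=1e-6)
        np.testing.assert_allclose(state.r_aoa, [0.84463758, 0.57768121], atol=1e-6)

    def test_constant_interaction_gives_uniform_gamma(self):
        a = np.zeros((4, 3))
        b = np.ones((2, 3))
        state = aoa_attention(a, b)
        np.testing.assert_allclose(state.gamma, np.full(4, 0.25), atol=1e-12)
        np.testing.assert_allclose(state.r_aoa, a.mean(axis=0), atol=1e-12)

    def test_single_snippet_token_degenerate(self):
        a = np.array([[2.0, -1.0, 0.5]])
        state = aoa_attention(a, np.random.default_rng(0).normal(size=(3, 3)))
        np.testing.assert_allclose(state.gamma, [1.0])
        np.testing.assert_allclose(state.r_aoa, a[0])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            aoa_attention(np.ones((2, 3)), np.ones((2, 4)))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        n=st.integers(1, 8),
        m=st.integers(1, 8),
        d=st.integers(1, 8),
        seed=st.integers(0, 10_000),
    )
    def test_stochasticity_and_convexity_invariants(self, n, m, d, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(scale=2.0, size=(n, d))
        b = rng.normal(scale=2.0, size=(m, d))
        state = aoa_attention(a, b)
        np.testing.assert_allclose(state.alpha.sum(axis=0), np.ones(m), atol=1e-6)
        np.testing.assert_allclose(state.beta.sum(axis=1), np.ones(n), atol=1e-6)
        assert (state.gamma >= 0).all()
        assert abs(state.gamma.sum() - 1.0) < 1e-6
        # r_aoa is a convex combination of snippet vectors, column-wise
        assert (state.r_aoa >= a.min(axis=0) - 1e-9).all()
        assert (state.r_aoa <= a.max(axis=0) + 1e-9).all()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(n=st.integers(2, 6), m=st.integers(1, 5), seed=st.integers(0, 1000))
    def test_permutation_equivariance_of_snippet_tokens(self, n, m, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n, 4))
        b = rng.normal(size=(m, 4))
        perm = rng.permutation(n)
        base = aoa_attention(a, b)
        permuted = aoa_attention(a[perm], b)
        np.testing.assert_allclose(permuted.gamma, base.gamma[perm], atol=1e-9)
        np.testing.assert_allclose(permuted.r_aoa, base.r_aoa, atol=1e-9)


class TestRepresentationAndHead:
    def test_representation_concatenation(self):
        state = aoa_attention(np.eye(2), np.ones((1, 2)))
        h0 = np.array([3.0, 4.0])
        r = snippet_representation(state, h0, use_cls=True)
        assert r.shape == (4,)
        np.testing.assert_allclose(r[:2], h0)
        np.testing.assert_allclose(r[2:], state.r_aoa)
        np.testing.assert_allclose(snippet_representation(state, h0, use_cls=False), state.r_aoa)
        zero = snippet_representation(state, np.zeros(2), use_cls=True)
        np.testing.assert_allclose(zero[2:], state.r_aoa)

    def test_uniform_probabilities_tie_break_to_first_label(self):
        head = LinearHead.zeros(4)
        probs, label = predict_class(np.ones(4), head)
        np.testing.assert_allclose(probs, np.full(3, 1 / 3))
        assert label == "nonspecific"  # fixed order nonspecific < neutral < specific

    def test_dominant_logit_wins(self):
        head = LinearHead(W=np.zeros((3, 2)), b=np.array([0.0, 0.0, 10.0]))
        probs, label = predict_class(np.zeros(2), head)
        assert label == "specific" and probs[2] > 0.99

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(3)
        head = LinearHead(W=rng.normal(size=(3, 5)), b=rng.normal(size=3))
        probs, _ = predict_class(rng.normal(size=5), head)
        assert abs(probs.sum() - 1.0) < 1e-6


def tiny_dataset(n_per_class=20, seed=0):
    """Separable three-class snippets built from distinct cue phrasings."""
    rng = np.random.default_rng(seed)
    tok = HashTokenizer()
    phrases = {
        "nonspecific": "non-specific bands were detected with the {} antibody",
        "neutral": "specificity of the {} antibody was assessed by an assay",
        "specific": "the {} antibody is specific and blocking confirmed it",
    }
    out = []
    for label, tmpl in phrases.items():
        for _ in range(n_per_class):
            clone = f"{rng.integers(1, 10)}E{rng.integers(10, 99)}"
            out.append(build_input(tmpl.format(clone), "antibody", tok, label=label))
    return out


class TestTraining:
    CFG = dict(epochs=5, learning_rate=1e-2, seed=0)

    def test_loss_decreases_over_epochs(self):
        model = train_classifier(tiny_dataset(), ClassifierConfig(**self.CFG))
        log = model.training_log
        assert len(log) == 5
        assert log[-1]["loss"] < log[0]["loss"]

    def test_same_seed_reproduces_final_loss(self):
        runs = [
            train_classifier(tiny_dataset(), ClassifierConfig(**self.CFG)).training_log[-1]["loss"]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_strong_l2_shrinks_head(self):
        data = tiny_dataset()
        free = train_classifier(data, ClassifierConfig(epochs=10, l2_lambda=0.0, seed=0))
        shrunk = train_classifier(data, ClassifierConfig(epochs=10, l2_lambda=1e3, seed=0))
        assert shrunk.head.sq_norm() < free.head.sq_norm()

    def test_missing_class_rejected(self):
        data = [d for d in tiny_dataset() if d.label != "neutral"]
        with pytest.raises(ConfigurationError, match="missing class"):
            train_classifier(data, ClassifierConfig(**self.CFG))

    def test_loss_requires_labels_and_matches_closed_form(self):
        data = tiny_dataset(n_per_class=2)
        model = train_classifier(data, ClassifierConfig(epochs=1, seed=0))
        # zeroed head -> uniform predictions -> mean CE = ln 3, no l2 on zero weights
        model.head = LinearHead.zeros(model.head.W.shape[1])
        assert model.loss(data) == pytest.approx(np.log(3.0), abs=1e-9)
        data[0].label = None
        with pytest.raises(ValueError, match="labeled"):
            model.loss(data)

    def test_classify_end_to_end_and_empty_input(self):
        model = train_classifier(tiny_dataset(), ClassifierConfig(epochs=40, learning_rate=1e-2, seed=0))
        label, probs = model.classify("the 7E42 antibody is specific and blocking confirmed it")
        assert label == "specific"
        assert abs(probs.sum() - 1.0) < 1e-6
        with pytest.raises(ValueError, match="empty"):
            model.classify("  ")

    def test_aspect_longer_than_half_max_len_rejected(self):
        tok = HashTokenizer()
        with pytest.raises(ValueError, match="max_len"):
            build_input("short snippet", "a b c d e f", tok, max_len=10)

    def test_truncation_removes_snippet_tokens_only(self):
        tok = HashTokenizer()
        inst = build_input("tok " * 300, "antibody aspect", tok, max_len=64)
        assert inst.m == 2
        assert 2 + inst.n + inst.m == 64


class TestSequenceBaseline:
    def test_baseline_classifies_with_and_without_aspect(self):
        model = train_classifier(tiny_dataset(), ClassifierConfig(**TestTraining.CFG), use_aoa=False)
        with_aspect = baseline_sequence_classify(model, "the antibody is specific", "antibody")
        without = baseline_sequence_classify(model, "the antibody is specific", None)
        assert with_aspect in LABELS and without in LABELS

    def test_baseline_rejects_aoa_model(self):
        model = train_classifier(tiny_dataset(), ClassifierConfig(**TestTraining.CFG), use_aoa=True)
        with pytest.raises(ConfigurationError):
            baseline_sequence_classify(model, "text", "antibody")


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        model = train_classifier(tiny_dataset(), ClassifierConfig(epochs=3, seed=1))
        model.save(tmp_path / "m")
        loaded = SpecificityClassifier.load(tmp_path / "m")
        text = "non-specific bands were detected with the 3E55 antibody"
        l1, p1 = model.classify(text)
        l2, p2 = loaded.classify(text)
        assert l1 == l2
        np.testing.assert_allclose(p1, p2)
        assert loaded.training_log == model.training_log
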