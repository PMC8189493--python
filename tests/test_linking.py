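"""Jaro-Winkler matching, the common-word baseline, and the trained linkers."""

import string

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abspec.linking import (
    BaselineConfig,
    ConfigurationError,
    LinkerConfig,
    SiameseConfig,
    SnippetPair,
    baseline_link,
    extract_candidate_words,
    jaro_winkler,
    load_default_dictionary,
    pair_classify,
    siamese_similarity,
    train_linker,
    train_siamese,
    read_pairs_csv,
    write_pairs_csv,
)


def jaro_winkler_reference(s1: str, s2: str) -> float:
    """Brute-force reference built directly from the textbook definition."""
    if s1 == s2:
        return 1.0
    if not s1 or not s2:
        return 0.0
    window = max(len(s1), len(s2)) // 2 - 1
    m1, m2 = [], []
    taken = set()
    for i, c in enumerate(s1):
        for j in range(len(s2)):
            if j in taken or abs(i - j) > window:
                continue
            if s2[j] == c:
                m1.append((i, c))
                m2.append((j, c))
                taken.add(j)
                break
    if not m1:
        return 0.0
    m2_in_order = [c for j, c in sorted(m2)]
    transpositions = sum(1 for (_, c1), c2 in zip(m1, m2_in_order) if c1 != c2) // 2
    m = len(m1)
    jaro = (m / len(s1) + m / len(s2) + (m - transpositions) / m) / 3
    prefix = 0
    for c1, c2 in zip(s1[:4], s2[:4]):
        if c1 != c2:
            break
        prefix += 1
    return jaro + prefix * 0.1 * (1 - jaro)


class TestJaroWinkler:
    @pytest.mark.parametrize(
        "s1, s2, expected",
        [
            ("6E10", "6E10", 1.0),
            ("MARTHA", "MARHTA", 0.9611),  # Jaro 17/18 with prefix 3 boost
            ("ABC", "XYZ", 0.0),
            ("", "", 1.0),
            ("A", "", 0.0),
        ],
    )
    def test_known_values(self, s1, s2, expected):
        assert jaro_winkler(s1, s2) == pytest.approx(expected, abs=5e-5)

    def test_agrees_with_brute_force_reference(self):
        rng = np.random.default_rng(7)
        alphabet = string.ascii_uppercase + string.digits
        for _ in range(300):
            s1 = "".join(rng.choice(list(alphabet), size=rng.integers(0, 10)))
            s2 = "".join(rng.choice(list(alphabet), size=rng.integers(0, 10)))
            assert jaro_winkler(s1, s2) == pytest.approx(jaro_winkler_reference(s1, s2), abs=1e-9)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.text(alphabet="AB1", max_size=8), st.text(alphabet="AB1", max_size=8))
    def test_symmetry_and_range(self, s1, s2):
        v = jaro_winkler(s1, s2)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(jaro_winkler(s2, s1), abs=1e-12)
        if s1 == s2 and s1:
            assert v == 1.0

    def test_monotone_in_shared_prefix(self):
        # same Jaro core, growing prefix agreement
        vals = [jaro_winkler("abcdX", "abcdY"), jaro_winkler("abXcd", "abYcd")]
        assert vals[0] >= vals[1]


class TestCandidateWords:
    DICT = load_default_dictionary()

    def test_clone_token_is_candidate(self):
        assert extract_candidate_words("the 6E10 antibody was used", self.DICT) == {"6E10"}

    def test_all_dictionary_words_yield_empty(self):
        assert extract_candidate_words("the antibody was used", self.DICT) == set()

    def test_digit_bearing_hyphenated_token(self):
        assert extract_candidate_words("anti-Panx1 antibodies", self.DICT) == {"anti-Panx1"}

    def test_rrid_tokens_excluded(self):
        words = extract_candidate_words("clone 6E10 with RRID:AB_2564652 and AB_99", self.DICT)
        assert words == {"6E10"}

    def test_internal_capital_is_candidate_even_if_listed(self):
        assert "NIgG" in extract_candidate_words("precleared with NIgG serum", self.DICT)


class TestBaselineLink:
    def test_shared_clone_links_at_threshold_one(self):
        pred = baseline_link(
            "Some non-specific bands were seen with the 6E10 antibody.",
            "Purified antibody (6E10) (Cat. No. 803003; RRID:AB_2564652) was obtained.",
            BaselineConfig(jw_threshold=1.0),
        )
        assert pred.decision == "yes"
        assert ("6E10", "6E10") in pred.evidence

    def test_near_match_passes_only_permissive_threshold(self):
        # jaro_winkler("6E1O","6E10") = 0.8833: below 0.9, above 0.8
        assert jaro_winkler("6E1O", "6E10") == pytest.approx(0.8833, abs=5e-5)
        spec, rrid = "the 6E1O antibody", "clone 6E10, RRID:AB_1"
        assert baseline_link(spec, rrid, BaselineConfig(jw_threshold=0.8)).decision == "yes"
        assert baseline_link(spec, rrid, BaselineConfig(jw_threshold=0.9)).decision == "no"
        assert baseline_link(spec, rrid, BaselineConfig(jw_threshold=1.0)).decision == "no"

    def test_no_shared_candidates(self):
        pred = baseline_link("the 6E10 antibody", "clone 9K12, RRID:AB_1", BaselineConfig())
        assert pred.decision == "no" and pred.evidence == ()

    def test_threshold_one_equals_exact_set_intersection(self):
        rng = np.random.default_rng(11)
        dictionary = load_default_dictionary()
        vocab = [f"{a}{d}X{d2}" for a in "QZJ" for d in range(4) for d2 in range(4)]
        for _ in range(50):
            w1 = set(rng.choice(vocab, size=rng.integers(0, 6), replace=False))
            w2 = set(rng.choice(vocab, size=rng.integers(0, 6), replace=False))
            s1 = "measured with " + " ".join(sorted(w1))
            s2 = "obtained as " + " ".join(sorted(w2))
            pred = baseline_link(s1, s2, BaselineConfig(jw_threshold=1.0))
            expect = "yes" if w1 & w2 else "no"
            assert pred.decision == expect
            assert len(pred.evidence) == len(w1 & w2)

    def test_empty_rrid_candidates_never_links(self):
        pred = baseline_link("the 6E10 antibody", "the reagent was used", BaselineConfig())
        assert pred.decision == "no"

    def test_invalid_config(self):
        with pytest.raises(ConfigurationError):
            BaselineConfig(jw_threshold=0.0)


def synthetic_pairs(n_yes=15, n_no=85, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_yes + n_no):
        clone = f"{rng.integers(1, 10)}E{rng.integers(10, 99)}"
        other = f"{rng.integers(1, 10)}K{rng.integers(10, 99)}"
        spec = f"Some non-specific bands were seen with the {clone} antibody."
        if i < n_yes:
            rrid_clone = clone
            label = "yes"
        else:
            rrid_clone = other
            label = "no"
        rrid_text = f"Purified antibody ({rrid_clone}) (Cat. No. {rng.integers(10**5, 10**6)}; RRID:AB_{i}) was obtained."
        pairs.append(SnippetPair(spec_text=spec, rrid_text=rrid_text, rrid=f"AB_{i}", label=label))
    return pairs


class TestPairLinker:
    def test_training_and_determinism(self):
        pairs = synthetic_pairs()
        cfg = LinkerConfig(epochs=5, seed=0)
        m1 = train_linker(pairs, cfg)
        m2 = train_linker(pairs, LinkerConfig(epochs=5, seed=0))
        assert m1.training_log[-1]["loss"] == m2.training_log[-1]["loss"]
        assert m1.training_log[-1]["loss"] < m1.training_log[0]["loss"]
        preds1 = [pair_classify(m1, p).decision for p in pairs]
        preds2 = [pair_classify(m2, p).decision for p in pairs]
        assert preds1 == preds2

    def test_single_class_rejected(self):
        pairs = [p for p in synthetic_pairs() if p.label == "no"]
        with pytest.raises(ConfigurationError):
            train_linker(pairs, LinkerConfig(epochs=1))

    def test_empty_text_rejected(self):
        model = train_linker(synthetic_pairs(), LinkerConfig(epochs=1))
        with pytest.raises(ValueError, match="empty"):
            pair_classify(model, SnippetPair(spec_text=" ", rrid_text="x RRID:AB_1", rrid="AB_1"))

    def test_decision_matches_threshold(self):
        model = train_linker(synthetic_pairs(), LinkerConfig(epochs=3, seed=1))
        for p in synthetic_pairs(seed=3)[:10]:
            pred = pair_classify(model, p)
            assert (pred.decision == "yes") == (pred.probability_yes >= 0.5)


class TestSiamese:
    def test_identical_inputs_score_one(self):
        model = train_siamese(synthetic_pairs(), SiameseConfig(epochs=1, seed=0))
        assert siamese_similarity(model, "same text here", "same text here") == pytest.approx(1.0)

    def test_weight_sharing_is_structural(self):
        model = train_siamese(synthetic_pairs(), SiameseConfig(epochs=1, seed=0))
        for left, right in zip(model.encoder_left, model.encoder_right):
            assert left is right  # one parameter set serves both branches

    def test_unknown_metric_rejected(self):
        model = train_siamese(synthetic_pairs(), SiameseConfig(epochs=1, seed=0))
        with pytest.raises(ValueError, match="metric"):
            siamese_similarity(model, "a b", "c d", metric="cosine")
        with pytest.raises(ValueError, match="metric"):
            SiameseConfig(metric="cosine") and train_siamese(synthetic_pairs(), SiameseConfig(epochs=1, metric="cosine"))

    @pytest.mark.parametrize("metric", ["manhattan", "euclidean"])
    def test_training_runs_and_logs(self, metric):
        model = train_siamese(synthetic_pairs(n_yes=10, n_no=30), SiameseConfig(epochs=3, metric=metric, seed=0))
        assert len(model.training_log) == 3
        acc = np.mean([model.predict(p).decision == p.label for p in synthetic_pairs(n_yes=5, n_no=15, seed=9)])
        assert 0.0 <= acc <= 1.0  # recorded for comparison, no performance contract


class TestPairsIO:
    def test_csv_round_trip(self, tmp_path):
        pairs = synthetic_pairs(n_yes=2, n_no=3)
        path = tmp_path / "pairs.csv"
        write_pairs_csv(pairs, path)
        assert read_pairs_csv(path) == pairs
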