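"""Classification and captioning metrics against hand-computed oracles."""

import numpy as np
import pytest

from ftda import bleu, cider, classification_metrics
from ftda.errors import ValidationError
from ftda.experiments import confusion_matrix_oracle


class TestClassificationMetrics:
    def test_hand_confusion_example(self):
        rep = classification_metrics(["a", "b", "b", "b"], ["a", "a", "b", "b"],
                                     ["a", "b"])
        f1 = dict(zip(rep.per_class["label"], rep.per_class["f1"]))
        assert f1["a"] == pytest.approx(2.0 / 3.0)
        assert f1["b"] == pytest.approx(0.8)
        assert rep.macro_f1 == pytest.approx((2.0 / 3.0 + 0.8) / 2.0)
        assert rep.accuracy == pytest.approx(0.75)

    def test_perfect_predictions(self):
        rep = classification_metrics(["a", "b"], ["a", "b"], ["a", "b"])
        assert rep.accuracy == rep.macro_f1 == rep.macro_precision == 1.0
        assert rep.invalid_rate == 0.0

    def test_all_invalid_predictions(self):
        rep = classification_metrics([None, None], ["a", "b"], ["a", "b"])
        assert rep.accuracy == 0.0
        assert rep.macro_recall == 0.0
        assert rep.invalid_rate == 1.0

    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 6))
            labels = [f"c{j}" for j in range(k)]
            n = int(rng.integers(1, 21))
            refs = [labels[j] for j in rng.integers(0, k, size=n)]
            preds = [None if j == k else labels[j]
                     for j in rng.integers(0, k + 1, size=n)]
            rep = classification_metrics(preds, refs, labels)
            oracle = confusion_matrix_oracle(
                ["<invalid>" if p is None else p for p in preds], refs, labels)
            for key in ("macro_precision", "macro_recall", "macro_f1",
                        "accuracy"):
                assert getattr(rep, key) == pytest.approx(oracle[key],
                                                          abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            classification_metrics(["a"], ["a", "b"], ["a", "b"])

    def test_reference_outside_label_set_rejected(self):
        with pytest.raises(ValidationError):
            classification_metrics(["a"], ["z"], ["a", "b"])


class TestBleu:
    def test_identical_long_candidate_scores_one(self):
        c = ["the grasper retracts the gallbladder"]
        assert bleu(c, c, max_n=1) == pytest.approx(1.0)
        assert bleu(c, c, max_n=4) == pytest.approx(1.0)

    def test_worked_example_closed_form(self):
        got = bleu(["the cat sat"], ["the cat sat down"], max_n=1)
        assert got == pytest.approx(np.exp(1.0 - 4.0 / 3.0), abs=1e-6)

    def test_disjoint_vocabulary_hits_smoothing_floor(self):
        assert bleu(["x y z"], ["a b c"], max_n=1) < 1e-6

    def test_permutation_invariant_over_corpus_order(self):
        cands = ["a b c", "d e f", "a d e"]
        refs = ["a b d", "d e g", "a a e"]
        fwd = bleu(cands, refs, max_n=4)
        rev = bleu(cands[::-1], refs[::-1], max_n=4)
        assert fwd == pytest.approx(rev, abs=1e-15)

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValidationError):
            bleu([], [])


class TestCider:
    def test_identical_corpus_with_distinct_refs_scores_ten(self):
        refs = ["the grasper retracts the gallbladder",
                "the hook dissects the cystic duct",
                "the clipper clips the cystic artery"]
        assert cider(list(refs), refs) == pytest.approx(10.0, abs=1e-9)

    def test_no_overlap_item_scores_zero(self):
        refs = ["a b c d", "e f g h"]
        cands = ["x y z w", "e f g h"]
        # first item shares no n-gram: contributes 0; second is identical
        score = cider(cands, refs)
        only_second = cider(["q r s t", "e f g h"], refs)
        assert score == pytest.approx(only_second)

    def test_two_item_hand_tfidf_oracle(self):
        # candidate "a x" vs reference "a b": unigram cosine = 1/sqrt(2),
        # no higher-order overlap; second pair identical ("c d") scores
        # 10 at n=1,2 and 0 at n=3,4.
        got = cider(["a x", "c d"], ["a b", "c d"])
        want = (10.0 / (4.0 * np.sqrt(2.0)) + 5.0) / 2.0
        assert got == pytest.approx(want, abs=1e-9)

    def test_permutation_invariant(self):
        cands = ["a b c", "c d e", "a e f"]
        refs = ["a b d", "c d f", "a e e"]
        assert cider(cands, refs) == pytest.approx(
            cider(cands[::-1], refs[::-1]), abs=1e-12)

    def test_small_corpus_rejected(self):
        with pytest.raises(ValidationError):
            cider(["a"], ["a"])

    def test_scores_bounded(self, rng):
        vocab = list("abcdefg")
        cands, refs = [], []
        for _ in range(10):
            cands.append(" ".join(rng.choice(vocab, size=5)))
            refs.append(" ".join(rng.choice(vocab, size=5)))
        s = cider(cands, refs)
        assert 0.0 <= s <= 10.0
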