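"""Encoder swap, label matching, multi-task routing."""

import numpy as np
import pytest

from ftda import (AlignmentMap, EmbeddingSet, Prediction, TaskSpec,
                  match_label, multitask_predict, predict)
from ftda.errors import ConfigurationError, ValidationError


class TestMatchLabel:
    def test_canonicalization_matches_across_case_and_whitespace(self):
        assert match_label("  Gallbladder   Dissection ",
                           ["gallbladder dissection"]) == \
            "gallbladder dissection"

    def test_nonsense_text_is_invalid(self):
        assert match_label("qwzx", ["prep", "dissect"]) is None

    def test_empty_label_set_rejected(self):
        with pytest.raises(ValidationError):
            match_label("prep", [])

    def test_returns_original_label_spelling(self):
        assert match_label("prep", ["Prep"]) == "Prep"


def _spec(labels, d, alignment="identity"):
    amap = AlignmentMap.identity(d) if alignment == "identity" else alignment
    return TaskSpec(name="phase", type="classification", label_set=labels,
                    alignment=amap)


class TestPredict:
    def test_empty_corpus_gives_empty_predictions(self, small_decoder):
        E = EmbeddingSet(ids=[], matrix=np.zeros((0, 16)), modality="image")
        spec = _spec(["clip applied"], 16)
        assert predict(E, spec, small_decoder) == []

    def test_missing_alignment_map_is_configuration_error(self, small_decoder):
        E = EmbeddingSet(ids=["a"], matrix=np.zeros((1, 16)), modality="image")
        spec = TaskSpec(name="phase", type="classification",
                        label_set=["clip applied"], alignment=None)
        with pytest.raises(ConfigurationError, match="identity"):
            predict(E, spec, small_decoder)

    def test_predictions_align_with_ids_and_match_labels(self, small_decoder,
                                                         unit_encoder):
        labels = ("clip applied", "hook dissection", "irrigation")
        E = EmbeddingSet(ids=["a", "b"],
                         matrix=np.stack([unit_encoder(labels[0]),
                                          unit_encoder(labels[2])]),
                         modality="image")
        preds = predict(E, _spec(labels, 16), small_decoder)
        assert [p.id for p in preds] == ["a", "b"]
        assert all(isinstance(p, Prediction) for p in preds)
        assert preds[0].label == labels[0] and preds[1].label == labels[2]

    def test_single_task_multitask_reduces_to_predict(self, small_decoder,
                                                      unit_encoder):
        labels = ("clip applied", "irrigation")
        E = EmbeddingSet(ids=["a", "b"],
                         matrix=np.stack([unit_encoder(l) for l in labels]),
                         modality="image")
        spec = _spec(labels, 16)
        direct = predict(E, spec, small_decoder)
        routed = multitask_predict(E, [spec], small_decoder)
        assert routed == {"phase": direct}

    def test_multitask_requires_a_map_per_task(self, small_decoder):
        E = EmbeddingSet(ids=["a"], matrix=np.zeros((1, 16)), modality="image")
        good = _spec(["clip applied"], 16)
        bad = TaskSpec(name="triplet", type="classification",
                       label_set=["x,y,z"], alignment=None)
        with pytest.raises(ConfigurationError, match="triplet"):
            multitask_predict(E, [good, bad], small_decoder)


def test_classification_task_requires_labels():
    with pytest.raises(ValidationError):
        TaskSpec(name="phase", type="classification", label_set=())
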