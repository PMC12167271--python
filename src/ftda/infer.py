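"""Inference-time encoder swap: image embeddings drive the text decoder.

Each task binds exactly one alignment map; an image embedding is aligned into
text-embedding space, the shared decoder generates greedily, and for
classification tasks the generated string is canonicalized and matched
against the closed label vocabulary.  Ground-truth texts are never consulted.
Runs without modality alignment (no-anchor baselines) must opt in explicitly
by binding an identity map — a task with no map at all is a configuration
error, so the collapse mode cannot be triggered by accident.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .align import AlignmentMap, apply_alignment
from .decoder import DecoderModel
from .errors import ConfigurationError, ValidationError
from .io import EmbeddingSet

__all__ = ["TaskSpec", "Prediction", "match_label", "predict",
           "multitask_predict"]

_WS = re.compile(r"\s+")


def _canon(text: str) -> str:
    """Lowercase, trim, and collapse internal whitespace."""
    return _WS.sub(" ", str(text).strip().lower())


@dataclass(frozen=True)
class TaskSpec:
    """A downstream task: name, type, label vocabulary and its alignment map."""

    name: str
    type: str  # "classification" | "captioning"
    label_set: Optional[tuple] = None
    alignment: Optional[AlignmentMap] = None

    def __post_init__(self):
        if self.type not in ("classification", "captioning"):
            raise ValidationError(f"unknown task type {self.type!r}")
        if self.type == "classification":
            if not self.label_set:
                raise ValidationError(
                    f"classification task {self.name!r} needs a non-empty label_set")
            object.__setattr__(self, "label_set",
                               tuple(str(x) for x in self.label_set))


@dataclass(frozen=True)
class Prediction:
    """One generated output; ``label`` is None when no vocabulary entry matched."""

    id: str
    text: str
    label: Optional[str] = None


def match_label(text: str, label_set: Sequence[str]) -> Optional[str]:
    """Map generated text onto a closed label set, or None if invalid.

    Both sides are canonicalized (lowercase, trimmed, internal whitespace
    collapsed); only exact canonical matches count.  A None result scores as
    a wrong prediction for accuracy/recall and as a reserved invalid class
    for precision bookkeeping.
    """
    labels = list(label_set)
    if not labels:
        raise ValidationError("label_set must be non-empty")
    lookup = {}
    for lab in labels:
        lookup.setdefault(_canon(lab), str(lab))
    return lookup.get(_canon(text))


def predict(corpus_images: EmbeddingSet, task: TaskSpec,
            model: DecoderModel, max_length: Optional[int] = None):
    """Align each image embedding, generate greedily, and match labels."""
    if task.alignment is None:
        raise ConfigurationError(
            f"task {task.name!r} has no alignment map bound; no-anchor runs "
            f"must bind AlignmentMap.identity(d) explicitly")
    if corpus_images.n == 0:
        return []
    aligned = apply_alignment(task.alignment, corpus_images)
    texts = model.generate(aligned.matrix, max_length=max_length)
    preds = []
    for sid, text in zip(corpus_images.ids, texts):
        label = (match_label(text, task.label_set)
                 if task.type == "classification" else None)
        preds.append(Prediction(id=sid, text=text, label=label))
    return preds


def multitask_predict(corpus_images: EmbeddingSet, tasks: Sequence[TaskSpec],
                      shared_model: DecoderModel):
    """Per-task predictions from one shared decoder.

    Routing is purely by each task's alignment map — no task token enters the
    decoder input — so per-task outputs are independent.
    """
    for task in tasks:
        if task.alignment is None:
            raise ConfigurationError(
                f"task {task.name!r} has no alignment map bound")
    return {task.name: predict(corpus_images, task, shared_model)
            for task in tasks}
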