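"""Portable on-disk containers for corpora, anchor sets and trained models.

Corpus container layout (a directory)::

    manifest.json     schema version, row count, task list, component checksums
    ids.txt           one opaque sample id per line (canonical row order)
    images.csv        n x d float32 matrix, one row per sample, %.9g text floats
    texts/<task>.tsv  id <TAB> text, one row per sample, UTF-8

Model archives are a directory with a JSON hyperparameter manifest plus the
raw parameter tensors in an ``.npz``; anchor sets are a single JSON file.
Floating data is stored at 32-bit precision, and ``%.9g`` formatting
round-trips every float32 exactly, so repeated writes of the same object are
byte-identical and checksums are stable.  All writes are atomic
(temp directory + rename).
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
import os
import shutil
import tempfile
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import (
    ContainerError,
    CorpusAlignmentError,
    IncompatibleArtifactError,
    ValidationError,
)

CORPUS_FORMAT = "ftda-corpus"
ANCHORS_FORMAT = "ftda-anchors"
SCHEMA_VERSION = 1

__all__ = [
    "EmbeddingSet",
    "TaskInfo",
    "PairedCorpus",
    "read_corpus",
    "write_corpus",
    "save_model",
    "load_model",
    "read_anchors",
    "write_anchors",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingSet:
    """An ordered set of sample embeddings for one modality."""

    ids: tuple
    matrix: np.ndarray  # (n, d) float32
    modality: str  # "image" | "text"

    def __post_init__(self):
        self.ids = tuple(str(i) for i in self.ids)
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        if self.matrix.ndim != 2:
            raise ValidationError(f"embedding matrix must be 2-D, got shape {self.matrix.shape}")
        if self.modality not in ("image", "text"):
            raise ValidationError(f"modality must be 'image' or 'text', got {self.modality!r}")
        if len(self.ids) != self.matrix.shape[0]:
            raise CorpusAlignmentError(
                f"{len(self.ids)} ids but {self.matrix.shape[0]} embedding rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("sample ids must be unique")
        if self.matrix.shape[1] < 1:
            raise ValidationError("embedding dimensionality must be >= 1")
        bad = ~np.isfinite(self.matrix)
        if bad.any():
            row = int(np.argwhere(bad)[0][0])
            raise ValidationError(f"non-finite embedding value at row {row}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def equals(self, other: "EmbeddingSet") -> bool:
        return (self.ids == other.ids and self.modality == other.modality
                and self.matrix.shape == other.matrix.shape
                and np.array_equal(self.matrix, other.matrix))


@dataclass(frozen=True)
class TaskInfo:
    """Task metadata: classification tasks carry a closed label vocabulary."""

    type: str  # "classification" | "captioning"
    label_set: Optional[tuple] = None

    def __post_init__(self):
        if self.type not in ("classification", "captioning"):
            raise ValidationError(f"unknown task type {self.type!r}")
        if self.type == "classification":
            if not self.label_set:
                raise ValidationError("classification task requires a non-empty label_set")
            object.__setattr__(self, "label_set", tuple(str(x) for x in self.label_set))
        elif self.label_set is not None:
            object.__setattr__(self, "label_set", tuple(str(x) for x in self.label_set))


@dataclass
class PairedCorpus:
    """Aligned records of (id, image embedding, per-task text)."""

    image_embeddings: EmbeddingSet
    texts: dict = field(default_factory=dict)  # task name -> tuple of texts
    tasks: dict = field(default_factory=dict)  # task name -> TaskInfo
    meta: dict = field(default_factory=dict)   # JSON-able extras (e.g. encoder params)

    def __post_init__(self):
        if self.image_embeddings.modality != "image":
            raise ValidationError("image_embeddings must have modality 'image'")
        self.texts = {k: tuple(str(t) for t in v) for k, v in self.texts.items()}
        if set(self.texts) != set(self.tasks):
            raise ValidationError(
                f"text tasks {sorted(self.texts)} != declared tasks {sorted(self.tasks)}")
        n = self.image_embeddings.n
        for task, seq in self.texts.items():
            if len(seq) != n:
                raise CorpusAlignmentError(
                    f"task {task!r} has {len(seq)} texts but corpus has {n} rows")
            info = self.tasks[task]
            if info.type == "classification":
                labels = set(info.label_set)
                for i, t in enumerate(seq):
                    if t not in labels:
                        raise ValidationError(
                            f"row {i} of task {task!r}: text {t!r} not in label_set")

    @property
    def ids(self) -> tuple:
        return self.image_embeddings.ids

    @property
    def n(self) -> int:
        return self.image_embeddings.n

    def equals(self, other: "PairedCorpus") -> bool:
        return (self.image_embeddings.equals(other.image_embeddings)
                and self.texts == other.texts and self.tasks == other.tasks
                and self.meta == other.meta)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n", encoding="utf-8")


def _atomic_replace(tmp: Path, dest: Path) -> None:
    dest = Path(dest)
    if dest.exists():
        old = dest.with_name(dest.name + ".old")
        if old.exists():
            shutil.rmtree(old)
        os.replace(dest, old)
        os.replace(tmp, dest)
        shutil.rmtree(old, ignore_errors=True)
    else:
        os.replace(tmp, dest)


def _matrix_to_csv(path: Path, matrix: np.ndarray) -> None:
    # %.9g round-trips float32 exactly and keeps the file diffable.
    np.savetxt(path, matrix.astype(np.float32), fmt="%.9g", delimiter=",")


def _matrix_from_csv(path: Path) -> np.ndarray:
    m = np.loadtxt(path, delimiter=",", dtype=np.float64, ndmin=2)
    return m.astype(np.float32)


# ---------------------------------------------------------------------------
# Corpus read/write
# ---------------------------------------------------------------------------

def write_corpus(corpus: PairedCorpus, path) -> Path:
    """Write ``corpus`` as a container directory; atomic and byte-stable."""
    dest = Path(path)
    dest.parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=dest.name + ".tmp.", dir=dest.parent))
    try:
        (tmp / "ids.txt").write_text(
            "".join(i + "\n" for i in corpus.ids), encoding="utf-8")
        _matrix_to_csv(tmp / "images.csv", corpus.image_embeddings.matrix)
        (tmp / "texts").mkdir()
        for task in sorted(corpus.texts):
            lines = ["id\ttext\n"]
            for sid, text in zip(corpus.ids, corpus.texts[task]):
                if "\t" in text or "\n" in text:
                    raise ValidationError(
                        f"task {task!r}: text for id {sid!r} contains tab/newline")
                lines.append(f"{sid}\t{text}\n")
            (tmp / "texts" / f"{task}.tsv").write_text("".join(lines), encoding="utf-8")
        components = ["ids.txt", "images.csv"] + [
            f"texts/{task}.tsv" for task in sorted(corpus.texts)]
        manifest = {
            "format": CORPUS_FORMAT,
            "version": SCHEMA_VERSION,
            "n": corpus.n,
            "d_image": corpus.image_embeddings.d,
            "tasks": [
                {"name": name,
                 "type": corpus.tasks[name].type,
                 "label_set": list(corpus.tasks[name].label_set)
                 if corpus.tasks[name].label_set else None}
                for name in sorted(corpus.tasks)
            ],
            "components": {c: _sha256(tmp / c) for c in components},
            "meta": corpus.meta,
        }
        _write_json(tmp / "manifest.json", manifest)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    _atomic_replace(tmp, dest)
    return dest


def read_corpus(path) -> PairedCorpus:
    """Read a corpus container; validates checksums and all invariants."""
    root = Path(path)
    mpath = root / "manifest.json"
    if not mpath.is_file():
        raise ContainerError(f"corrupt container: missing component manifest.json in {root}")
    try:
        manifest = json.loads(mpath.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ContainerError(f"corrupt container: unreadable manifest.json ({exc})") from exc
    if manifest.get("format") != CORPUS_FORMAT:
        raise IncompatibleArtifactError(
            f"not a corpus container: format {manifest.get('format')!r}")
    if manifest.get("version") != SCHEMA_VERSION:
        raise IncompatibleArtifactError(
            f"unsupported corpus schema version {manifest.get('version')!r} "
            f"(expected {SCHEMA_VERSION})")
    for comp, digest in manifest["components"].items():
        cpath = root / comp
        if not cpath.is_file():
            raise ContainerError(f"corrupt container: missing component {comp}")
        if _sha256(cpath) != digest:
            raise ContainerError(f"corrupt container: checksum mismatch for {comp}")

    ids = tuple((root / "ids.txt").read_text(encoding="utf-8").splitlines())
    matrix = _matrix_from_csv(root / "images.csv")
    if len(ids) != matrix.shape[0]:
        raise CorpusAlignmentError(
            f"{len(ids)} ids but {matrix.shape[0]} embedding rows")

    texts = {}
    tasks = {}
    for entry in manifest["tasks"]:
        name = entry["name"]
        tpath = root / "texts" / f"{name}.tsv"
        if not tpath.is_file():
            raise ContainerError(f"corrupt container: missing component texts/{name}.tsv")
        rows = tpath.read_text(encoding="utf-8").splitlines()
        if not rows or rows[0] != "id\ttext":
            raise ContainerError(f"corrupt container: bad header in texts/{name}.tsv")
        body = rows[1:]
        if len(body) != len(ids):
            raise CorpusAlignmentError(
                f"task {name!r} has {len(body)} texts but corpus has {len(ids)} rows")
        seq = []
        for i, line in enumerate(body):
            sid, _, text = line.partition("\t")
            if sid != ids[i]:
                raise CorpusAlignmentError(
                    f"task {name!r} row {i}: id {sid!r} != manifest id {ids[i]!r}")
            seq.append(text)
        texts[name] = tuple(seq)
        tasks[name] = TaskInfo(type=entry["type"],
                               label_set=tuple(entry["label_set"]) if entry["label_set"] else None)

    image = EmbeddingSet(ids=ids, matrix=matrix, modality="image")
    return PairedCorpus(image_embeddings=image, texts=texts, tasks=tasks,
                        meta=manifest.get("meta", {}))


# ---------------------------------------------------------------------------
# Model archives
# ---------------------------------------------------------------------------

def save_model(artifact, path) -> Path:
    """Save an :class:`AlignmentMap` or :class:`DecoderModel` archive."""
    manifest = artifact.to_manifest()  # carries "format"
    arrays = artifact.to_arrays()
    dest = Path(path)
    dest.parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=dest.name + ".tmp.", dir=dest.parent))
    try:
        manifest = dict(manifest)
        manifest["version"] = SCHEMA_VERSION
        buf = _stdio.BytesIO()
        np.savez(buf, **{k: np.asarray(v) for k, v in arrays.items()})
        (tmp / "params.npz").write_bytes(buf.getvalue())
        manifest["params_sha256"] = _sha256(tmp / "params.npz")
        _write_json(tmp / "manifest.json", manifest)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    _atomic_replace(tmp, dest)
    return dest


def load_model(path):
    """Load a model archive written by :func:`save_model`."""
    from .align import AlignmentMap
    from .decoder import DecoderModel

    registry = {"ftda-alignment-map": AlignmentMap, "ftda-decoder": DecoderModel}
    root = Path(path)
    mpath = root / "manifest.json"
    if not mpath.is_file():
        raise ContainerError(f"corrupt archive: missing manifest.json in {root}")
    manifest = json.loads(mpath.read_text(encoding="utf-8"))
    fmt = manifest.get("format")
    if fmt not in registry:
        raise IncompatibleArtifactError(f"unknown artifact format {fmt!r}")
    if manifest.get("version") != SCHEMA_VERSION:
        raise IncompatibleArtifactError(
            f"artifact schema version {manifest.get('version')!r} is incompatible "
            f"with supported version {SCHEMA_VERSION}")
    ppath = root / "params.npz"
    if not ppath.is_file():
        raise ContainerError("corrupt archive: missing params.npz")
    if _sha256(ppath) != manifest.get("params_sha256"):
        raise ContainerError("corrupt archive: params.npz checksum mismatch")
    try:
        with np.load(ppath) as npz:
            arrays = {k: npz[k] for k in npz.files}
    except (zipfile.BadZipFile, ValueError, OSError) as exc:
        raise ContainerError(f"corrupt archive: unreadable params.npz ({exc})") from exc
    return registry[fmt].from_state(manifest, arrays)


# ---------------------------------------------------------------------------
# Anchor sets
# ---------------------------------------------------------------------------

def write_anchors(anchors, path) -> Path:
    """Write an :class:`~ftda.anchors.AnchorSet` as JSON."""
    dest = Path(path)
    dest.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "format": ANCHORS_FORMAT,
        "version": SCHEMA_VERSION,
        "method": anchors.method,
        "K": anchors.K,
        "seed": anchors.seed,
        "start_index": anchors.start_index,
        "indices": [int(i) for i in anchors.indices],
    }
    fd, tmp = tempfile.mkstemp(prefix=dest.name + ".tmp.", dir=dest.parent)
    os.close(fd)
    _write_json(Path(tmp), payload)
    os.replace(tmp, dest)
    return dest


def read_anchors(path):
    from .anchors import AnchorSet

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != ANCHORS_FORMAT:
        raise IncompatibleArtifactError(
            f"not an anchor set: format {payload.get('format')!r}")
    if payload.get("version") != SCHEMA_VERSION:
        raise IncompatibleArtifactError(
            f"unsupported anchor schema version {payload.get('version')!r}")
    return AnchorSet(indices=tuple(payload["indices"]), method=payload["method"],
                     K=payload["K"], seed=payload["seed"],
                     start_index=payload["start_index"])
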