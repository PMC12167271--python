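"""The feed-forward modality-alignment map from image to text embedding space.

A small rectifier network (two hidden layers of 128 units) is fit on the K
anchor pairs by minimizing the mean squared error

    (1/K) * sum_i || f(v_image_i) - v_text_i ||^2,

i.e. the squared Euclidean norm averaged over pairs only (not additionally
over dimensions).  All K anchors are training data — no validation split is
held out, since K is tiny by design.  Training is seeded and reproducible
bit-for-bit under fixed arithmetic settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._nn import MLP, Adam
from .errors import ValidationError
from .io import EmbeddingSet

__all__ = ["AlignTrainConfig", "AlignmentMap", "fit_alignment",
           "apply_alignment", "alignment_mse"]

HIDDEN_WIDTHS = (128, 128)


@dataclass(frozen=True)
class AlignTrainConfig:
    """Alignment training hyperparameters (Adam, lr 1e-3, 15 epochs, batch 16)."""

    lr: float = 0.001
    epochs: int = 15
    batch_size: int = 16
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self):
        if self.lr <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValidationError("lr, epochs and batch_size must be positive")
        if self.optimizer != "adam":
            raise ValidationError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class AlignmentMap:
    """A trained image-to-text alignment transform (or the identity)."""

    kind: str  # "mlp" | "identity"
    d_in: int
    d_out: int
    mlp: Optional[MLP] = None
    meta: dict = field(default_factory=dict)

    @classmethod
    def identity(cls, d: int) -> "AlignmentMap":
        """Pass-through map for no-anchor baselines (requires d_in == d_out)."""
        return cls(kind="identity", d_in=int(d), d_out=int(d),
                   meta={"note": "identity (no-anchor baseline)"})

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=np.float32)
        if matrix.ndim == 1:
            return self.transform(matrix[None, :])[0]
        if matrix.shape[1] != self.d_in:
            raise ValidationError(
                f"input dimension {matrix.shape[1]} != map input dimension {self.d_in}")
        if self.kind == "identity":
            return matrix.copy()
        return self.mlp(matrix)

    # -- serialization -----------------------------------------------------

    def to_manifest(self) -> dict:
        return {
            "format": "ftda-alignment-map",
            "kind": self.kind,
            "d_in": self.d_in,
            "d_out": self.d_out,
            "hidden": list(self.mlp.hidden) if self.mlp else [],
            "meta": {k: v for k, v in self.meta.items()},
        }

    def to_arrays(self) -> dict:
        return dict(self.mlp.params) if self.mlp else {}

    @classmethod
    def from_state(cls, manifest: dict, arrays: dict) -> "AlignmentMap":
        obj = cls(kind=manifest["kind"], d_in=manifest["d_in"],
                  d_out=manifest["d_out"], meta=dict(manifest.get("meta", {})))
        if obj.kind == "mlp":
            mlp = MLP(obj.d_in, obj.d_out, hidden=tuple(manifest["hidden"]))
            for key in mlp.params:
                mlp.params[key] = np.asarray(arrays[key], dtype=np.float32)
            obj.mlp = mlp
        return obj


def alignment_mse(pred_rows: np.ndarray, text_rows: np.ndarray) -> float:
    """Mean over pairs of the squared Euclidean distance (the training loss)."""
    diff = np.asarray(pred_rows, dtype=np.float64) - np.asarray(text_rows, dtype=np.float64)
    return float((diff ** 2).sum(axis=1).mean())


def fit_alignment(image_rows: np.ndarray, text_rows: np.ndarray,
                  cfg: AlignTrainConfig = AlignTrainConfig()) -> AlignmentMap:
    """Fit the alignment network on K anchor pairs."""
    X = np.asarray(image_rows, dtype=np.float32)
    T = np.asarray(text_rows, dtype=np.float32)
    if X.ndim != 2 or T.ndim != 2:
        raise ValidationError("image_rows and text_rows must be 2-D matrices")
    if X.shape[0] == 0:
        raise ValidationError("cannot fit an alignment map on zero anchor pairs")
    if X.shape[0] != T.shape[0]:
        raise ValidationError(
            f"row-count mismatch: {X.shape[0]} image rows vs {T.shape[0]} text rows")
    if not (np.isfinite(X).all() and np.isfinite(T).all()):
        raise ValidationError("anchor matrices contain non-finite values")

    K = X.shape[0]
    mlp = MLP(X.shape[1], T.shape[1], hidden=HIDDEN_WIDTHS, seed=cfg.seed)
    opt = Adam(mlp.params, lr=cfg.lr)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 3]))

    initial_loss = alignment_mse(mlp(X), T)
    for _ in range(cfg.epochs):
        order = rng.permutation(K)
        for lo in range(0, K, cfg.batch_size):
            batch = order[lo:lo + cfg.batch_size]
            xb, tb = X[batch], T[batch]
            yb, cache = mlp.forward(xb)
            dy = (2.0 / len(batch)) * (yb - tb)
            grads = mlp.backward(cache, dy)
            opt.step(mlp.params, grads)
    final_loss = alignment_mse(mlp(X), T)

    meta = {"K": K, "lr": cfg.lr, "epochs": cfg.epochs,
            "batch_size": cfg.batch_size, "seed": cfg.seed,
            "initial_loss": initial_loss, "final_loss": final_loss}
    return AlignmentMap(kind="mlp", d_in=X.shape[1], d_out=T.shape[1],
                        mlp=mlp, meta=meta)


def apply_alignment(amap: AlignmentMap, E: EmbeddingSet) -> EmbeddingSet:
    """Row-wise application of the map; output keeps the image modality tag."""
    if E.d != amap.d_in:
        raise ValidationError(
            f"embedding dimension {E.d} != map input dimension {amap.d_in}")
    return EmbeddingSet(ids=E.ids, matrix=amap.transform(E.matrix),
                        modality="image")
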