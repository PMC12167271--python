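"""Modality-gap diagnostics and before/after visualization.

The gap between paired image and text embedding clouds is operationalized by
three scalars plus a deterministic 2-D projection:

* mean paired Euclidean distance ``mean_i ||v_img_i - v_txt_i||``;
* distance between the two modality centroids (mean vectors);
* cross-modal retrieval recall@1 — the fraction of image rows whose own pair
  is among their nearest text rows (Euclidean; tie-aware, since repeated
  labels make identical text rows common);
* principal-component projection of the stacked ``2n x d`` matrix, one 2-D
  point per row per modality (deterministic, unlike neighbor embeddings).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .errors import ValidationError
from .io import EmbeddingSet

__all__ = ["GapReport", "gap_metrics", "gap_figure"]


@dataclass
class GapReport:
    mean_paired_distance: float
    centroid_distance: float
    recall_at_1: float
    projection_image: np.ndarray  # (n, 2)
    projection_text: np.ndarray   # (n, 2)

    def scalars(self) -> dict:
        return {"mean_paired_distance": self.mean_paired_distance,
                "centroid_distance": self.centroid_distance,
                "recall_at_1": self.recall_at_1}


def gap_metrics(img: EmbeddingSet, txt: EmbeddingSet) -> GapReport:
    """Gap diagnostics for position-paired image/text embedding sets."""
    if img.n != txt.n:
        raise ValidationError(f"row-count mismatch: {img.n} image vs {txt.n} text rows")
    if img.d != txt.d:
        raise ValidationError(f"dimension mismatch: {img.d} vs {txt.d}")
    if img.n == 0:
        raise ValidationError("cannot compute gap metrics on an empty corpus")
    X = img.matrix.astype(np.float64)
    T = txt.matrix.astype(np.float64)

    paired = np.linalg.norm(X - T, axis=1)
    centroid = float(np.linalg.norm(X.mean(axis=0) - T.mean(axis=0)))
    # tie-aware retrieval: a hit when the own pair is *a* nearest text row
    # (classification corpora repeat identical text embeddings, so exact ties
    # are the norm, not the exception)
    D = cdist(X, T)
    dmin = D.min(axis=1)
    recall = float(np.mean(D[np.arange(img.n), np.arange(img.n)]
                           <= dmin + 1e-9))

    stacked = np.vstack([X, T])
    n_comp = min(2, stacked.shape[0], stacked.shape[1])
    proj = PCA(n_components=n_comp, svd_solver="full").fit_transform(stacked)
    if n_comp < 2:
        proj = np.hstack([proj, np.zeros((proj.shape[0], 2 - n_comp))])
    return GapReport(mean_paired_distance=float(paired.mean()),
                     centroid_distance=centroid,
                     recall_at_1=recall,
                     projection_image=proj[: img.n],
                     projection_text=proj[img.n:])


def gap_figure(before: GapReport, after: GapReport, path) -> Path:
    """Two-panel scatter of the projections before and after alignment."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5), sharex=False)
    for ax, rep, title in ((axes[0], before, "before alignment"),
                           (axes[1], after, "after alignment")):
        ax.scatter(rep.projection_image[:, 0], rep.projection_image[:, 1],
                   s=8, c="goldenrod", label="image", alpha=0.7)
        ax.scatter(rep.projection_text[:, 0], rep.projection_text[:, 1],
                   s=8, c="steelblue", label="text", alpha=0.7)
        ax.set_title(f"{title}\nmean paired distance "
                     f"{rep.mean_paired_distance:.3f}, "
                     f"R@1 {rep.recall_at_1:.2f}")
        ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
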