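"""Few-shot data-anchor selection from the image-embedding cloud.

Two selection strategies are provided:

* ``kmeans_anchors`` — cluster the embeddings with seeded k-means (k-means++
  init, 10 restarts) and take the dataset row nearest each final centroid;
* ``fps_anchors`` — greedy farthest-point sampling, repeatedly adding the row
  with maximal distance to its nearest already-selected row.

Both return indices into the dataset (selection, never synthesis).  Distances
are Euclidean on the raw embeddings; an optional per-row L2 normalization flag
is available but off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances

from .errors import DegenerateDataError, ValidationError
from .io import EmbeddingSet, PairedCorpus

__all__ = ["AnchorSet", "kmeans_anchors", "fps_anchors", "gather_anchor_pairs"]


@dataclass(frozen=True)
class AnchorSet:
    """Indices of the K selected few-shot anchors plus selection metadata."""

    indices: tuple
    method: str  # "kmeans" | "fps"
    K: int
    seed: Optional[int] = None
    start_index: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))
        if self.method not in ("kmeans", "fps"):
            raise ValidationError(f"unknown anchor method {self.method!r}")
        if len(self.indices) != self.K or self.K < 1:
            raise ValidationError(
                f"anchor set has {len(self.indices)} indices but K={self.K}")
        if len(set(self.indices)) != len(self.indices):
            raise ValidationError("anchor indices must be distinct")
        if any(i < 0 for i in self.indices):
            raise ValidationError("anchor indices must be non-negative")

    def validate_for(self, n: int) -> None:
        if self.K > n or any(i >= n for i in self.indices):
            raise ValidationError(
                f"anchor indices out of range for a corpus of {n} rows")


def _embedding_matrix(E, normalize: bool) -> np.ndarray:
    X = E.matrix if isinstance(E, EmbeddingSet) else np.asarray(E)
    X = X.astype(np.float64)
    if normalize:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        X = X / np.where(norms == 0.0, 1.0, norms)
    return X


def kmeans_anchors(E, K: int, seed: int = 0, normalize: bool = False) -> AnchorSet:
    """Select K anchors as the dataset rows nearest the k-means centroids.

    Centroid-to-row assignment walks clusters in cluster-id order; a row
    already claimed by an earlier cluster is replaced by the next-nearest
    unused row, and exact distance ties break toward the lowest row index.
    """
    X = _embedding_matrix(E, normalize)
    n = X.shape[0]
    if not 1 <= K <= n:
        raise ValidationError(f"K={K} must satisfy 1 <= K <= n={n}")
    if K > 1 and np.all(X == X[0]):
        raise DegenerateDataError(
            f"all {n} rows are identical; cannot select K={K} > 1 distinct anchors")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points can trip ConvergenceWarning
        km = KMeans(n_clusters=K, init="k-means++", n_init=10,
                    random_state=int(seed)).fit(X)
    dists = pairwise_distances(km.cluster_centers_, X)  # (K, n)
    used = np.zeros(n, dtype=bool)
    indices = []
    for cluster in range(K):
        row_d = np.where(used, np.inf, dists[cluster])
        idx = int(np.argmin(row_d))  # argmin ties resolve to the lowest index
        indices.append(idx)
        used[idx] = True
    return AnchorSet(indices=tuple(indices), method="kmeans", K=K, seed=int(seed))


def medoid_index(E, normalize: bool = False) -> int:
    """Row minimizing the sum of Euclidean distances to all rows."""
    X = _embedding_matrix(E, normalize)
    totals = pairwise_distances(X, X).sum(axis=1)
    return int(np.argmin(totals))


def fps_anchors(E, K: int, start_index: Optional[int] = None,
                normalize: bool = False) -> AnchorSet:
    """Greedy farthest-point sampling under Euclidean distance.

    Starts at ``start_index`` (default: the dataset medoid) and repeatedly
    adds the row with maximal distance to its nearest selected row, breaking
    ties toward the lowest row index.  Indices are returned in selection
    order.
    """
    X = _embedding_matrix(E, normalize)
    n = X.shape[0]
    if not 1 <= K <= n:
        raise ValidationError(f"K={K} must satisfy 1 <= K <= n={n}")
    if start_index is None:
        start_index = medoid_index(E, normalize)
    start_index = int(start_index)
    if not 0 <= start_index < n:
        raise ValidationError(f"start_index={start_index} out of range [0, {n})")

    selected = [start_index]
    min_dist = np.linalg.norm(X - X[start_index], axis=1)
    for _ in range(K - 1):
        min_dist[selected] = -np.inf  # keep selected rows out of the argmax
        nxt = int(np.argmax(min_dist))  # first max == lowest-index tie-break
        selected.append(nxt)
        np.minimum(min_dist, np.linalg.norm(X - X[nxt], axis=1), out=min_dist)
    return AnchorSet(indices=tuple(selected), method="fps", K=K,
                     start_index=start_index)


def gather_anchor_pairs(corpus: PairedCorpus, anchors: AnchorSet, task: str,
                        text_encoder):
    """Paired (image, text-embedding) rows for the selected anchors.

    Row *i* of both returned matrices corresponds to anchor *i*; the text
    matrix is ``text_encoder`` applied to each anchor's task text.
    """
    if task not in corpus.texts:
        raise KeyError(
            f"task {task!r} not in corpus (available: {sorted(corpus.texts)})")
    anchors.validate_for(corpus.n)
    idx = np.asarray(anchors.indices, dtype=int)
    image_rows = corpus.image_embeddings.matrix[idx].astype(np.float32)
    text_rows = np.stack(
        [np.asarray(text_encoder(corpus.texts[task][i]), dtype=np.float32)
         for i in idx])
    return image_rows, text_rows
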