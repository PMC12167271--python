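"""Anchor selection: k-means exemplars, farthest-point sampling, pair gathering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from ftda import (EmbeddingSet, PairedCorpus, TaskInfo, ToyTextEncoder,
                  fps_anchors, gather_anchor_pairs, kmeans_anchors)
from ftda.errors import DegenerateDataError, ValidationError


def _col(values):
    return np.asarray(values, dtype=np.float32).reshape(-1, 1)


def _reference_fps(X, K, start):
    """Independent greedy oracle: full distance matrix, explicit arg-scan."""
    D = cdist(np.asarray(X, float), np.asarray(X, float))
    chosen = [start]
    while len(chosen) < K:
        rest = [i for i in range(len(X)) if i not in chosen]
        dmin = {i: D[i, chosen].min() for i in rest}
        best = max(dmin.values())
        chosen.append(min(i for i in rest if dmin[i] == best))
    return chosen


class TestKMeansAnchors:
    def test_k_equals_n_selects_every_row(self, rng):
        X = rng.normal(size=(6, 3))
        aset = kmeans_anchors(X, 6, seed=0)
        assert sorted(aset.indices) == list(range(6))

    def test_single_centroid_is_row_nearest_global_mean(self):
        # mean of (0, 0.1, 0.2, 10) is 2.575; the nearest row is 0.2 (index 2)
        aset = kmeans_anchors(_col([0.0, 0.1, 0.2, 10.0]), 1, seed=0)
        assert aset.indices == (2,)

    def test_two_blobs_yield_the_blob_medians(self):
        aset = kmeans_anchors(_col([0.0, 0.1, 0.2, 10.0, 10.1, 10.2]), 2, seed=0)
        assert sorted(aset.indices) == [1, 4]

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValidationError):
            kmeans_anchors(rng.normal(size=(3, 2)), 4)

    def test_degenerate_identical_rows_rejected(self):
        with pytest.raises(DegenerateDataError, match="identical"):
            kmeans_anchors(np.ones((5, 2)), 2)

    def test_one_anchor_per_separated_blob(self, rng):
        centers = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 50.0]])
        for trial in range(5):
            X = np.vstack([c + rng.normal(scale=1.0, size=(30, 2))
                           for c in centers])
            labels = np.repeat([0, 1, 2], 30)
            aset = kmeans_anchors(X, 3, seed=trial)
            assert sorted(labels[list(aset.indices)]) == [0, 1, 2]


class TestFpsAnchors:
    def test_k1_returns_start_index(self, rng):
        X = rng.normal(size=(5, 2))
        assert fps_anchors(X, 1, start_index=3).indices == (3,)

    def test_line_example_prefers_far_point(self):
        aset = fps_anchors(_col([0.0, 1.0, 2.0, 10.0]), 2, start_index=0)
        assert aset.indices == (0, 3)

    def test_square_with_center_selects_corners_lowest_index_first(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1], [0.5, 0.5]], float)
        aset = fps_anchors(X, 5, start_index=4)
        assert aset.indices == (4, 0, 1, 2, 3)

    def test_default_start_is_medoid(self):
        X = _col([0.0, 1.0, 1.1, 1.2, 10.0])
        # row 2 (1.1) minimizes the summed distance to all rows
        assert fps_anchors(X, 1).indices == (2,)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_matches_independent_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        d = int(rng.integers(1, 4))
        K = int(rng.integers(1, n + 1))
        start = int(rng.integers(0, n))
        X = rng.normal(size=(n, d))
        got = list(fps_anchors(X, K, start_index=start).indices)
        assert got == _reference_fps(X, K, start)

    def test_spread_beats_uniform_sampling(self):
        """FPS min pairwise distance >= uniform sampling in >=95% of trials."""
        wins = 0
        for trial in range(100):
            rng = np.random.default_rng(trial)
            centers = rng.normal(scale=10.0, size=(4, 2))
            X = np.vstack([c + rng.normal(size=(25, 2)) for c in centers])
            K = 8
            fps_idx = list(fps_anchors(X, K).indices)
            uni_idx = rng.choice(len(X), size=K, replace=False)
            def min_pair(idx):
                D = cdist(X[idx], X[idx])
                return D[np.triu_indices(len(idx), k=1)].min()
            wins += min_pair(fps_idx) >= min_pair(uni_idx)
        assert wins >= 95


class TestGatherAnchorPairs:
    @pytest.fixture()
    def corpus(self, rng):
        emb = EmbeddingSet(ids=[f"s{i}" for i in range(5)],
                           matrix=rng.normal(size=(5, 8)), modality="image")
        labels = ("phase_1", "phase_3")
        return PairedCorpus(
            image_embeddings=emb,
            texts={"phase": ["phase_3", "phase_1", "phase_3", "phase_1",
                             "phase_3"]},
            tasks={"phase": TaskInfo(type="classification", label_set=labels)})

    def test_rows_align_with_anchor_order(self, corpus):
        enc = ToyTextEncoder(d_text=8, seed=0)
        aset = fps_anchors(corpus.image_embeddings, 2, start_index=0)
        img, txt = gather_anchor_pairs(corpus, aset, "phase", enc)
        assert img.shape == (2, 8) and txt.shape == (2, 8)
        for row, anchor in enumerate(aset.indices):
            assert np.array_equal(img[row],
                                  corpus.image_embeddings.matrix[anchor])

    def test_identical_labels_give_identical_text_rows(self, corpus):
        enc = ToyTextEncoder(d_text=8, seed=0)
        from ftda.anchors import AnchorSet
        aset = AnchorSet(indices=(0, 2), method="fps", K=2, start_index=0)
        _, txt = gather_anchor_pairs(corpus, aset, "phase", enc)
        assert np.array_equal(txt[0], txt[1])  # both anchors say "phase_3"

    def test_unknown_task_is_key_error(self, corpus):
        enc = ToyTextEncoder(d_text=8, seed=0)
        aset = fps_anchors(corpus.image_embeddings, 1, start_index=0)
        with pytest.raises(KeyError):
            gather_anchor_pairs(corpus, aset, "caption", enc)

    def test_out_of_range_anchor_rejected(self, corpus):
        from ftda.anchors import AnchorSet
        enc = ToyTextEncoder(d_text=8, seed=0)
        bad = AnchorSet(indices=(0, 7), method="fps", K=2, start_index=0)
        with pytest.raises(ValidationError):
            gather_anchor_pairs(corpus, bad, "phase", enc)
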