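"""Alignment-map training and application."""

import numpy as np
import pytest

from ftda import (AlignTrainConfig, AlignmentMap, EmbeddingSet,
                  apply_alignment, fit_alignment, gap_metrics)
from ftda.align import alignment_mse
from ftda.errors import ValidationError
from ftda.experiments import affine_gap_data


def test_default_config_matches_stated_hyperparameters():
    cfg = AlignTrainConfig()
    assert (cfg.lr, cfg.epochs, cfg.batch_size, cfg.optimizer) == \
        (0.001, 15, 16, "adam")


def test_identity_target_training_reduces_mse(rng):
    X = rng.normal(size=(50, 8)).astype(np.float32)
    amap = fit_alignment(X, X, AlignTrainConfig(seed=0))
    assert amap.meta["final_loss"] <= amap.meta["initial_loss"]


def test_training_is_reproducible_bitwise(rng):
    X = rng.normal(size=(30, 6)).astype(np.float32)
    T = rng.normal(size=(30, 6)).astype(np.float32)
    m1 = fit_alignment(X, T, AlignTrainConfig(seed=3, epochs=3))
    m2 = fit_alignment(X, T, AlignTrainConfig(seed=3, epochs=3))
    for key in m1.mlp.params:
        assert np.array_equal(m1.mlp.params[key], m2.mlp.params[key])


def test_zero_weight_map_outputs_bias_vector(rng):
    X = rng.normal(size=(10, 4)).astype(np.float32)
    amap = fit_alignment(X, X, AlignTrainConfig(epochs=1, seed=0))
    for key in list(amap.mlp.params):
        amap.mlp.params[key][:] = 0.0
    bias = np.arange(4, dtype=np.float32)
    amap.mlp.params["b2"][:] = bias
    out = amap.transform(X)
    assert np.array_equal(out, np.tile(bias, (10, 1)))


def test_apply_preserves_order_and_modality(rng):
    X = rng.normal(size=(12, 5)).astype(np.float32)
    amap = fit_alignment(X, X, AlignTrainConfig(epochs=1, seed=0))
    E = EmbeddingSet(ids=[f"s{i}" for i in range(12)], matrix=X,
                     modality="image")
    out = apply_alignment(amap, E)
    assert out.ids == E.ids and out.modality == "image" and out.n == 12
    out2 = apply_alignment(amap, E)
    assert np.array_equal(out.matrix, out2.matrix)


def test_dimension_mismatch_names_both_dimensions(rng):
    X = rng.normal(size=(10, 4)).astype(np.float32)
    amap = fit_alignment(X, X, AlignTrainConfig(epochs=1, seed=0))
    E = EmbeddingSet(ids=["a"], matrix=np.zeros((1, 7)), modality="image")
    with pytest.raises(ValidationError, match="7.*4"):
        apply_alignment(amap, E)


def test_rejects_empty_and_mismatched_anchors():
    with pytest.raises(ValidationError):
        fit_alignment(np.zeros((0, 3)), np.zeros((0, 3)))
    with pytest.raises(ValidationError, match="mismatch"):
        fit_alignment(np.zeros((4, 3)), np.zeros((5, 3)))


def test_rectangular_map_adapts_input_output_widths(rng):
    X = rng.normal(size=(40, 6)).astype(np.float32)
    T = rng.normal(size=(40, 3)).astype(np.float32)
    amap = fit_alignment(X, T, AlignTrainConfig(epochs=2, seed=0))
    assert amap.transform(X).shape == (40, 3)
    assert amap.mlp.hidden == (128, 128)


def test_alignment_shrinks_the_gap_on_affine_corpus():
    X, T = affine_gap_data(200, 8, seed=0, sample_key=0)
    amap = fit_alignment(X, T, AlignTrainConfig(seed=0))
    before = alignment_mse(X, T)
    after = alignment_mse(amap.transform(X), T)
    assert after < before
    img = EmbeddingSet(ids=[str(i) for i in range(200)], matrix=X,
                       modality="image")
    txt = EmbeddingSet(ids=[str(i) for i in range(200)], matrix=T,
                       modality="text")
    aligned = apply_alignment(amap, img)
    assert (gap_metrics(aligned, txt).mean_paired_distance
            < gap_metrics(img, txt).mean_paired_distance)


def test_identity_map_passes_through(rng):
    amap = AlignmentMap.identity(5)
    X = rng.normal(size=(3, 5)).astype(np.float32)
    assert np.array_equal(amap.transform(X), X)
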