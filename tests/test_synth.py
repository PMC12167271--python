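"""Synthetic-corpus generator and toy text encoder."""

import numpy as np
import pytest

from ftda import (SynthConfig, ToyTextEncoder, gap_metrics,
                  make_standard_fixture, simulate_corpus, text_embeddings,
                  toy_text_encoder)
from ftda.errors import ValidationError
from ftda.synth import PHASES, corpus_encoder


class TestToyTextEncoder:
    def test_deterministic(self):
        a = toy_text_encoder("phase_3", 32, seed=0)
        b = toy_text_encoder("phase_3", 32, seed=0)
        assert np.array_equal(a, b)

    def test_unit_norm_for_every_input(self):
        enc = ToyTextEncoder(16, seed=1)
        for text in ("preparation", "the grasper retracts the gallbladder",
                     "a", "x y z"):
            assert np.linalg.norm(enc(text)) == pytest.approx(1.0, abs=1e-6)

    def test_distinct_phase_labels_are_separated(self):
        enc = ToyTextEncoder(32, seed=0)
        vecs = [enc(p) for p in PHASES]
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                assert np.linalg.norm(vecs[i] - vecs[j]) > 0.1

    def test_empty_text_rejected(self):
        with pytest.raises(ValidationError):
            ToyTextEncoder(8)("   ")


class TestSimulateCorpus:
    def test_gap_off_makes_image_equal_text(self):
        cfg = SynthConfig(n=40, d=16, seed=3, tasks=("phase",), sigma=0.0,
                          offset_norm=0.0, rotation=False)
        corpus, _ = simulate_corpus(cfg)
        txt = text_embeddings(corpus, "phase", corpus_encoder(cfg))
        assert np.array_equal(corpus.image_embeddings.matrix, txt.matrix)

    def test_same_config_is_bit_identical(self):
        cfg = SynthConfig(n=30, d=8, seed=5, tasks=("phase", "triplet"))
        c1, t1 = simulate_corpus(cfg)
        c2, t2 = simulate_corpus(cfg)
        assert c1.equals(c2)
        assert t1.equals(t2)

    def test_mean_paired_distance_at_least_offset_norm(self):
        cfg = SynthConfig(n=200, d=32, seed=0, tasks=("phase",),
                          separation=10.0, sigma=0.3, offset_norm=5.0)
        corpus, _ = simulate_corpus(cfg)
        txt = text_embeddings(corpus, "phase", corpus_encoder(cfg))
        rep = gap_metrics(corpus.image_embeddings, txt)
        assert rep.mean_paired_distance >= cfg.offset_norm

    def test_gap_grows_with_offset_and_noise(self):
        """Mean paired distance is monotone in ||c|| and sigma (rotation off)."""
        for seed in range(3):
            grid = np.zeros((3, 3))
            for i, off in enumerate((0.0, 2.0, 6.0)):
                for j, sig in enumerate((0.0, 0.5, 1.5)):
                    cfg = SynthConfig(n=150, d=16, seed=seed, tasks=("phase",),
                                      sigma=sig, offset_norm=off,
                                      rotation=False)
                    corpus, _ = simulate_corpus(cfg)
                    txt = text_embeddings(corpus, "phase", corpus_encoder(cfg))
                    grid[i, j] = gap_metrics(corpus.image_embeddings,
                                             txt).mean_paired_distance
            assert (np.diff(grid, axis=0) >= -1e-9).all()
            assert (np.diff(grid, axis=1) >= -1e-9).all()

    def test_classification_texts_lie_in_label_sets(self):
        cfg = SynthConfig(n=50, d=8, seed=1, tasks=("phase", "triplet"))
        corpus, truth = simulate_corpus(cfg)
        assert set(corpus.texts["phase"]) <= set(corpus.tasks["phase"].label_set)
        assert set(corpus.texts["triplet"]) <= set(
            corpus.tasks["triplet"].label_set)
        assert list(truth["phase"]) == list(corpus.texts["phase"])

    def test_too_many_phases_rejected(self):
        with pytest.raises(ValidationError):
            SynthConfig(n=5, d=4, seed=0, k_phases=9)


class TestStandardFixture:
    def test_regenerates_bit_identically(self, fixture_bundle):
        again = make_standard_fixture(seed=0)
        assert again.train.equals(fixture_bundle.train)
        assert again.test.equals(fixture_bundle.test)

    def test_dimensions_and_vocabularies(self, fixture_bundle):
        fx = fixture_bundle
        assert fx.train.n == 700 and fx.test.n == 300
        assert fx.train.image_embeddings.d == 32
        assert len(fx.train.tasks["phase"].label_set) == 7
        assert len(fx.train.tasks["triplet"].label_set) == 12
        assert len(set(fx.train.texts["caption"])) <= 50

    def test_phase_classes_balanced_within_one(self, fixture_bundle):
        from collections import Counter
        counts = Counter(fixture_bundle.train.texts["phase"])
        assert max(counts.values()) - min(counts.values()) <= 1

    def test_sample_seed_varies_samples_not_structure(self):
        cfg = SynthConfig(n=20, d=8, seed=2, tasks=("phase",))
        c1, _ = simulate_corpus(cfg, sample_seed=100)
        c2, _ = simulate_corpus(cfg, sample_seed=101)
        assert not np.array_equal(c1.image_embeddings.matrix,
                                  c2.image_embeddings.matrix)
        # same label -> same text embedding geometry (shared encoder)
        enc = corpus_encoder(cfg)
        assert np.array_equal(enc("preparation"), enc("preparation"))
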