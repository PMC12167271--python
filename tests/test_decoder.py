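"""Tokenizer and text-only decoder training/generation."""

import inspect

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ftda import (DecoderTrainConfig, ToyTextEncoder, build_tokenizer,
                  generate, train_decoder)
from ftda.decoder import SPECIALS, Tokenizer, UNK
from ftda.errors import TruncationError, ValidationError


class TestTokenizer:
    def test_vocabulary_is_corpus_words_plus_specials(self):
        tok = build_tokenizer(["a b", "b c"])
        assert tok.size == 7
        assert set(tok.vocab) == set(SPECIALS) | {"a", "b", "c"}

    def test_encode_decode_round_trip(self):
        tok = build_tokenizer(["a b", "b c"])
        assert tok.decode(tok.encode("a b")) == "a b"

    def test_unseen_token_maps_to_unk_marker(self):
        tok = build_tokenizer(["a b"])
        ids = tok.encode("a z")
        assert ids[1] == UNK
        assert tok.decode(ids) == "a <unk>"

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValidationError):
            build_tokenizer([])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.text(alphabet=st.characters(
        whitelist_categories=("Ll", "Lu", "Nd"), max_codepoint=0x24F),
        min_size=1, max_size=6), min_size=1, max_size=8))
    def test_round_trips_any_canonical_text(self, words):
        text = " ".join(words)
        tok = build_tokenizer([text])
        assert tok.decode(tok.encode(text)) == text

    def test_round_trips_every_training_text(self, fixture_bundle):
        texts = [t for task in ("phase", "triplet", "caption")
                 for t in fixture_bundle.train.texts[task]]
        tok = build_tokenizer(texts)
        for t in set(texts):
            assert tok.decode(tok.encode(t)) == t


class TestTrainDecoder:
    def test_default_config_matches_stated_hyperparameters(self):
        cfg = DecoderTrainConfig()
        assert (cfg.optimizer, cfg.epochs, cfg.batch_size) == ("adamw", 10, 34)
        assert cfg.prefix_len == 8
        assert cfg.resolved_lr == pytest.approx(3e-4)  # from-scratch backbone
        assert DecoderTrainConfig(pretrained_backbone=True).resolved_lr == \
            pytest.approx(2e-5)

    def test_training_has_no_image_input(self):
        params = inspect.signature(train_decoder).parameters
        assert "texts" in params and "text_encoder" in params
        assert not any("image" in name for name in params)

    def test_single_repeated_text_is_memorized(self, unit_encoder):
        text = "clip the cystic duct"
        cfg = DecoderTrainConfig(seed=0, epochs=10, batch_size=16,
                                 preset="mini", max_length=8)
        model = train_decoder([text] * 40, unit_encoder, cfg)
        assert model.generate(unit_encoder(text)) == text

    def test_loss_trajectory_recorded_and_decreasing(self, small_decoder):
        history = small_decoder.meta["loss_history"]
        assert len(history) == small_decoder.meta["epochs"] + 1
        assert history[-1] < history[0]

    def test_epoch_losses_non_increasing_across_seeds(self, unit_encoder):
        texts = ["clip applied", "hook dissection", "irrigation"] * 20
        for seed in range(3):
            cfg = DecoderTrainConfig(seed=seed, epochs=6, batch_size=16,
                                     preset="mini", max_length=8)
            h = train_decoder(texts, unit_encoder, cfg).meta["loss_history"]
            assert all(b <= a for a, b in zip(h, h[1:])), h

    def test_over_long_text_raises_truncation_error(self, unit_encoder):
        cfg = DecoderTrainConfig(max_length=3, epochs=1)
        with pytest.raises(TruncationError, match="max_length"):
            train_decoder(["one two three four"], unit_encoder, cfg)

    def test_empty_corpus_rejected(self, unit_encoder):
        with pytest.raises(ValidationError):
            train_decoder([], unit_encoder, DecoderTrainConfig())


class TestGenerate:
    def test_greedy_is_deterministic(self, small_decoder, unit_encoder):
        emb = unit_encoder("hook dissection")
        assert small_decoder.generate(emb) == small_decoder.generate(emb)

    def test_max_length_zero_gives_empty_string(self, small_decoder,
                                                unit_encoder):
        assert small_decoder.generate(unit_encoder("irrigation"),
                                      max_length=0) == ""

    def test_seeded_sampling_is_reproducible(self, small_decoder, unit_encoder):
        emb = unit_encoder("clip applied")
        a = small_decoder.generate(emb, mode="sample", seed=11, temperature=1.5)
        b = small_decoder.generate(emb, mode="sample", seed=11, temperature=1.5)
        assert a == b

    def test_dimension_mismatch_rejected(self, small_decoder):
        with pytest.raises(ValidationError):
            small_decoder.generate(np.zeros(5, dtype=np.float32))

    def test_batch_generation_matches_single(self, small_decoder, unit_encoder):
        embs = np.stack([unit_encoder("clip applied"),
                         unit_encoder("irrigation")])
        batch = small_decoder.generate(embs)
        assert batch == [small_decoder.generate(embs[0]),
                         small_decoder.generate(embs[1])]

    def test_module_level_alias(self, small_decoder, unit_encoder):
        emb = unit_encoder("irrigation")
        assert generate(small_decoder, emb) == small_decoder.generate(emb)


def test_reconstruction_of_closed_vocabulary(unit_encoder):
    """A tiny decoder reconstructs a small closed label set from embeddings."""
    labels = ["preparation", "clipping and cutting", "gallbladder retraction"]
    cfg = DecoderTrainConfig(seed=1, epochs=10, batch_size=16, preset="mini")
    model = train_decoder(labels * 25, unit_encoder, cfg)
    recon = [model.generate(unit_encoder(l)) for l in labels]
    assert recon == labels
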