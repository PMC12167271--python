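"""Prefix-conditioned autoregressive text decoder trained on text embeddings.

Text-only training: each target text ``T`` is encoded by the frozen text
encoder into an embedding ``v``, a linear prefix mapper turns ``v`` into ``P``
prefix vectors, and a small causal transformer is trained to emit
``BOS ... T ... EOS`` conditioned on the prefix, minimizing the summed token
cross-entropy over the corpus.  No image embedding is ever consumed during
training — at inference the same decoder is driven by aligned image
embeddings instead (the encoder swap).

The backbone is a from-scratch tiny causal transformer (default 2 layers,
4 heads, width 128) so the package carries no pretrained-weight dependency;
any object implementing the same ``forward`` / ``loss_and_grad`` /
``embed_tokens`` surface as :class:`ftda._nn.TinyCausalLM` can be substituted
as a backbone.  Greedy decoding is the default wherever results are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._nn import Adam, TinyCausalLM, _softmax, _uniform_fan_in
from .errors import TruncationError, ValidationError

__all__ = ["Tokenizer", "build_tokenizer", "DecoderTrainConfig",
           "DecoderModel", "train_decoder", "generate"]

PAD, BOS, EOS, UNK = 0, 1, 2, 3
SPECIALS = ("<pad>", "<bos>", "<eos>", "<unk>")

PRESETS = {
    "tiny": {"n_layers": 2, "n_heads": 4, "width": 128},
    "mini": {"n_layers": 1, "n_heads": 2, "width": 64},
}


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tokenizer:
    """Word-level vocabulary over a training corpus plus 4 specials.

    Tokens are whitespace-delimited words; encode -> decode round-trips any
    text whose words are separated by single spaces (all corpora produced by
    this package are canonical in that sense).  Unseen words encode to the
    UNK id and decode to the literal UNK marker.
    """

    vocab: tuple

    def __post_init__(self):
        object.__setattr__(self, "_ids", {t: i for i, t in enumerate(self.vocab)})

    @property
    def size(self) -> int:
        return len(self.vocab)

    def encode(self, text: str) -> list:
        return [self._ids.get(tok, UNK) for tok in str(text).split()]

    def decode(self, ids: Sequence[int]) -> str:
        words = []
        for i in ids:
            if i == EOS:
                break
            if i in (PAD, BOS):
                continue
            words.append(self.vocab[i] if 0 <= i < len(self.vocab) else SPECIALS[UNK])
        return " ".join(words)


def build_tokenizer(texts: Sequence[str]) -> Tokenizer:
    """Deterministic word-level tokenizer from a non-empty corpus."""
    texts = list(texts)
    if not texts:
        raise ValidationError("cannot build a tokenizer from an empty corpus")
    words = sorted({tok for t in texts for tok in str(t).split()})
    return Tokenizer(vocab=SPECIALS + tuple(words))


# ---------------------------------------------------------------------------
# Configs and model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecoderTrainConfig:
    """Decoder training hyperparameters (AdamW, 10 epochs, batch 34).

    ``lr=None`` resolves per backbone mode: 3e-4 for the from-scratch tiny
    transformer (the value a randomly initialized model needs), 2e-5 for a
    substituted pretrained backbone.
    """

    optimizer: str = "adamw"
    lr: Optional[float] = None
    epochs: int = 10
    batch_size: int = 34
    seed: int = 0
    prefix_len: int = 8
    preset: str = "tiny"
    max_length: int = 32
    weight_decay: float = 0.01
    pretrained_backbone: bool = False

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0 or self.prefix_len <= 0:
            raise ValidationError("epochs, batch_size and prefix_len must be positive")
        if self.lr is not None and self.lr <= 0:
            raise ValidationError("lr must be positive")
        if self.optimizer != "adamw":
            raise ValidationError(f"unsupported optimizer {self.optimizer!r}")
        if self.preset not in PRESETS:
            raise ValidationError(f"unknown model preset {self.preset!r}")

    @property
    def resolved_lr(self) -> float:
        if self.lr is not None:
            return self.lr
        return 2e-5 if self.pretrained_backbone else 3e-4


@dataclass
class DecoderModel:
    """Tokenizer + prefix mapper + causal LM; greedy generation is deterministic."""

    tokenizer: Tokenizer
    lm: TinyCausalLM
    prefix_w: np.ndarray  # (d_text, P * width)
    prefix_b: np.ndarray  # (P * width,)
    d_text: int
    prefix_len: int
    max_length: int
    meta: dict = field(default_factory=dict)

    def _prefix(self, emb: np.ndarray) -> np.ndarray:
        B = emb.shape[0]
        return (emb @ self.prefix_w + self.prefix_b).reshape(
            B, self.prefix_len, self.lm.width)

    def generate(self, embedding, max_length: Optional[int] = None,
                 mode: str = "greedy", seed: Optional[int] = None,
                 temperature: float = 1.0):
        """Generate text from one embedding (1-D) or a batch (2-D)."""
        emb = np.asarray(embedding, dtype=np.float32)
        single = emb.ndim == 1
        if single:
            emb = emb[None, :]
        if emb.shape[1] != self.d_text:
            raise ValidationError(
                f"embedding dimension {emb.shape[1]} != decoder d_text {self.d_text}")
        if not np.isfinite(emb).all():
            raise ValidationError("embedding contains non-finite values")
        if max_length is None:
            max_length = self.max_length
        n = emb.shape[0]
        if n == 0:
            return []
        if mode not in ("greedy", "sample"):
            raise ValidationError(f"unknown decoding mode {mode!r}")
        rng = np.random.default_rng(seed) if mode == "sample" else None

        prefix = self._prefix(emb)
        tokens = np.full((n, 1), BOS, dtype=np.int64)
        done = np.zeros(n, dtype=bool)
        for _ in range(max_length):
            x = np.concatenate([prefix, self.lm.embed_tokens(tokens)], axis=1)
            logits, _ = self.lm.forward(x)
            last = logits[:, -1, :].astype(np.float64)
            last[:, PAD] = -np.inf
            last[:, BOS] = -np.inf
            if mode == "greedy":
                nxt = last.argmax(axis=1)
            else:
                probs = _softmax(last / max(temperature, 1e-6), axis=1)
                u = rng.random((n, 1))
                nxt = (probs.cumsum(axis=1) < u).sum(axis=1)
            nxt = np.where(done, EOS, nxt)
            tokens = np.concatenate([tokens, nxt[:, None]], axis=1)
            done |= nxt == EOS
            if done.all():
                break
        out = [self.tokenizer.decode(row[1:]) for row in tokens]
        return out[0] if single else out

    # -- serialization -----------------------------------------------------

    def to_manifest(self) -> dict:
        return {
            "format": "ftda-decoder",
            "vocab": list(self.tokenizer.vocab),
            "width": self.lm.width,
            "n_layers": self.lm.n_layers,
            "n_heads": self.lm.n_heads,
            "lm_max_len": self.lm.max_len,
            "d_text": self.d_text,
            "prefix_len": self.prefix_len,
            "max_length": self.max_length,
            "meta": dict(self.meta),
        }

    def to_arrays(self) -> dict:
        arrays = {f"lm.{k}": v for k, v in self.lm.params.items()}
        arrays["prefix_w"] = self.prefix_w
        arrays["prefix_b"] = self.prefix_b
        return arrays

    @classmethod
    def from_state(cls, manifest: dict, arrays: dict) -> "DecoderModel":
        tok = Tokenizer(vocab=tuple(manifest["vocab"]))
        lm = TinyCausalLM(vocab_size=tok.size, width=manifest["width"],
                          n_layers=manifest["n_layers"],
                          n_heads=manifest["n_heads"],
                          max_len=manifest["lm_max_len"])
        for key in lm.params:
            lm.params[key] = np.asarray(arrays[f"lm.{key}"], dtype=np.float32)
        return cls(tokenizer=tok, lm=lm,
                   prefix_w=np.asarray(arrays["prefix_w"], dtype=np.float32),
                   prefix_b=np.asarray(arrays["prefix_b"], dtype=np.float32),
                   d_text=manifest["d_text"], prefix_len=manifest["prefix_len"],
                   max_length=manifest["max_length"],
                   meta=dict(manifest.get("meta", {})))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _batch_arrays(token_lists, batch_idx):
    """Right-padded input/target/mask arrays for one batch."""
    seqs = [token_lists[i] for i in batch_idx]
    L = max(len(s) for s in seqs) + 1  # +1 for EOS target / BOS input shift
    B = len(seqs)
    tokens_in = np.full((B, L), PAD, dtype=np.int64)
    targets = np.full((B, L), PAD, dtype=np.int64)
    mask = np.zeros((B, L), dtype=np.float64)
    for r, s in enumerate(seqs):
        m = len(s)
        tokens_in[r, 0] = BOS
        tokens_in[r, 1:m + 1] = s
        targets[r, :m] = s
        targets[r, m] = EOS
        mask[r, :m + 1] = 1.0
    return tokens_in, targets, mask


def corpus_loss(model: DecoderModel, embeddings: np.ndarray, token_lists,
                batch_size: int = 128) -> float:
    """Total summed-token cross-entropy of the corpus under the model."""
    total = 0.0
    n = len(token_lists)
    for lo in range(0, n, batch_size):
        idx = list(range(lo, min(lo + batch_size, n)))
        tokens_in, targets, mask = _batch_arrays(token_lists, idx)
        prefix = model._prefix(embeddings[idx])
        x = np.concatenate([prefix, model.lm.embed_tokens(tokens_in)], axis=1)
        logits, _ = model.lm.forward(x)
        P = model.prefix_len
        probs = _softmax(logits[:, P:, :].astype(np.float64))
        rows = np.arange(len(idx))[:, None], np.arange(targets.shape[1])[None, :]
        nll = -np.log(np.maximum(probs[rows[0], rows[1], targets], 1e-30))
        total += float((nll * mask).sum())
    return total


def train_decoder(texts: Sequence[str], text_encoder,
                  cfg: DecoderTrainConfig = DecoderTrainConfig()) -> DecoderModel:
    """Train the decoder to reconstruct ``texts`` from their text embeddings.

    ``text_encoder`` must be a deterministic callable string -> embedding.
    The training-loss trajectory (total corpus reconstruction loss at init and
    after each epoch) is recorded in ``model.meta['loss_history']``.
    """
    texts = [str(t) for t in texts]
    if not texts:
        raise ValidationError("cannot train a decoder on an empty text corpus")
    tok = build_tokenizer(texts)
    token_lists = [tok.encode(t) for t in texts]
    too_long = [i for i, s in enumerate(token_lists) if len(s) > cfg.max_length]
    if too_long:
        raise TruncationError(
            f"text at row {too_long[0]} has {len(token_lists[too_long[0]])} tokens, "
            f"exceeding max_length={cfg.max_length}; raise max_length instead of "
            f"silently truncating")

    embeddings = np.stack(
        [np.asarray(text_encoder(t), dtype=np.float32) for t in texts])
    d_text = embeddings.shape[1]
    arch = PRESETS[cfg.preset]
    width = arch["width"]
    lm_max_len = cfg.prefix_len + cfg.max_length + 2
    seedseq = np.random.SeedSequence([int(cfg.seed), 7])
    lm_seed, px_seed, shuf_seed = seedseq.generate_state(3) >> np.uint32(1)
    lm = TinyCausalLM(vocab_size=tok.size, width=width,
                      n_layers=arch["n_layers"], n_heads=arch["n_heads"],
                      max_len=lm_max_len, seed=int(lm_seed))
    px_rng = np.random.default_rng(int(px_seed))
    model = DecoderModel(
        tokenizer=tok, lm=lm,
        prefix_w=_uniform_fan_in(px_rng, d_text, (d_text, cfg.prefix_len * width),
                                 np.float32),
        prefix_b=np.zeros(cfg.prefix_len * width, dtype=np.float32),
        d_text=d_text, prefix_len=cfg.prefix_len, max_length=cfg.max_length)

    params = {f"lm.{k}": v for k, v in lm.params.items()}
    params["prefix_w"] = model.prefix_w
    params["prefix_b"] = model.prefix_b
    opt = Adam(params, lr=cfg.resolved_lr, weight_decay=cfg.weight_decay,
               decoupled=True)
    rng = np.random.default_rng(int(shuf_seed))

    n = len(texts)
    P = cfg.prefix_len
    history = [corpus_loss(model, embeddings, token_lists)]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            tokens_in, targets, mask = _batch_arrays(token_lists, idx)
            emb = embeddings[idx]
            prefix = model._prefix(emb)
            x = np.concatenate([prefix, lm.embed_tokens(tokens_in)], axis=1)
            L = x.shape[1]
            full_targets = np.zeros((len(idx), L), dtype=np.int64)
            full_mask = np.zeros((len(idx), L), dtype=np.float64)
            full_targets[:, P:] = targets
            full_mask[:, P:] = mask
            _, grads, dx = lm.loss_and_grad(x, full_targets, full_mask)
            lm.scatter_token_grads(grads, tokens_in, dx[:, P:, :])
            dprefix = dx[:, :P, :].reshape(len(idx), P * lm.width)
            gall = {f"lm.{k}": v for k, v in grads.items()}
            gall["prefix_w"] = emb.T @ dprefix
            gall["prefix_b"] = dprefix.sum(axis=0)
            opt.step(params, gall)
        history.append(corpus_loss(model, embeddings, token_lists))

    model.meta = {
        "optimizer": cfg.optimizer, "lr": cfg.resolved_lr,
        "epochs": cfg.epochs, "batch_size": cfg.batch_size, "seed": cfg.seed,
        "prefix_len": cfg.prefix_len, "preset": cfg.preset,
        "n_texts": n, "loss_history": [float(v) for v in history],
    }
    return model


def generate(model: DecoderModel, embedding, max_length: Optional[int] = None,
             mode: str = "greedy", seed: Optional[int] = None,
             temperature: float = 1.0):
    """Module-level alias for :meth:`DecoderModel.generate`."""
    return model.generate(embedding, max_length=max_length, mode=mode,
                         seed=seed, temperature=temperature)
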