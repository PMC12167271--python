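"""Synthetic paired multimodal corpora with a controllable modality gap.

The generator emulates the statistical structure the adaptation method
assumes: image embeddings form class clusters, and the paired text embeddings
live in a displaced region of the same space.  Concretely, with a
deterministic toy text encoder ``enc`` (unit-norm bag-of-token vectors):

* the text embedding of sample *i* for a task is ``t_i = s * enc(text_i)``,
  where ``s`` is the class-center separation scale;
* the image latent is the sum of the sample's per-task text embeddings
  (for a single-task corpus this is just ``t_i``);
* the image embedding is ``v_i = Q (z_i + eps_i) + c`` with a random
  orthogonal rotation ``Q``, isotropic noise ``eps_i ~ N(0, sigma^2 I)`` and a
  constant offset ``c`` — rotation + offset + noise being the three knobs of
  the modality gap.

Caption texts are deterministic templates of the sample's (phase, triplet)
pair, so the image latent is fully determined by the class assignment up to
the isotropic noise.  Everything is reproducible from the config seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import ortho_group

from .errors import ValidationError
from .io import EmbeddingSet, PairedCorpus, TaskInfo

__all__ = [
    "SynthConfig",
    "ToyTextEncoder",
    "toy_text_encoder",
    "simulate_corpus",
    "make_standard_fixture",
    "make_affine_pairs",
    "FixtureBundle",
    "PHASES",
]

# Closed task vocabularies modeled on laparoscopic cholecystectomy workflow.
PHASES = (
    "preparation",
    "calot triangle dissection",
    "clipping and cutting",
    "gallbladder dissection",
    "gallbladder packaging",
    "cleaning and coagulation",
    "gallbladder retraction",
)
INSTRUMENTS = ("grasper", "hook", "scissors", "clipper", "irrigator", "bipolar")
VERBS = ("retract", "dissect", "clip", "cut", "coagulate")
TARGETS = ("gallbladder", "cystic-duct", "cystic-artery", "liver")

_CAPTION_TEMPLATES = (
    "the {i} is used to {v} the {t}",
    "a surgeon uses the {i} to {v} the {t}",
    "the {i} carefully {v}s the {t}",
    "view of the {i} as it {v}s the {t}",
)
_EXTRA_CAPTIONS = (
    "the operative field is irrigated and cleaned",
    "the gallbladder is placed in a specimen bag",
)


# ---------------------------------------------------------------------------
# Toy text encoder
# ---------------------------------------------------------------------------

class ToyTextEncoder:
    """Deterministic bag-of-tokens text encoder.

    Each canonicalized token hashes to a fixed random unit vector; a text maps
    to the normalized sum of its token vectors times ``scale``.  With the
    default ``scale=1`` every output has unit norm.
    """

    def __init__(self, d_text: int, seed: int = 0, scale: float = 1.0):
        if d_text < 1:
            raise ValidationError("d_text must be >= 1")
        self.d_text = int(d_text)
        self.seed = int(seed)
        self.scale = float(scale)
        self._token_cache: dict = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._token_cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest()
            key = int.from_bytes(digest, "little")
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, key]))
            raw = rng.normal(size=self.d_text)
            vec = raw / np.linalg.norm(raw)
            self._token_cache[token] = vec
        return vec

    def __call__(self, text: str) -> np.ndarray:
        tokens = str(text).strip().lower().split()
        if not tokens:
            raise ValidationError("cannot encode an empty text")
        total = np.zeros(self.d_text)
        for tok in tokens:
            total += self._token_vector(tok)
        norm = np.linalg.norm(total)
        if norm == 0.0:  # pathological cancellation; fall back to first token
            total = self._token_vector(tokens[0])
            norm = 1.0
        return (self.scale * total / norm).astype(np.float32)

    def encode_batch(self, texts) -> np.ndarray:
        return np.stack([self(t) for t in texts]).astype(np.float32)


def toy_text_encoder(text: str, d_text: int, seed: int = 0) -> np.ndarray:
    """Functional form of :class:`ToyTextEncoder` (unit-norm output)."""
    return ToyTextEncoder(d_text=d_text, seed=seed)(text)


# ---------------------------------------------------------------------------
# Config and simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthConfig:
    """Conditions of a simulated corpus; the seed is mandatory."""

    n: int
    d: int
    seed: int
    tasks: tuple = ("phase",)
    k_phases: int = 7
    n_instruments: int = 3
    n_verbs: int = 2
    n_targets: int = 2
    separation: float = 10.0      # class-center scale s
    sigma: float = 0.3            # isotropic noise scale
    offset_norm: float = 5.0      # modality-gap constant offset ||c||
    rotation: bool = True         # random orthogonal rotation Q

    def __post_init__(self):
        if self.n < 1 or self.d < 1:
            raise ValidationError("n and d must be >= 1")
        if self.k_phases < 2:
            raise ValidationError("k_phases must be >= 2")
        if min(self.separation, self.sigma, self.offset_norm) < 0:
            raise ValidationError("scales must be >= 0")
        unknown = set(self.tasks) - {"phase", "triplet", "caption"}
        if unknown:
            raise ValidationError(f"unknown tasks: {sorted(unknown)}")
        if "phase" in self.tasks and self.k_phases > self.n:
            raise ValidationError(
                f"k_phases={self.k_phases} exceeds n={self.n}")

    @property
    def phase_labels(self) -> tuple:
        if self.k_phases <= len(PHASES):
            return PHASES[: self.k_phases]
        extra = tuple(f"phase-{j}" for j in range(len(PHASES), self.k_phases))
        return PHASES + extra

    @property
    def triplet_labels(self) -> tuple:
        return tuple(
            f"{i},{v},{t}"
            for i in INSTRUMENTS[: self.n_instruments]
            for v in VERBS[: self.n_verbs]
            for t in TARGETS[: self.n_targets]
        )

    @property
    def caption_pool(self) -> tuple:
        pool = []
        for trip in self.triplet_labels:
            i, v, t = trip.split(",")
            for tpl in _CAPTION_TEMPLATES:
                pool.append(tpl.format(i=i, v=v, t=t.replace("-", " ")))
        pool.extend(_EXTRA_CAPTIONS)
        return tuple(dict.fromkeys(pool))[:50]


@dataclass
class FixtureBundle:
    """The canonical simulated study: train/test corpora plus ground truth."""

    train: PairedCorpus
    test: PairedCorpus
    truth_train: pd.DataFrame
    truth_test: pd.DataFrame
    encoder: ToyTextEncoder
    config: SynthConfig


def _gap_transform(cfg: SynthConfig):
    """Structural gap parameters (Q, c), deterministic from cfg.seed."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    if cfg.rotation and cfg.d > 1:
        Q = ortho_group.rvs(cfg.d, random_state=rng)
    else:
        Q = np.eye(cfg.d)
    direction = rng.normal(size=cfg.d)
    direction /= np.linalg.norm(direction)
    c = cfg.offset_norm * direction
    return Q, c


def corpus_encoder(cfg: SynthConfig) -> ToyTextEncoder:
    """The text encoder a corpus simulated from ``cfg`` pairs with."""
    return ToyTextEncoder(d_text=cfg.d, seed=cfg.seed, scale=cfg.separation)


def simulate_corpus(cfg: SynthConfig, sample_seed: Optional[int] = None,
                    id_prefix: str = "s"):
    """Simulate a paired corpus; returns ``(PairedCorpus, ground_truth)``.

    Structure (encoder, rotation, offset) depends only on ``cfg.seed`` so
    corpora sharing a config but differing in ``sample_seed`` live in the same
    embedding geometry with fresh samples.
    """
    if sample_seed is None:
        sample_seed = cfg.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(sample_seed), 29]))
    enc = corpus_encoder(cfg)
    Q, c = _gap_transform(cfg)
    n = cfg.n

    phases = cfg.phase_labels
    triplets = cfg.triplet_labels
    captions = cfg.caption_pool

    # Phase assignment balanced to +-1 sample; triplets uniform; captions are
    # a deterministic template of the (phase, triplet) pair.
    phase_idx = np.array([i % len(phases) for i in range(n)])
    rng.shuffle(phase_idx)
    trip_idx = rng.integers(0, len(triplets), size=n)
    cap_idx = (phase_idx * len(triplets) + trip_idx) % len(captions)

    texts = {}
    truth = {"id": [f"{id_prefix}{sample_seed}-{i:05d}" for i in range(n)]}
    if "phase" in cfg.tasks:
        texts["phase"] = tuple(phases[j] for j in phase_idx)
        truth["phase"] = list(texts["phase"])
    if "triplet" in cfg.tasks:
        texts["triplet"] = tuple(triplets[j] for j in trip_idx)
        truth["triplet"] = list(texts["triplet"])
    if "caption" in cfg.tasks:
        texts["caption"] = tuple(captions[j] for j in cap_idx)
        truth["caption"] = list(texts["caption"])
    if not texts:
        raise ValidationError("at least one task must be enabled")

    latent = np.zeros((n, cfg.d))
    for task in texts:
        latent += enc.encode_batch(texts[task]).astype(np.float64)
    noise = rng.normal(0.0, cfg.sigma, size=(n, cfg.d)) if cfg.sigma > 0 else 0.0
    images = (latent + noise) @ Q.T + c
    image_set = EmbeddingSet(ids=tuple(truth["id"]),
                             matrix=images.astype(np.float32),
                             modality="image")

    tasks = {}
    if "phase" in texts:
        tasks["phase"] = TaskInfo(type="classification", label_set=phases)
    if "triplet" in texts:
        tasks["triplet"] = TaskInfo(type="classification", label_set=triplets)
    if "caption" in texts:
        tasks["caption"] = TaskInfo(type="captioning")

    meta = {"encoder": {"d_text": cfg.d, "seed": cfg.seed,
                        "scale": cfg.separation},
            "synth": {"seed": cfg.seed, "sample_seed": int(sample_seed),
                      "sigma": cfg.sigma, "offset_norm": cfg.offset_norm,
                      "rotation": cfg.rotation}}
    corpus = PairedCorpus(image_embeddings=image_set, texts=texts, tasks=tasks,
                          meta=meta)
    return corpus, pd.DataFrame(truth)


def text_embeddings(corpus: PairedCorpus, task: str, encoder) -> EmbeddingSet:
    """Encode a corpus task's texts into a text-modality embedding set."""
    if task not in corpus.texts:
        raise KeyError(f"task {task!r} not in corpus (has {sorted(corpus.texts)})")
    return EmbeddingSet(ids=corpus.ids,
                        matrix=np.stack([encoder(t) for t in corpus.texts[task]]),
                        modality="text")


# ---------------------------------------------------------------------------
# Canonical fixtures
# ---------------------------------------------------------------------------

def make_standard_fixture(seed: int = 0) -> FixtureBundle:
    """The canonical test corpus: 700 train / 300 test samples, d=32,
    7 phases, 12 triplets (3x2x2 vocabularies), 50 templated captions,
    s=10, sigma=0.3, ||c||=5, rotation on."""
    cfg = SynthConfig(n=700, d=32, seed=seed,
                      tasks=("phase", "triplet", "caption"),
                      k_phases=7, n_instruments=3, n_verbs=2, n_targets=2,
                      separation=10.0, sigma=0.3, offset_norm=5.0, rotation=True)
    train, truth_train = simulate_corpus(cfg, sample_seed=cfg.seed * 1000 + 1,
                                         id_prefix="tr")
    test_cfg = SynthConfig(**{**cfg.__dict__, "n": 300})
    test, truth_test = simulate_corpus(test_cfg, sample_seed=cfg.seed * 1000 + 2,
                                       id_prefix="te")
    return FixtureBundle(train=train, test=test, truth_train=truth_train,
                         truth_test=truth_test, encoder=corpus_encoder(cfg),
                         config=cfg)


def make_affine_pairs(n: int, d: int, offset_norm: float = 5.0, seed: int = 0):
    """Exactly affine modality gap: ``t = Q x + c`` with no noise.

    Returns ``(image_rows, text_rows)`` float32; used to probe whether the
    alignment map can recover a noiseless affine transformation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    Q = ortho_group.rvs(d, random_state=rng) if d > 1 else np.eye(1)
    c = rng.normal(size=d)
    c *= offset_norm / np.linalg.norm(c)
    x = rng.normal(size=(n, d))
    t = x @ Q.T + c
    return x.astype(np.float32), t.astype(np.float32)
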