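"""Canonical study runs on the synthetic fixture.

These functions bundle the package's reference experiments — the ones the
test suite asserts on and ``scripts/acceptance.py`` reports — so that both
always execute the exact same computation:

* farthest-point-sampling equivalence against a brute-force greedy oracle;
* k-means anchor coverage of well-separated blobs;
* alignment recovery of a noiseless affine modality gap;
* the anchor-count trend (K=100 vs K=500 vs no-anchor identity baseline) on
  the standard fixture, including end-task phase accuracy and decoder
  reconstruction;
* multi-task parity of a jointly trained decoder versus task-specific ones;
* closed-form metric fixtures (confusion-matrix oracle, BLEU, CIDEr).

Each function takes an explicit seed and returns plain dicts of numbers.
"""

from __future__ import annotations

import numpy as np
from sklearn.datasets import make_blobs

from .align import AlignTrainConfig, AlignmentMap, alignment_mse, fit_alignment
from .anchors import fps_anchors, gather_anchor_pairs, kmeans_anchors
from .decoder import DecoderTrainConfig, train_decoder
from .infer import TaskSpec, multitask_predict, predict
from .metrics import bleu, cider, classification_metrics
from .synth import make_standard_fixture, text_embeddings
from scipy.stats import ortho_group

__all__ = [
    "brute_force_fps",
    "fps_oracle_agreement",
    "kmeans_blob_coverage",
    "affine_gap_data",
    "alignment_recovery",
    "anchor_count_trend",
    "multitask_parity",
    "metric_fixtures",
]


# ---------------------------------------------------------------------------
# Anchor selection probes
# ---------------------------------------------------------------------------

def brute_force_fps(X: np.ndarray, K: int, start: int) -> list:
    """Reference greedy farthest-point sampling, O(n^2 K), lowest-index ties.

    Kept deliberately independent of :func:`ftda.anchors.fps_anchors` (full
    recomputation of every candidate's distance to the selected set at every
    step) so the two can be compared exactly.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    selected = [int(start)]
    for _ in range(K - 1):
        best_idx, best_d = -1, -np.inf
        for cand in range(n):
            if cand in selected:
                continue
            d = min(float(np.linalg.norm(X[cand] - X[s])) for s in selected)
            if d > best_d:
                best_idx, best_d = cand, d
        selected.append(best_idx)
    return selected


def fps_oracle_agreement(n_instances: int = 200, seed: int = 0) -> dict:
    """Fraction of random small instances where FPS matches the oracle exactly."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(2, 13))
        d = int(rng.integers(1, 4))
        K = int(rng.integers(1, n + 1))
        start = int(rng.integers(0, n))
        X = rng.normal(size=(n, d))
        got = list(fps_anchors(X, K, start_index=start).indices)
        want = brute_force_fps(X, K, start)
        agree += got == want
    return {"agreement": agree / n_instances, "n_instances": n_instances}


def kmeans_blob_coverage(n_trials: int = 20, n_blobs: int = 7,
                         seed: int = 0) -> dict:
    """Trials in which K-means anchoring hits every well-separated blob once.

    Blobs are isotropic with unit scale and centers at least 20 sigma apart,
    so a correct anchoring puts exactly one anchor in each blob.
    """
    from scipy.spatial.distance import pdist

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 103]))
    hits = 0
    for _ in range(n_trials):
        t_seed = int(rng.integers(0, 2**31 - 1))
        while True:  # rejection-sample centers at least 20 sigma apart
            centers = rng.uniform(-90, 90, size=(n_blobs, 8))
            if pdist(centers).min() >= 20.0:
                break
        X, labels = make_blobs(n_samples=70 * n_blobs, centers=centers,
                               cluster_std=1.0, random_state=t_seed)
        aset = kmeans_anchors(X, n_blobs, seed=t_seed)
        anchor_blobs = sorted(labels[list(aset.indices)])
        hits += anchor_blobs == list(range(n_blobs))
    return {"covered_trials": hits, "n_trials": n_trials}


# ---------------------------------------------------------------------------
# Alignment recovery
# ---------------------------------------------------------------------------

def affine_gap_data(n: int, d: int, seed: int, sample_key: int,
                    offset_norm: float = 5.0):
    """Pairs ``t = Q x + c`` (noiseless); gap structure depends on seed only."""
    srng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    Q = ortho_group.rvs(d, random_state=srng) if d > 1 else np.eye(1)
    c = srng.normal(size=d)
    c *= offset_norm / np.linalg.norm(c)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 43, sample_key]))
    x = rng.normal(size=(n, d))
    return x.astype(np.float32), (x @ Q.T + c).astype(np.float32)


def alignment_recovery(seeds=(0, 1, 2, 3, 4), d: int = 16, K: int = 200,
                       n_holdout: int = 500, epochs: int = 300) -> dict:
    """Can the alignment net recover a noiseless affine gap?

    Trains on K anchor pairs and evaluates on fresh pairs from the same gap.
    The probe trains to convergence (300 epochs at the standard lr/batch);
    the least-squares affine fit on the same anchors is reported as the
    closed-form reference.
    """
    out = {"seeds": list(seeds), "ratio": [], "ls_mse": [], "mlp_mse": [],
           "pre_mse": []}
    for seed in seeds:
        Xa, Ta = affine_gap_data(K, d, seed, sample_key=0)
        Xh, Th = affine_gap_data(n_holdout, d, seed, sample_key=1)
        amap = fit_alignment(Xa, Ta, AlignTrainConfig(seed=seed, epochs=epochs))
        pre = alignment_mse(Xh, Th)
        post = alignment_mse(amap.transform(Xh), Th)
        A = np.hstack([Xa, np.ones((K, 1), dtype=np.float64)])
        W, *_ = np.linalg.lstsq(A, Ta.astype(np.float64), rcond=None)
        Ah = np.hstack([Xh, np.ones((n_holdout, 1), dtype=np.float64)])
        ls = alignment_mse(Ah @ W, Th)
        out["pre_mse"].append(pre)
        out["mlp_mse"].append(post)
        out["ratio"].append(post / pre)
        out["ls_mse"].append(ls)
    return out


# ---------------------------------------------------------------------------
# Standard-fixture studies
# ---------------------------------------------------------------------------

def _accuracy(preds, refs) -> float:
    return float(np.mean([p.label == r for p, r in zip(preds, refs)]))


def anchor_count_trend(base_seed: int = 0, seeds=(0, 1, 2, 3, 4),
                       k_small: int = 100, k_large: int = 500) -> dict:
    """K=100 vs K=500 vs identity baseline on the standard fixture.

    For each seed: select anchors, fit one alignment map per K, train the
    phase decoder on text embeddings only, and measure held-out alignment MSE
    plus end-task phase accuracy under the encoder swap.  Also records the
    decoder's exact-match reconstruction rate over the 7 phase labels (the
    text-only training check).
    """
    fx = make_standard_fixture(seed=base_seed)
    labels = fx.train.tasks["phase"].label_set
    test_refs = list(fx.test.texts["phase"])
    txt_test = text_embeddings(fx.test, "phase", fx.encoder).matrix
    label_embs = np.stack([fx.encoder(l) for l in labels])

    out = {"seeds": list(seeds), "mse_small": [], "mse_large": [],
           "acc_small": [], "acc_large": [], "acc_identity": [],
           "reconstruction_rate": [], "invalid_rate_large": [],
           "k_small": k_small, "k_large": k_large, "n_test": fx.test.n,
           "mse_identity": alignment_mse(fx.test.image_embeddings.matrix,
                                         txt_test)}
    for seed in seeds:
        model = train_decoder(fx.train.texts["phase"], fx.encoder,
                              DecoderTrainConfig(seed=seed))
        recon = model.generate(label_embs)
        out["reconstruction_rate"].append(
            float(np.mean([r == l for r, l in zip(recon, labels)])))
        accs = {}
        for key, K in (("small", k_small), ("large", k_large)):
            anch = kmeans_anchors(fx.train.image_embeddings, K, seed=seed)
            img, txt = gather_anchor_pairs(fx.train, anch, "phase", fx.encoder)
            amap = fit_alignment(img, txt, AlignTrainConfig(seed=seed))
            out[f"mse_{key}"].append(
                alignment_mse(amap.transform(fx.test.image_embeddings.matrix),
                              txt_test))
            spec = TaskSpec(name="phase", type="classification",
                            label_set=labels, alignment=amap)
            preds = predict(fx.test.image_embeddings, spec, model)
            accs[key] = _accuracy(preds, test_refs)
            if key == "large":
                out["invalid_rate_large"].append(
                    float(np.mean([p.label is None for p in preds])))
        spec_id = TaskSpec(name="phase", type="classification",
                           label_set=labels,
                           alignment=AlignmentMap.identity(fx.config.d))
        preds_id = predict(fx.test.image_embeddings, spec_id, model)
        out["acc_small"].append(accs["small"])
        out["acc_large"].append(accs["large"])
        out["acc_identity"].append(_accuracy(preds_id, test_refs))
    return out


def multitask_parity(base_seed: int = 0, k_anchors: int = 500) -> dict:
    """Joint phase+triplet decoder versus task-specific decoders.

    The joint decoder trains on the concatenated phase and triplet texts;
    routing at inference is purely by each task's alignment map.
    """
    fx = make_standard_fixture(seed=base_seed)
    tasks = ("phase", "triplet")
    anch = kmeans_anchors(fx.train.image_embeddings, k_anchors, seed=base_seed)
    maps = {}
    for task in tasks:
        img, txt = gather_anchor_pairs(fx.train, anch, task, fx.encoder)
        maps[task] = fit_alignment(img, txt, AlignTrainConfig(seed=base_seed))
    specs = [TaskSpec(name=t, type="classification",
                      label_set=fx.train.tasks[t].label_set, alignment=maps[t])
             for t in tasks]

    joint_texts = [t for task in tasks for t in fx.train.texts[task]]
    joint = train_decoder(joint_texts, fx.encoder,
                          DecoderTrainConfig(seed=base_seed))
    joint_preds = multitask_predict(fx.test.image_embeddings, specs, joint)

    out = {"n_test": fx.test.n}
    route_texts = {}
    for spec in specs:
        task = spec.name
        single = train_decoder(fx.train.texts[task], fx.encoder,
                               DecoderTrainConfig(seed=base_seed))
        single_preds = predict(fx.test.image_embeddings, spec, single)
        refs = list(fx.test.texts[task])
        out[f"acc_joint_{task}"] = _accuracy(joint_preds[task], refs)
        out[f"acc_single_{task}"] = _accuracy(single_preds, refs)
        route_texts[task] = [p.text for p in joint_preds[task]]
    out["routing_disagreement"] = float(np.mean(
        [a != b for a, b in zip(route_texts["phase"], route_texts["triplet"])]))
    return out


# ---------------------------------------------------------------------------
# Metric fixtures
# ---------------------------------------------------------------------------

def confusion_matrix_oracle(preds, refs, label_set) -> dict:
    """Brute-force per-class precision/recall/F1 and accuracy."""
    labels = list(label_set)
    per = {}
    for lab in labels:
        tp = sum(1 for p, r in zip(preds, refs) if p == lab and r == lab)
        fp = sum(1 for p, r in zip(preds, refs) if p == lab and r != lab)
        fn = sum(1 for p, r in zip(preds, refs) if p != lab and r == lab)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per[lab] = (prec, rec, f1)
    acc = sum(1 for p, r in zip(preds, refs) if p == r) / len(refs) if refs else 0.0
    return {
        "per_class": per,
        "macro_precision": float(np.mean([v[0] for v in per.values()])),
        "macro_recall": float(np.mean([v[1] for v in per.values()])),
        "macro_f1": float(np.mean([v[2] for v in per.values()])),
        "accuracy": acc,
    }


def metric_fixtures(n_instances: int = 200, seed: int = 0) -> dict:
    """Closed-form metric checks.

    Random classification instances are scored both by the package and by the
    brute-force confusion-matrix oracle; the BLEU worked example has the
    closed form exp(1 - 4/3) (unigram precision 1, brevity penalty for a
    3-token candidate against a 4-token reference); CIDEr of an
    identical candidate/reference corpus with distinct references is exactly
    10.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 107]))
    agree = 0
    for _ in range(n_instances):
        n_classes = int(rng.integers(2, 6))
        labels = [f"c{j}" for j in range(n_classes)]
        n = int(rng.integers(1, 21))
        refs = [labels[j] for j in rng.integers(0, n_classes, size=n)]
        preds = []
        for j in rng.integers(0, n_classes + 1, size=n):
            preds.append(None if j == n_classes else labels[j])
        rep = classification_metrics(preds, refs, labels)
        oracle = confusion_matrix_oracle(
            ["<invalid>" if p is None else p for p in preds], refs, labels)
        ok = all(
            abs(getattr(rep, key) - oracle[key]) < 1e-12
            for key in ("macro_precision", "macro_recall", "macro_f1", "accuracy"))
        agree += ok
    bleu1 = bleu(["the cat sat"], ["the cat sat down"], max_n=1)
    refs = ["the grasper retracts the gallbladder",
            "the hook dissects the cystic duct",
            "the clipper clips the cystic artery"]
    cider_identity = cider(list(refs), refs)
    return {
        "classification_agreement": agree / n_instances,
        "n_instances": n_instances,
        "bleu1_worked_example": bleu1,
        "bleu1_closed_form": float(np.exp(1.0 - 4.0 / 3.0)),
        "cider_identity": cider_identity,
    }
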