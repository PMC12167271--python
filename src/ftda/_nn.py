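"""Minimal seeded neural-network core used by the alignment map and the decoder.

Everything here is plain numpy with hand-derived reverse-mode gradients:

* :class:`MLP` — feed-forward rectifier network (the modality-alignment map).
* :class:`TinyCausalLM` — a small pre-layer-norm causal transformer language
  model with learned positional embeddings, used as the from-scratch text
  decoder backbone.
* :class:`Adam` — Adam / AdamW (decoupled weight decay) on flat parameter
  dicts.

Parameters are stored as ``dict[str, np.ndarray]`` in float32 by default so
that serialized artifacts reproduce outputs bit-for-bit after a save/load
round trip.  Gradient correctness is asserted against central finite
differences in the test suite (in float64, where the comparison is sharp).
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "TinyCausalLM", "Adam"]

_NEG = -1e9  # additive causal-mask value; large but finite to stay NaN-safe in f32


def _uniform_fan_in(rng: np.random.Generator, fan_in: int, shape, dtype):
    k = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-k, k, size=shape).astype(dtype)


class Adam:
    """Adam optimizer over a parameter dict; ``decoupled=True`` gives AdamW."""

    def __init__(self, params, lr, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0, decoupled=False):
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for key, p in params.items():
            g = grads[key]
            if self.weight_decay and not self.decoupled:
                g = g + self.weight_decay * p
            m = self.m[key]
            v = self.v[key]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            if self.weight_decay and self.decoupled:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Feed-forward network
# ---------------------------------------------------------------------------

class MLP:
    """Feed-forward network with rectifier hidden layers and linear output."""

    def __init__(self, d_in, d_out, hidden=(128, 128), seed=0, dtype=np.float32):
        self.d_in = int(d_in)
        self.d_out = int(d_out)
        self.hidden = tuple(int(h) for h in hidden)
        self.dtype = dtype
        sizes = [self.d_in, *self.hidden, self.d_out]
        rng = np.random.default_rng(seed)
        self.params = {}
        for i in range(len(sizes) - 1):
            self.params[f"w{i}"] = _uniform_fan_in(rng, sizes[i], (sizes[i], sizes[i + 1]), dtype)
            self.params[f"b{i}"] = _uniform_fan_in(rng, sizes[i], (sizes[i + 1],), dtype)
        self.n_layers = len(sizes) - 1

    def forward(self, x):
        """Return (output, cache) for a (n, d_in) batch."""
        x = np.asarray(x, dtype=self.dtype)
        acts = [x]
        pre = []
        h = x
        for i in range(self.n_layers):
            z = h @ self.params[f"w{i}"] + self.params[f"b{i}"]
            pre.append(z)
            h = np.maximum(z, 0.0) if i < self.n_layers - 1 else z
            acts.append(h)
        return h, (acts, pre)

    def __call__(self, x):
        return self.forward(x)[0]

    def backward(self, cache, dy):
        """Gradients of a scalar loss wrt all parameters given d(loss)/d(output)."""
        acts, pre = cache
        grads = {}
        d = np.asarray(dy, dtype=self.dtype)
        for i in reversed(range(self.n_layers)):
            if i < self.n_layers - 1:
                d = d * (pre[i] > 0)
            grads[f"w{i}"] = acts[i].T @ d
            grads[f"b{i}"] = d.sum(axis=0)
            if i > 0:
                d = d @ self.params[f"w{i}"].T
        return grads


# ---------------------------------------------------------------------------
# Tiny causal transformer LM
# ---------------------------------------------------------------------------

def _layernorm(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv)


def _layernorm_backward(dy, cache, g):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class TinyCausalLM:
    """Small causal transformer: learned positions, pre-LN blocks, untied head.

    The model consumes a sequence of continuous input vectors (prefix vectors
    followed by token embeddings looked up from its own vocabulary table) and
    produces next-token logits at every position.
    """

    def __init__(self, vocab_size, width=128, n_layers=2, n_heads=4,
                 max_len=64, seed=0, dtype=np.float32):
        if width % n_heads != 0:
            raise ValueError(f"width {width} not divisible by n_heads {n_heads}")
        self.vocab_size = int(vocab_size)
        self.width = int(width)
        self.n_layers = int(n_layers)
        self.n_heads = int(n_heads)
        self.max_len = int(max_len)
        self.dtype = dtype
        self.head_dim = self.width // self.n_heads
        rng = np.random.default_rng(seed)
        W, V = self.width, self.vocab_size
        p = {
            "wte": (rng.normal(0.0, 0.02, (V, W))).astype(dtype),
            "wpe": (rng.normal(0.0, 0.02, (self.max_len, W))).astype(dtype),
            "lnf_g": np.ones(W, dtype=dtype),
            "lnf_b": np.zeros(W, dtype=dtype),
            "head_w": _uniform_fan_in(rng, W, (W, V), dtype),
            "head_b": np.zeros(V, dtype=dtype),
        }
        for i in range(self.n_layers):
            p[f"l{i}_ln1_g"] = np.ones(W, dtype=dtype)
            p[f"l{i}_ln1_b"] = np.zeros(W, dtype=dtype)
            p[f"l{i}_wqkv"] = _uniform_fan_in(rng, W, (W, 3 * W), dtype)
            p[f"l{i}_bqkv"] = np.zeros(3 * W, dtype=dtype)
            p[f"l{i}_wo"] = _uniform_fan_in(rng, W, (W, W), dtype)
            p[f"l{i}_bo"] = np.zeros(W, dtype=dtype)
            p[f"l{i}_ln2_g"] = np.ones(W, dtype=dtype)
            p[f"l{i}_ln2_b"] = np.zeros(W, dtype=dtype)
            p[f"l{i}_w1"] = _uniform_fan_in(rng, W, (W, 4 * W), dtype)
            p[f"l{i}_b1"] = np.zeros(4 * W, dtype=dtype)
            p[f"l{i}_w2"] = _uniform_fan_in(rng, 4 * W, (4 * W, W), dtype)
            p[f"l{i}_b2"] = np.zeros(W, dtype=dtype)
        self.params = p

    # -- forward -----------------------------------------------------------

    def _split_heads(self, x):
        B, L, W = x.shape
        return x.reshape(B, L, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def _merge_heads(self, x):
        B, H, L, hd = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, H * hd)

    def forward(self, x, want_cache=False):
        """``x``: (B, L, W) input embeddings (positions are added here)."""
        p = self.params
        B, L, W = x.shape
        if L > self.max_len:
            raise ValueError(f"sequence length {L} exceeds max_len {self.max_len}")
        scale = 1.0 / np.sqrt(self.head_dim)
        mask = np.triu(np.full((L, L), _NEG, dtype=self.dtype), k=1)
        h = x + p["wpe"][:L]
        caches = []
        for i in range(self.n_layers):
            a1, c1 = _layernorm(h, p[f"l{i}_ln1_g"], p[f"l{i}_ln1_b"])
            qkv = a1 @ p[f"l{i}_wqkv"] + p[f"l{i}_bqkv"]
            q, k, v = (self._split_heads(t) for t in np.split(qkv, 3, axis=-1))
            s = (q @ k.swapaxes(-1, -2)) * scale + mask
            att = _softmax(s)
            o = self._merge_heads(att @ v)
            att_out = o @ p[f"l{i}_wo"] + p[f"l{i}_bo"]
            h_mid = h + att_out
            a2, c2 = _layernorm(h_mid, p[f"l{i}_ln2_g"], p[f"l{i}_ln2_b"])
            u = a2 @ p[f"l{i}_w1"] + p[f"l{i}_b1"]
            r = np.maximum(u, 0.0)
            h = h_mid + r @ p[f"l{i}_w2"] + p[f"l{i}_b2"]
            if want_cache:
                caches.append((h_mid - att_out, a1, c1, q, k, v, att, o, h_mid, a2, c2, u, r))
        hf, cf = _layernorm(h, p["lnf_g"], p["lnf_b"])
        logits = hf @ p["head_w"] + p["head_b"]
        cache = (caches, hf, cf) if want_cache else None
        return logits, cache

    def loss_and_grad(self, x, targets, target_mask):
        """Cross-entropy loss and gradients.

        ``targets``/``target_mask``: (B, L) integer targets and 0/1 mask over
        positions that carry a prediction.  The loss is the mean over batch
        rows of the *summed* token cross-entropy (the reconstruction loss is a
        sum over the tokens of each target text).  Returns
        ``(loss, grads, dx)`` where ``dx`` is the gradient wrt the input
        embeddings (used by the prefix mapper and the embedding table).
        """
        p = self.params
        B, L, W = x.shape
        logits, cache = self.forward(x, want_cache=True)
        caches, hf, cf = cache
        probs = _softmax(logits.astype(np.float64))
        rows = np.arange(B)[:, None], np.arange(L)[None, :]
        tgt = np.clip(targets, 0, self.vocab_size - 1)
        nll = -np.log(np.maximum(probs[rows[0], rows[1], tgt], 1e-30))
        loss = float((nll * target_mask).sum() / B)

        dlogits = probs
        onehot_idx = (rows[0], rows[1], tgt)
        dlogits[onehot_idx] -= 1.0
        dlogits *= (target_mask / B)[..., None]
        dlogits = dlogits.astype(self.dtype)

        grads = {}
        flat_hf = hf.reshape(-1, W)
        flat_dl = dlogits.reshape(-1, self.vocab_size)
        grads["head_w"] = flat_hf.T @ flat_dl
        grads["head_b"] = flat_dl.sum(axis=0)
        dhf = dlogits @ p["head_w"].T
        dh, grads["lnf_g"], grads["lnf_b"] = _layernorm_backward(dhf, cf, p["lnf_g"])

        scale = 1.0 / np.sqrt(self.head_dim)
        for i in reversed(range(self.n_layers)):
            (h_in, a1, c1, q, k, v, att, o, h_mid, a2, c2, u, r) = caches[i]
            # feed-forward sub-block
            dm = dh  # gradient at block output; residual adds dh to h_mid too
            flat_r = r.reshape(-1, 4 * W)
            flat_dm = dm.reshape(-1, W)
            grads[f"l{i}_w2"] = flat_r.T @ flat_dm
            grads[f"l{i}_b2"] = flat_dm.sum(axis=0)
            dr = dm @ p[f"l{i}_w2"].T
            du = dr * (u > 0)
            flat_a2 = a2.reshape(-1, W)
            flat_du = du.reshape(-1, 4 * W)
            grads[f"l{i}_w1"] = flat_a2.T @ flat_du
            grads[f"l{i}_b1"] = flat_du.sum(axis=0)
            da2 = du @ p[f"l{i}_w1"].T
            dh_mid_ln, grads[f"l{i}_ln2_g"], grads[f"l{i}_ln2_b"] = \
                _layernorm_backward(da2, c2, p[f"l{i}_ln2_g"])
            dh_mid = dh + dh_mid_ln
            # attention sub-block
            datt_out = dh_mid
            flat_o = o.reshape(-1, W)
            flat_dao = datt_out.reshape(-1, W)
            grads[f"l{i}_wo"] = flat_o.T @ flat_dao
            grads[f"l{i}_bo"] = flat_dao.sum(axis=0)
            do = self._split_heads(datt_out @ p[f"l{i}_wo"].T)
            datt = do @ v.swapaxes(-1, -2)
            dv = att.swapaxes(-1, -2) @ do
            ds = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
            dq = (ds @ k) * scale
            dk = (ds.swapaxes(-1, -2) @ q) * scale
            dqkv = np.concatenate(
                [self._merge_heads(t) for t in (dq, dk, dv)], axis=-1)
            flat_a1 = a1.reshape(-1, W)
            flat_dqkv = dqkv.reshape(-1, 3 * W)
            grads[f"l{i}_wqkv"] = flat_a1.T @ flat_dqkv
            grads[f"l{i}_bqkv"] = flat_dqkv.sum(axis=0)
            da1 = dqkv @ p[f"l{i}_wqkv"].T
            dh_in_ln, grads[f"l{i}_ln1_g"], grads[f"l{i}_ln1_b"] = \
                _layernorm_backward(da1, c1, p[f"l{i}_ln1_g"])
            dh = dh_mid + dh_in_ln

        grads["wpe"] = np.zeros_like(p["wpe"])
        grads["wpe"][:L] = dh.sum(axis=0)
        grads["wte"] = np.zeros_like(p["wte"])  # caller scatters token grads
        return loss, grads, dh

    def embed_tokens(self, token_ids):
        return self.params["wte"][token_ids]

    def scatter_token_grads(self, grads, token_ids, dx_tokens):
        """Accumulate input-embedding gradients into the vocabulary table."""
        np.add.at(grads["wte"], token_ids.reshape(-1),
                  dx_tokens.reshape(-1, self.width))
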