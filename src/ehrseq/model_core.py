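"""Encoder network for longitudinal visit sequences.

Each input position is the elementwise sum of three dense embeddings — a
code embedding, a code-type embedding (principal / auxiliary / external
cause / procedure / demographic / special), and a temporal-bucket embedding
(seven days-before-index buckets plus a padding bucket). The summed
representations pass through a stack of bidirectional multi-head
self-attention blocks (post-layer-norm, GELU feed-forward), and a pooler
(dense + tanh on the CLS position) summarises the trajectory.

Three heads sit on top:

* a masked-feature decoder over the code vocabulary at selected positions,
* a next-visit diagnosis-category classifier on the pooled vector,
* a binary risk head (dense + sigmoid) on the pooled vector.

The whole network is implemented in numpy with explicit forward caches and
hand-written backward passes, which keeps the CPU desk-scale configuration
(d_model 64, 2 layers) fast, fully deterministic, and differentiable with
respect to the summed input embeddings — the quantity integrated-gradients
attribution needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf, expit

__all__ = [
    "ModelConfig",
    "init_params",
    "embed_features",
    "encoder_forward",
    "encoder_backward",
    "encode",
    "head_mlm",
    "head_next_category",
    "head_binary",
    "count_parameters",
]

DTYPE = np.float64
_LN_EPS = 1e-5
_NEG_INF = -1e9


@dataclass
class ModelConfig:
    """Hyperparameters of the encoder.

    The production-scale configuration in the reference study used
    780-dimensional embeddings (~27M parameters); the desk default
    (d_model=64, 2 layers, 4 heads) trains in minutes on one CPU and is the
    configuration exercised by the test suite.
    """

    vocab_size: int
    n_types: int = 6
    n_time_buckets: int = 8  # seven real buckets + one padding bucket
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 128
    dropout: float = 0.0
    max_len: int = 512
    n_next_categories: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.n_time_buckets < 8:
            raise ValueError("need 7 temporal buckets plus a padding bucket")


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    x = rng.standard_normal(shape) * std
    return np.clip(x, -2 * std, 2 * std).astype(DTYPE)


def init_params(cfg: ModelConfig) -> dict[str, np.ndarray]:
    """Seeded parameter initialisation (truncated normal, sigma=0.02)."""
    rng = np.random.default_rng(cfg.seed)
    d, f = cfg.d_model, cfg.d_ff
    p: dict[str, np.ndarray] = {}
    p["emb_code"] = _trunc_normal(rng, (cfg.vocab_size, d))
    p["emb_type"] = _trunc_normal(rng, (cfg.n_types, d))
    p["emb_time"] = _trunc_normal(rng, (cfg.n_time_buckets, d))
    p["emb_ln_g"] = np.ones(d, dtype=DTYPE)
    p["emb_ln_b"] = np.zeros(d, dtype=DTYPE)
    for layer in range(cfg.n_layers):
        pre = f"l{layer}_"
        for w in ("q", "k", "v", "o"):
            p[pre + f"W{w}"] = _trunc_normal(rng, (d, d))
            p[pre + f"b{w}"] = np.zeros(d, dtype=DTYPE)
        p[pre + "ln1_g"] = np.ones(d, dtype=DTYPE)
        p[pre + "ln1_b"] = np.zeros(d, dtype=DTYPE)
        p[pre + "W1"] = _trunc_normal(rng, (d, f))
        p[pre + "b1"] = np.zeros(f, dtype=DTYPE)
        p[pre + "W2"] = _trunc_normal(rng, (f, d))
        p[pre + "b2"] = np.zeros(d, dtype=DTYPE)
        p[pre + "ln2_g"] = np.ones(d, dtype=DTYPE)
        p[pre + "ln2_b"] = np.zeros(d, dtype=DTYPE)
    p["pool_W"] = _trunc_normal(rng, (d, d))
    p["pool_b"] = np.zeros(d, dtype=DTYPE)
    p["mlm_W"] = _trunc_normal(rng, (d, cfg.vocab_size))
    p["mlm_b"] = np.zeros(cfg.vocab_size, dtype=DTYPE)
    p["next_W"] = _trunc_normal(rng, (d, cfg.n_next_categories))
    p["next_b"] = np.zeros(cfg.n_next_categories, dtype=DTYPE)
    p["bin_w"] = _trunc_normal(rng, (d,))
    p["bin_b"] = np.zeros((), dtype=DTYPE)
    return p


def count_parameters(params: dict[str, np.ndarray], prefixes=None) -> int:
    """Exact count of trainable scalars, optionally restricted by name prefix."""
    items = params.items()
    if prefixes is not None:
        items = [(k, v) for k, v in items if any(k.startswith(p) for p in prefixes)]
    return int(sum(v.size for _, v in items))


# ---------------------------------------------------------------------------
# primitive forward/backward pairs
# ---------------------------------------------------------------------------


def _layer_norm(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    inv = 1.0 / np.sqrt((xc * xc).mean(-1, keepdims=True) + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layer_norm_backward(dy, cache):
    xhat, inv, g = cache
    axes = tuple(range(dy.ndim - 1))
    dg = (dy * xhat).sum(axis=axes)
    db = dy.sum(axis=axes)
    dxh = dy * g
    dx = inv * (
        dxh
        - dxh.mean(-1, keepdims=True)
        - xhat * (dxh * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def _gelu_grad(x):
    return 0.5 * (1.0 + erf(x / np.sqrt(2.0))) + x * np.exp(-0.5 * x * x) / np.sqrt(
        2.0 * np.pi
    )


def _softmax(x):
    z = x - x.max(-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(-1, keepdims=True)


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------


def embed_features(params, code_ids, type_ids, time_ids) -> np.ndarray:
    """Summed three-embedding input representation (batch, L, d_model)."""
    for ids, table in (
        (code_ids, "emb_code"),
        (type_ids, "emb_type"),
        (time_ids, "emb_time"),
    ):
        if np.any(ids < 0) or np.any(ids >= params[table].shape[0]):
            raise IndexError(f"id out of range for {table}")
    return (
        params["emb_code"][code_ids]
        + params["emb_type"][type_ids]
        + params["emb_time"][time_ids]
    )


def encoder_forward(params, cfg: ModelConfig, x0, attn_mask):
    """Run the attention stack on summed embeddings ``x0``.

    Returns (hidden, pooled, cache). Padded key positions are excluded from
    every attention distribution, so outputs at real positions are invariant
    to the content of padding.
    """
    B, L, d = x0.shape
    H = cfg.n_heads
    dh = d // H
    scale = 1.0 / np.sqrt(dh)
    key_bias = np.where(attn_mask[:, None, None, :] > 0, 0.0, _NEG_INF)

    cache: dict = {"x0": x0, "mask": attn_mask, "layers": []}
    h, ln_cache = _layer_norm(x0, params["emb_ln_g"], params["emb_ln_b"])
    cache["emb_ln"] = ln_cache
    for layer in range(cfg.n_layers):
        pre = f"l{layer}_"
        q = h @ params[pre + "Wq"] + params[pre + "bq"]
        k = h @ params[pre + "Wk"] + params[pre + "bk"]
        v = h @ params[pre + "Wv"] + params[pre + "bv"]
        qh = q.reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        kh = k.reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        vh = v.reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        scores = np.matmul(qh, kh.transpose(0, 1, 3, 2)) * scale + key_bias
        attn = _softmax(scores)
        ctx = np.matmul(attn, vh)  # (B,H,L,dh)
        ctx_flat = ctx.transpose(0, 2, 1, 3).reshape(B, L, d)
        attn_out = ctx_flat @ params[pre + "Wo"] + params[pre + "bo"]
        x1, ln1_cache = _layer_norm(
            h + attn_out, params[pre + "ln1_g"], params[pre + "ln1_b"]
        )
        ff_pre = x1 @ params[pre + "W1"] + params[pre + "b1"]
        ff_act = _gelu(ff_pre)
        ff_out = ff_act @ params[pre + "W2"] + params[pre + "b2"]
        h_new, ln2_cache = _layer_norm(
            x1 + ff_out, params[pre + "ln2_g"], params[pre + "ln2_b"]
        )
        cache["layers"].append(
            dict(
                h_in=h,
                qh=qh,
                kh=kh,
                vh=vh,
                attn=attn,
                ctx_flat=ctx_flat,
                ln1=ln1_cache,
                x1=x1,
                ff_pre=ff_pre,
                ff_act=ff_act,
                ln2=ln2_cache,
            )
        )
        h = h_new
    z = h[:, 0] @ params["pool_W"] + params["pool_b"]
    pooled = np.tanh(z)
    cache["hidden"] = h
    cache["pooled"] = pooled
    return h, pooled, cache


def encoder_backward(params, cfg: ModelConfig, cache, d_hidden, d_pooled):
    """Backpropagate gradients at (hidden, pooled) to parameters and x0."""
    B, L, d = cache["x0"].shape
    H = cfg.n_heads
    dh = d // H
    scale = 1.0 / np.sqrt(dh)
    grads: dict[str, np.ndarray] = {}

    dhid = np.array(d_hidden, dtype=DTYPE, copy=True)
    if d_pooled is not None:
        pooled = cache["pooled"]
        dz = d_pooled * (1.0 - pooled * pooled)
        grads["pool_W"] = cache["hidden"][:, 0].T @ dz
        grads["pool_b"] = dz.sum(axis=0)
        dhid[:, 0] += dz @ params["pool_W"].T
    else:
        grads["pool_W"] = np.zeros_like(params["pool_W"])
        grads["pool_b"] = np.zeros_like(params["pool_b"])

    for layer in range(cfg.n_layers - 1, -1, -1):
        pre = f"l{layer}_"
        c = cache["layers"][layer]
        dsum2, dg2, db2 = _layer_norm_backward(dhid, c["ln2"])
        grads[pre + "ln2_g"], grads[pre + "ln2_b"] = dg2, db2
        dx1 = dsum2.copy()
        dff_out = dsum2
        grads[pre + "W2"] = np.tensordot(c["ff_act"], dff_out, axes=([0, 1], [0, 1]))
        grads[pre + "b2"] = dff_out.sum(axis=(0, 1))
        dff_act = dff_out @ params[pre + "W2"].T
        dff_pre = dff_act * _gelu_grad(c["ff_pre"])
        grads[pre + "W1"] = np.tensordot(c["x1"], dff_pre, axes=([0, 1], [0, 1]))
        grads[pre + "b1"] = dff_pre.sum(axis=(0, 1))
        dx1 += dff_pre @ params[pre + "W1"].T
        dsum1, dg1, db1 = _layer_norm_backward(dx1, c["ln1"])
        grads[pre + "ln1_g"], grads[pre + "ln1_b"] = dg1, db1
        dh_res = dsum1.copy()
        dattn_out = dsum1
        grads[pre + "Wo"] = np.tensordot(
            c["ctx_flat"], dattn_out, axes=([0, 1], [0, 1])
        )
        grads[pre + "bo"] = dattn_out.sum(axis=(0, 1))
        dctx_flat = dattn_out @ params[pre + "Wo"].T
        dctx = dctx_flat.reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        dattn = np.matmul(dctx, c["vh"].transpose(0, 1, 3, 2))
        dvh = np.matmul(c["attn"].transpose(0, 1, 3, 2), dctx)
        a = c["attn"]
        dscores = a * (dattn - (dattn * a).sum(-1, keepdims=True))
        dqh = np.matmul(dscores, c["kh"]) * scale
        dkh = np.matmul(dscores.transpose(0, 1, 3, 2), c["qh"]) * scale
        dq = dqh.transpose(0, 2, 1, 3).reshape(B, L, d)
        dk = dkh.transpose(0, 2, 1, 3).reshape(B, L, d)
        dv = dvh.transpose(0, 2, 1, 3).reshape(B, L, d)
        h_in = c["h_in"]
        for name, dmat in (("q", dq), ("k", dk), ("v", dv)):
            grads[pre + f"W{name}"] = np.tensordot(h_in, dmat, axes=([0, 1], [0, 1]))
            grads[pre + f"b{name}"] = dmat.sum(axis=(0, 1))
        dh_res += dq @ params[pre + "Wq"].T
        dh_res += dk @ params[pre + "Wk"].T
        dh_res += dv @ params[pre + "Wv"].T
        dhid = dh_res

    dx0, dge, dbe = _layer_norm_backward(dhid, cache["emb_ln"])
    grads["emb_ln_g"], grads["emb_ln_b"] = dge, dbe
    return dx0, grads


def encode(params, cfg: ModelConfig, code_ids, type_ids, time_ids, attn_mask):
    """Embed then encode a batch; returns (hidden, pooled, cache)."""
    x0 = embed_features(params, code_ids, type_ids, time_ids)
    return encoder_forward(params, cfg, x0, attn_mask)


# ---------------------------------------------------------------------------
# heads
# ---------------------------------------------------------------------------


def head_mlm(hidden_at_positions, params):
    """Linear decoder over the code vocabulary at selected positions."""
    return hidden_at_positions @ params["mlm_W"] + params["mlm_b"]


def head_next_category(pooled, params):
    """Feed-forward scores over next-visit diagnosis categories."""
    return pooled @ params["next_W"] + params["next_b"]


def head_binary(pooled, params):
    """Scalar outcome probability via dense layer + logistic function."""
    return expit(pooled @ params["bin_w"] + params["bin_b"])
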