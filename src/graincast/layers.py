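"""Building blocks of the forecaster, as pure functions over explicit params.

All functions run on numpy arrays and autodiff tensors alike (see
:mod:`graincast.autodiff`), so the exact code path that is trained is
also the one used for inference and checked against loop oracles.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .exceptions import ConfigError, ShapeError

__all__ = [
    "embed_series",
    "scaled_dot_attention",
    "layer_norm",
    "ffn",
    "dynamic_gate",
    "forecast_head",
]


def embed_series(window, w_embed, b_embed):
    """Variable-token embedding: one token per variable.

    ``window`` is (..., T, N) — each variable's full length-T series is
    mapped by the shared linear map ``w_embed`` (T, D) to a width-D token,
    giving (..., N, D). Sharing the map across variables makes the
    embedding permutation-equivariant in the variables.
    """
    if window.shape[-2] != w_embed.shape[0]:
        raise ShapeError(
            f"window has T={window.shape[-2]} steps but the embedding "
            f"expects {w_embed.shape[0]}"
        )
    tokens = window.swapaxes(-1, -2)  # (..., N, T)
    return ad.matmul(tokens, w_embed) + b_embed


def scaled_dot_attention(h, w_q, w_k, w_v, n_heads: int = 1):
    """Multi-head self-attention ``softmax(Q K^T / sqrt(d_k)) V`` over tokens.

    ``h`` is (..., N, D); Q/K/V are linear projections of ``h``; heads
    split D into n_heads slices and their outputs are concatenated back,
    exactly the printed attention map (no extra output projection).
    """
    *lead, n_tok, d = h.shape
    if d % n_heads:
        raise ConfigError(f"width {d} not divisible by {n_heads} heads")
    dh = d // n_heads

    def split_heads(x):
        return x.reshape(*lead, n_tok, n_heads, dh).swapaxes(-3, -2)

    q = split_heads(ad.matmul(h, w_q))
    k = split_heads(ad.matmul(h, w_k))
    v = split_heads(ad.matmul(h, w_v))
    scores = ad.matmul(q, k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
    att = ad.softmax(scores, axis=-1)
    out = ad.matmul(att, v)  # (..., heads, N, dh)
    return out.swapaxes(-3, -2).reshape(*lead, n_tok, d)


def layer_norm(x, gamma, beta, eps: float = 1e-5):
    """Normalize the last axis to zero mean / unit variance, then affine."""
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / ((var + eps) ** 0.5) * gamma + beta


def ffn(h, w1, b1, w2, b2):
    """Position-wise feed-forward map ``max(0, h W1 + b1) W2 + b2``."""
    return ad.matmul(ad.relu(ad.matmul(h, w1) + b1), w2) + b2


def dynamic_gate(h, s, w_gamma, b_gamma, concat_input: bool = False):
    """Gated fusion of the attention branch ``h`` and the graph branch ``s``.

    ``gamma = sigmoid(W_gamma (h + s) + b_gamma)`` (elementwise addition of
    the branches; set ``concat_input`` to gate on their concatenation
    instead, with a correspondingly wider ``w_gamma``), then
    ``k = gamma * h + (1 - gamma) * s`` — an elementwise convex
    combination, so saturating the gate recovers either branch exactly.
    Returns ``(gamma, k)``.
    """
    if h.shape != s.shape:
        raise ShapeError(f"branch shapes differ: {h.shape} vs {s.shape}")
    gate_in = ad.concat([h, s], axis=-1) if concat_input else h + s
    gamma = ad.sigmoid(ad.matmul(gate_in, w_gamma) + b_gamma)
    return gamma, gamma * h + (1.0 - gamma) * s


def forecast_head(k, w_head, b_head):
    """Per-variable linear map D -> horizon; output (..., horizon, N)."""
    return (ad.matmul(k, w_head) + b_head).swapaxes(-1, -2)
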