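"""Minimal NumPy neural-network internals for the synergy regressor.

Implements exactly the pieces the model needs — linear layers, layer norm,
multi-head self-attention over a 3-token sequence, inverted dropout, ReLU,
and Adam — with hand-written backward passes. Single-threaded and fully
deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

_LN_EPS = 1e-5


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


# ---------------------------------------------------------------------------
# layer primitives: each forward returns (output, cache); backward consumes it
# ---------------------------------------------------------------------------

def linear_fwd(x, W, b):
    return x @ W + b, (x, W)


def linear_bwd(dy, cache):
    x, W = cache
    dW = np.tensordot(x, dy, axes=(tuple(range(x.ndim - 1)),) * 2)
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dx = dy @ W.T
    return dx, dW, db


def relu_fwd(x):
    return np.maximum(x, 0.0), (x > 0.0)


def relu_bwd(dy, mask):
    return dy * mask


def dropout_fwd(x, rate: float, train: bool, rng: np.random.Generator | None):
    if not train or rate == 0.0:
        return x, None
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * keep, keep


def dropout_bwd(dy, keep):
    return dy if keep is None else dy * keep


def layernorm_fwd(x, gamma, beta):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return gamma * xhat + beta, (xhat, inv, gamma)


def layernorm_bwd(dy, cache):
    xhat, inv, gamma = cache
    dgamma = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    dbeta = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * gamma
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dgamma, dbeta


def _split_heads(x, n_heads):
    b, t, d = x.shape
    return x.reshape(b, t, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x):
    b, h, t, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, t, h * dh)


def attention_fwd(x, p, prefix, n_heads):
    """Multi-head self-attention; p is the parameter dict, prefix names the block."""
    q, cq = linear_fwd(x, p[f"{prefix}.Wq"], p[f"{prefix}.bq"])
    k, ck = linear_fwd(x, p[f"{prefix}.Wk"], p[f"{prefix}.bk"])
    v, cv = linear_fwd(x, p[f"{prefix}.Wv"], p[f"{prefix}.bv"])
    qh, kh, vh = (_split_heads(z, n_heads) for z in (q, k, v))
    scale = 1.0 / np.sqrt(qh.shape[-1])
    scores = (qh @ kh.transpose(0, 1, 3, 2)) * scale
    scores -= scores.max(axis=-1, keepdims=True)
    attn = np.exp(scores)
    attn /= attn.sum(axis=-1, keepdims=True)
    ctx = _merge_heads(attn @ vh)
    out, co = linear_fwd(ctx, p[f"{prefix}.Wo"], p[f"{prefix}.bo"])
    return out, (cq, ck, cv, co, qh, kh, vh, attn, scale, n_heads)


def attention_bwd(dy, cache, grads, prefix):
    cq, ck, cv, co, qh, kh, vh, attn, scale, n_heads = cache
    dctx, dWo, dbo = linear_bwd(dy, co)
    grads[f"{prefix}.Wo"] += dWo
    grads[f"{prefix}.bo"] += dbo
    dctx_h = _split_heads(dctx, n_heads)
    dattn = dctx_h @ vh.transpose(0, 1, 3, 2)
    dvh = attn.transpose(0, 1, 3, 2) @ dctx_h
    # softmax backward (rows of attn sum to 1)
    dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
    dscores *= scale
    dqh = dscores @ kh
    dkh = dscores.transpose(0, 1, 3, 2) @ qh
    dx = np.zeros_like(cq[0])
    for dzh, c, wkey, bkey in (
        (dqh, cq, "Wq", "bq"),
        (dkh, ck, "Wk", "bk"),
        (dvh, cv, "Wv", "bv"),
    ):
        dz, dW, db = linear_bwd(_merge_heads(dzh), c)
        grads[f"{prefix}.{wkey}"] += dW
        grads[f"{prefix}.{bkey}"] += db
        dx += dz
    return dx


class Adam:
    """Standard Adam with canonical betas/eps, operating on a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
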