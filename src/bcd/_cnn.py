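"""Minimal NumPy implementation of the spectrogram CNN.

Architecture (in order): 3×3 convolution with 24 kernels + ReLU, batch
normalization, 3×3 convolution with 48 kernels + ReLU, 2×2 max pooling
(stride 1), batch normalization, flatten, fully connected 64 + ReLU,
dropout, fully connected 2 (class logits). Training uses Adam on a softmax
cross-entropy loss. Forward and backward passes are written with
im2col-style vectorization; sizes here are small (tens of frequency rows,
tens of time bins) so plain NumPy is adequate.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-5


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def init_params(
    rng: np.random.Generator,
    in_shape: tuple[int, int],
    k1: int = 24,
    k2: int = 48,
    ksize: int = 3,
    pool: int = 2,
    pool_stride: int = 1,
    hidden: int = 64,
    n_classes: int = 2,
) -> dict:
    h, w = in_shape
    h2, w2 = h - (ksize - 1) * 2, w - (ksize - 1) * 2
    hp = (h2 - pool) // pool_stride + 1
    wp = (w2 - pool) // pool_stride + 1
    if min(h2, w2, hp, wp) < 1:
        raise ValueError(f"input image {in_shape} too small for the architecture")
    d = k2 * hp * wp
    return {
        "W1": _he(rng, (k1, 1, ksize, ksize), ksize * ksize),
        "b1": np.zeros(k1, np.float32),
        "g1": np.ones(k1, np.float32),
        "be1": np.zeros(k1, np.float32),
        "W2": _he(rng, (k2, k1, ksize, ksize), k1 * ksize * ksize),
        "b2": np.zeros(k2, np.float32),
        "g2": np.ones(k2, np.float32),
        "be2": np.zeros(k2, np.float32),
        "Wf1": _he(rng, (d, hidden), d),
        "bf1": np.zeros(hidden, np.float32),
        "Wf2": _he(rng, (hidden, n_classes), hidden),
        "bf2": np.zeros(n_classes, np.float32),
    }


def init_bn_state(params: dict) -> dict:
    return {
        "m1": np.zeros_like(params["b1"]), "v1": np.ones_like(params["b1"]),
        "m2": np.zeros_like(params["b2"]), "v2": np.ones_like(params["b2"]),
    }


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid 3×3 correlation via one contiguous im2col matmul.

    Returns the output map and the (N*H'*W', C*k*k) column matrix, cached
    for the backward pass.
    """
    k = W.shape[-1]
    n, c, h, w = x.shape
    h2, w2 = h - k + 1, w - k + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h2 * w2, c * k * k
    )
    out = cols @ W.reshape(W.shape[0], -1).T  # (N*H'*W', K)
    out = out.reshape(n, h2, w2, W.shape[0]).transpose(0, 3, 1, 2) + b[None, :, None, None]
    return np.ascontiguousarray(out, np.float32), cols


def _conv_backward(dout: np.ndarray, cols: np.ndarray, W: np.ndarray, x_shape):
    k = W.shape[-1]
    n, kk, h2, w2 = dout.shape
    dout2d = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, kk)
    dW = (dout2d.T @ cols).reshape(W.shape)
    db = dout2d.sum(axis=0)
    dx = np.zeros(x_shape, np.float32)
    for u in range(k):
        for v in range(k):
            contrib = dout2d @ W[:, :, u, v]  # (N*H'*W', C)
            dx[:, :, u : u + h2, v : v + w2] += contrib.reshape(n, h2, w2, -1).transpose(
                0, 3, 1, 2
            )
    return dx, dW.astype(np.float32), db.astype(np.float32)


def _bn_forward(x, gamma, beta, running_m, running_v, train: bool, momentum=0.1):
    if train:
        m = x.mean(axis=(0, 2, 3))
        v = x.var(axis=(0, 2, 3))
        running_m *= 1 - momentum
        running_m += momentum * m
        running_v *= 1 - momentum
        running_v += momentum * v
    else:
        m, v = running_m, running_v
    invstd = 1.0 / np.sqrt(v + EPS)
    xhat = (x - m[None, :, None, None]) * invstd[None, :, None, None]
    out = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return out.astype(np.float32), (xhat, invstd)


def _bn_backward(dout, cache, gamma):
    xhat, invstd = cache
    axes = (0, 2, 3)
    m = dout.shape[0] * dout.shape[2] * dout.shape[3]
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    dxhat = dout * gamma[None, :, None, None]
    dx = (
        invstd[None, :, None, None]
        / m
        * (
            m * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True)
        )
    )
    return dx.astype(np.float32), dgamma.astype(np.float32), dbeta.astype(np.float32)


def _pool_views(x: np.ndarray, pool: int, stride: int):
    h, w = x.shape[2], x.shape[3]
    hp = (h - pool) // stride + 1
    wp = (w - pool) // stride + 1
    for u in range(pool):
        for v in range(pool):
            yield u, v, x[:, :, u : u + stride * hp : stride, v : v + stride * wp : stride]


def _pool_forward(x: np.ndarray, pool: int, stride: int):
    """Max pool via shifted views; caches first-match masks for backward."""
    out = None
    for _, _, view in _pool_views(x, pool, stride):
        out = view.copy() if out is None else np.maximum(out, view, out=out)
    masks = []
    assigned = np.zeros(out.shape, bool)
    for _, _, view in _pool_views(x, pool, stride):
        m = (view == out) & ~assigned
        assigned |= m
        masks.append(m)
    return out.astype(np.float32), masks


def _pool_backward(dout, masks, x_shape, pool: int, stride: int):
    dx = np.zeros(x_shape, np.float32)
    hp, wp = dout.shape[2], dout.shape[3]
    k = 0
    for u in range(pool):
        for v in range(pool):
            dx[:, :, u : u + stride * hp : stride, v : v + stride * wp : stride] += (
                dout * masks[k]
            )
            k += 1
    return dx


def forward(
    params: dict,
    bn: dict,
    x: np.ndarray,
    train: bool,
    rng: np.random.Generator | None = None,
    dropout: float = 0.5,
    pool: int = 2,
    pool_stride: int = 1,
):
    """Forward pass; returns logits and (if train) the backprop cache."""
    cache: dict = {}
    x = x[:, None, :, :].astype(np.float32)  # (N,1,F,T)
    cache["x_shape"] = x.shape
    z1, cols1 = _conv_forward(x, params["W1"], params["b1"])
    a1 = np.maximum(z1, 0)
    n1, bncache1 = _bn_forward(a1, params["g1"], params["be1"], bn["m1"], bn["v1"], train)
    z2, cols2 = _conv_forward(n1, params["W2"], params["b2"])
    a2 = np.maximum(z2, 0)
    p, pool_masks = _pool_forward(a2, pool, pool_stride)
    n2, bncache2 = _bn_forward(p, params["g2"], params["be2"], bn["m2"], bn["v2"], train)
    flat = n2.reshape(n2.shape[0], -1)
    h = flat @ params["Wf1"] + params["bf1"]
    ah = np.maximum(h, 0)
    if train and dropout > 0:
        mask = (rng.random(ah.shape) >= dropout).astype(np.float32) / (1.0 - dropout)
        ah = ah * mask
    else:
        mask = None
    logits = ah @ params["Wf2"] + params["bf2"]
    if train:
        cache.update(
            cols1=cols1, z1=z1, a1_shape=a1.shape, bncache1=bncache1, n1_shape=n1.shape,
            cols2=cols2, z2=z2, a2_shape=a2.shape, pool_masks=pool_masks, p_shape=p.shape,
            bncache2=bncache2, n2_shape=n2.shape, flat=flat, h=h, mask=mask, ah=ah,
        )
    return logits, cache


def backward(params: dict, cache: dict, dlogits: np.ndarray, pool: int, pool_stride: int) -> dict:
    g: dict = {}
    g["Wf2"] = cache["ah"].T @ dlogits
    g["bf2"] = dlogits.sum(axis=0)
    dah = dlogits @ params["Wf2"].T
    if cache["mask"] is not None:
        dah = dah * cache["mask"]
    dh = dah * (cache["h"] > 0)
    g["Wf1"] = cache["flat"].T @ dh
    g["bf1"] = dh.sum(axis=0)
    dflat = dh @ params["Wf1"].T
    dn2 = dflat.reshape(cache["n2_shape"])
    dp, g["g2"], g["be2"] = _bn_backward(dn2, cache["bncache2"], params["g2"])
    da2 = _pool_backward(dp, cache["pool_masks"], cache["a2_shape"], pool, pool_stride)
    dz2 = da2 * (cache["z2"] > 0)
    dn1, g["W2"], g["b2"] = _conv_backward(dz2, cache["cols2"], params["W2"], cache["n1_shape"])
    da1, g["g1"], g["be1"] = _bn_backward(dn1, cache["bncache1"], params["g1"])
    dz1 = da1 * (cache["z1"] > 0)
    _, g["W1"], g["b1"] = _conv_backward(dz1, cache["cols1"], params["W1"], cache["x_shape"])
    return g


def softmax_xent(logits: np.ndarray, y: np.ndarray):
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = y.size
    loss = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)


class Adam:
    def __init__(self, params: dict, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        c1 = 1.0 / (1 - self.b1**self.t)
        c2 = 1.0 / (1 - self.b2**self.t)
        for k, gk in grads.items():
            m, v = self.m[k], self.v[k]
            m *= self.b1
            m += (1 - self.b1) * gk
            v *= self.b2
            v += (1 - self.b2) * np.square(gk)
            denom = np.sqrt(v * c2)
            denom += self.eps
            params[k] -= (self.lr * c1) * m / denom
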