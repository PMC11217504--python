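"""Minimal numpy neural-network core for the triplet encoder.

Implements exactly the pieces the encoder needs — 3x3 stride-2 convolutions
(computed as nine per-offset tensordots, which keeps both passes as plain
BLAS matmuls), ReLU, global average pooling, a linear head, Adam, and a
vectorised batch affine warp for augmentation.  Gradients are exercised
against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Conv3x3Stride2:
    """3x3 convolution, stride 2, padding 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0.0, std, (c_out, c_in, 3, 3)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp = None

    @staticmethod
    def out_hw(h: int, w: int) -> tuple[int, int]:
        return (h - 1) // 2 + 1, (w - 1) // 2 + 1

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b_, c, h, w = x.shape
        oh, ow = self.out_hw(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        y = np.broadcast_to(
            self.b[None, :, None, None], (b_, self.W.shape[0], oh, ow)
        ).copy()
        for di in range(3):
            for dj in range(3):
                xs = xp[:, :, di:di + 2 * oh - 1:2, dj:dj + 2 * ow - 1:2]
                y += np.tensordot(
                    xs, self.W[:, :, di, dj], axes=([1], [1])
                ).transpose(0, 3, 1, 2)
        if train:
            self._xp = xp
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        b_, c, hp, wp = xp.shape
        oh, ow = dy.shape[2], dy.shape[3]
        self.db[:] = dy.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                sl = (slice(None), slice(None),
                      slice(di, di + 2 * oh - 1, 2),
                      slice(dj, dj + 2 * ow - 1, 2))
                xs = xp[sl]
                self.dW[:, :, di, dj] = np.tensordot(
                    dy, xs, axes=([0, 2, 3], [0, 2, 3])
                )
                dxp[sl] += np.tensordot(
                    dy, self.W[:, :, di, dj], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, train):
        if train:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class GlobalAvgPool:
    def __init__(self):
        self._hw = None

    def forward(self, x, train):
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        b_, c, h, w = self._shape
        return np.broadcast_to(
            dy[:, :, None, None] / self._hw, self._shape
        ).copy()

    def params(self):
        return []


class Flatten:
    def __init__(self):
        self._shape = None

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params(self):
        return []


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(1.0 / n_in)
        self.W = rng.normal(0.0, std, (n_out, n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW[:] = dy.T @ self._x
        self.db[:] = dy.sum(axis=0)
        return dy @ self.W

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Encoder:
    """Strided-conv stack + GAP + linear head mapping images to embeddings."""

    def __init__(self, channels, embed_dim: int, rng: np.random.Generator,
                 in_channels: int = 3, input_hw: tuple[int, int] | None = None,
                 pool: str = "flatten"):
        self.layers = []
        c = in_channels
        h, w = input_hw if input_hw is not None else (None, None)
        for c_out in channels:
            self.layers.append(Conv3x3Stride2(c, c_out, rng))
            self.layers.append(ReLU())
            if h is not None:
                h, w = Conv3x3Stride2.out_hw(h, w)
            c = c_out
        if pool == "gap":
            self.layers.append(GlobalAvgPool())
            n_feat = c
        elif pool == "flatten":
            if h is None:
                raise ValueError("flatten pooling needs input_hw")
            self.layers.append(Flatten())
            n_feat = c * h * w
        else:
            raise ValueError(f"unknown pool {pool!r}")
        self.head = Linear(n_feat, embed_dim, rng)
        self.layers.append(self.head)
        self.embed_dim = embed_dim

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, d_emb: np.ndarray) -> None:
        d = d_emb
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def triplet_batch_loss(emb: np.ndarray, margin: float):
    """Mean hinge triplet loss over a batch of stacked [a; p; n] embeddings.

    Returns (loss, d_emb) where d_emb is the gradient of the mean loss with
    respect to the stacked embedding array.
    """
    b = emb.shape[0] // 3
    a, p, n = emb[:b], emb[b:2 * b], emb[2 * b:]
    eps = 1e-12
    d_ap = np.sqrt(((a - p) ** 2).sum(axis=1) + eps)
    d_an = np.sqrt(((a - n) ** 2).sum(axis=1) + eps)
    hinge = d_ap - d_an + margin
    active = hinge > 0
    loss = float(np.maximum(hinge, 0).mean())
    scale = active.astype(float)[:, None] / b
    u_ap = (a - p) / d_ap[:, None]
    u_an = (a - n) / d_an[:, None]
    d_emb = np.concatenate([
        scale * (u_ap - u_an),
        -scale * u_ap,
        scale * u_an,
    ])
    return loss, d_emb


def affine_warp_batch(x: np.ndarray, mats: np.ndarray) -> np.ndarray:
    """Bilinear warp of a (B, C, H, W) batch.

    ``mats`` is (B, 2, 3): for each output pixel (row r, col c) the source
    location is ``mats @ [r - cy, c - cx, 1] + [cy, cx]`` with the centre of
    the image as origin.  Out-of-frame samples take the value of each image's
    top-left pixel (the background corner).
    """
    b_, c_, h, w = x.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rr, cc = np.meshgrid(np.arange(h, dtype=np.float32) - cy,
                         np.arange(w, dtype=np.float32) - cx, indexing="ij")
    ones = np.ones_like(rr)
    mats = mats.astype(np.float32)
    grid = np.stack([rr, cc, ones])                      # (3, H, W)
    src = np.einsum("bij,jhw->bihw", mats, grid)         # (B, 2, H, W)
    sr = src[:, 0] + cy
    sc = src[:, 1] + cx

    r0 = np.floor(sr).astype(np.int64)
    c0 = np.floor(sc).astype(np.int64)
    fr = sr - r0
    fc = sc - c0
    inside = (sr >= 0) & (sr <= h - 1) & (sc >= 0) & (sc <= w - 1)
    r0c = np.clip(r0, 0, h - 2)
    c0c = np.clip(c0, 0, w - 2)

    bidx = np.arange(b_)[:, None, None]
    def gather(ri, ci):
        return x[bidx, :, ri, ci]                        # (B, H, W, C)

    v00 = gather(r0c, c0c)
    v01 = gather(r0c, c0c + 1)
    v10 = gather(r0c + 1, c0c)
    v11 = gather(r0c + 1, c0c + 1)
    frq = fr[..., None]
    fcq = fc[..., None]
    out = ((1 - frq) * (1 - fcq) * v00 + (1 - frq) * fcq * v01
           + frq * (1 - fcq) * v10 + frq * fcq * v11)    # (B, H, W, C)
    fill = x[:, :, 0, 0][:, None, None, :]               # broadcast corner
    out = np.where(inside[..., None], out, fill)
    return out.transpose(0, 3, 1, 2)


def random_affine_mats(rng: np.random.Generator, n: int, h: int, w: int,
                       translate: float, scale_range, shear_deg: float):
    """Inverse affine matrices for :func:`affine_warp_batch`.

    Draws, per image: translation uniform in +-translate (fraction of each
    dimension), log-uniform scale in ``scale_range``, shear uniform in
    +-``shear_deg`` degrees applied to the column axis.
    """
    mats = np.zeros((n, 2, 3), dtype=np.float32)
    s_lo, s_hi = scale_range
    for i in range(n):
        s = np.exp(rng.uniform(np.log(s_lo), np.log(s_hi))) if s_hi > s_lo else s_lo
        sh = np.deg2rad(rng.uniform(-shear_deg, shear_deg)) if shear_deg > 0 else 0.0
        ty = rng.uniform(-translate, translate) * h if translate > 0 else 0.0
        tx = rng.uniform(-translate, translate) * w if translate > 0 else 0.0
        # forward map: scale then shear then translate; store its inverse
        fwd = np.array([[s, 0.0], [s * np.tan(sh), s]])
        inv = np.linalg.inv(fwd)
        mats[i, :, :2] = inv
        mats[i, :, 2] = -inv @ np.array([ty, tx])
    return mats
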