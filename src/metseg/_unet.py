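"""A small NumPy 2-D U-Net (encoder-decoder with skip connections).

Three resolution levels, base width 8, one 3x3 convolution + ReLU per
block, 2x2 max pooling, nearest-neighbour upsampling, a 1x1 output
convolution and a terminal sigmoid.  Forward and backward passes are
written directly in NumPy (each "same" convolution is nine shifted
matrix products), trained with Adam on a combined soft-Dice +
binary-cross-entropy pixel loss.  It is deliberately tiny: its job is to
be a real, CPU-trainable probability-map producer behind the model-bank
interface, not a clinical-grade segmenter.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

_F = np.float32


def _he(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(_F)


def _conv_fwd(x, w, b):
    """'Same' convolution; returns output and the padded input (cache)."""
    k = w.shape[0]
    p = k // 2
    n, h, wd, _ = x.shape
    co = w.shape[3]
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
    y = np.zeros((n, h, wd, co), _F)
    for i in range(k):
        for j in range(k):
            y += xp[:, i : i + h, j : j + wd, :] @ w[i, j]
    return y + b, xp


def _conv_bwd(dy, xp, w):
    k = w.shape[0]
    p = k // 2
    n, h, wd, co = dy.shape
    ci = w.shape[2]
    dw = np.zeros_like(w)
    db = dy.reshape(-1, co).sum(0)
    dxp = np.zeros_like(xp)
    dyf = dy.reshape(-1, co)
    for i in range(k):
        for j in range(k):
            xs = xp[:, i : i + h, j : j + wd, :].reshape(-1, ci)
            dw[i, j] = xs.T @ dyf
            dxp[:, i : i + h, j : j + wd, :] += dy @ w[i, j].T
    dx = dxp[:, p:-p, p:-p, :] if p else dxp
    return dx, dw, db


def _pool2(x):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    y = xr.max(axis=(2, 4))
    # cache which cell won, first-wins on ties
    flat = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
    arg = flat.argmax(axis=-1)
    return y, arg


def _pool2_bwd(dy, arg):
    n, h2, w2, c = dy.shape
    dflat = np.zeros((n, h2, w2, c, 4), _F)
    np.put_along_axis(dflat, arg[..., None], dy[..., None], axis=-1)
    dx = (
        dflat.reshape(n, h2, w2, c, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, h2 * 2, w2 * 2, c)
    )
    return dx


def _up2(x):
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _up2_bwd(dy):
    n, h, w, c = dy.shape
    return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(_F)


class TinyUNet:
    """CPU-trainable U-Net emitting per-pixel tumor probabilities.

    Layer spec (base width ``b``, default 8)::

        enc1: conv3x3(1 -> b)   + ReLU          @ 256x256
        enc2: conv3x3(b -> 2b)  + ReLU          @ 128x128
        bott: conv3x3(2b -> 4b) + ReLU          @  64x64
        dec2: conv3x3(4b+2b -> 2b) + ReLU       @ 128x128  (skip from enc2)
        dec1: conv3x3(2b+b -> b)   + ReLU       @ 256x256  (skip from enc1)
        out : conv1x1(b -> 1), sigmoid
    """

    def __init__(self, seed: int = 0, base_width: int = 8):
        rng = np.random.default_rng(seed)
        b = base_width
        self.base_width = b
        self.seed = seed
        self.params: dict[str, np.ndarray] = {}

        def mk(name, k, ci, co):
            self.params[f"{name}_w"] = _he(rng, (k, k, ci, co), k * k * ci)
            self.params[f"{name}_b"] = np.zeros(co, _F)

        mk("e1", 3, 1, b)
        mk("e2", 3, b, 2 * b)
        mk("bo", 3, 2 * b, 4 * b)
        mk("d2", 3, 6 * b, 2 * b)
        mk("d1", 3, 3 * b, b)
        mk("out", 1, b, 1)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray):
        p = self.params
        cache: dict = {}

        def conv_relu(name, inp):
            y, xp = _conv_fwd(inp, p[f"{name}_w"], p[f"{name}_b"])
            cache[name] = (xp, y > 0)
            return np.maximum(y, 0)

        e1 = conv_relu("e1", x)
        p1, cache["a1"] = _pool2(e1)
        e2 = conv_relu("e2", p1)
        p2, cache["a2"] = _pool2(e2)
        bo = conv_relu("bo", p2)
        u2 = np.concatenate([_up2(bo), e2], axis=3)
        d2 = conv_relu("d2", u2)
        u1 = np.concatenate([_up2(d2), e1], axis=3)
        d1 = conv_relu("d1", u1)
        z, cache["out_xp"] = _conv_fwd(d1, p["out_w"], p["out_b"])
        prob = expit(z)
        return prob, cache

    @staticmethod
    def loss(prob: np.ndarray, y: np.ndarray, w_dice=1.0, w_bce=0.5):
        """Combined soft-Dice + BCE loss and its gradient w.r.t. logits."""
        eps = 1.0
        inter = float((prob * y).sum())
        ps, ys = float(prob.sum()), float(y.sum())
        dice = (2 * inter + eps) / (ps + ys + eps)
        p_cl = np.clip(prob, 1e-7, 1 - 1e-7)
        bce = float(-(y * np.log(p_cl) + (1 - y) * np.log(1 - p_cl)).mean())
        loss = w_dice * (1.0 - dice) + w_bce * bce
        d_dice_dp = (2 * y * (ps + ys + eps) - (2 * inter + eps)) / (ps + ys + eps) ** 2
        dz = (-w_dice * d_dice_dp) * prob * (1 - prob) + w_bce * (prob - y) / prob.size
        return loss, dice, dz.astype(_F)

    def backward(self, dz: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p = self.params
        g: dict[str, np.ndarray] = {}
        b = self.base_width

        def conv_bwd(name, dy, relu=True):
            xp, pos = cache[name]
            if relu:
                dy = dy * pos
            dx, dw, db = _conv_bwd(dy, xp, p[f"{name}_w"])
            g[f"{name}_w"] = dw
            g[f"{name}_b"] = db
            return dx

        dd1, g["out_w"], g["out_b"] = _conv_bwd(dz, cache["out_xp"], p["out_w"])
        du1 = conv_bwd("d1", dd1)
        dd2 = _up2_bwd(du1[..., : 2 * b])
        de1_skip = du1[..., 2 * b :]
        du2 = conv_bwd("d2", dd2)
        dbo = _up2_bwd(du2[..., : 4 * b])
        de2_skip = du2[..., 4 * b :]
        dp2 = conv_bwd("bo", dbo)
        de2 = _pool2_bwd(dp2, cache["a2"]) + de2_skip
        dp1 = conv_bwd("e2", de2)
        de1 = _pool2_bwd(dp1, cache["a1"]) + de1_skip
        conv_bwd("e1", de1)
        return g

    def adam_step(self, grads, lr=3e-3, b1=0.9, b2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, gk in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * gk
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * gk * gk
            mhat = self._adam_m[k] / (1 - b1**t)
            vhat = self._adam_v[k] / (1 - b2**t)
            self.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(_F)

    # -- training / inference ----------------------------------------------

    def fit(
        self,
        images: np.ndarray,
        masks: np.ndarray,
        steps: int = 400,
        batch_size: int = 2,
        lr: float = 3e-3,
        seed: int = 0,
    ) -> list[float]:
        """Train on (n, H, W) images / binary masks; returns the loss trace."""
        x = np.asarray(images, _F)[..., None]
        y = np.asarray(masks, _F)[..., None]
        if x.shape[0] == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(seed)
        trace = []
        for _ in range(steps):
            idx = rng.choice(x.shape[0], size=min(batch_size, x.shape[0]), replace=False)
            prob, cache = self.forward(x[idx])
            loss, _, dz = self.loss(prob, y[idx])
            grads = self.backward(dz, cache)
            self.adam_step(grads, lr=lr)
            trace.append(loss)
        return trace

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel tumor probability for one (H, W) image, in [0, 1]."""
        prob, _ = self.forward(np.asarray(image, _F)[None, ..., None])
        return prob[0, ..., 0].astype(float)
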