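"""A compact 3D encoder–decoder network implemented in numpy.

This is the trainable backbone behind the iterative segmenter: a three-level
U-net ("Spine U-net") over channels-first ``(C, D, H, W)`` patches, with skip
connections, plus a small additional compression path branching off the
bottleneck that predicts two scalars — a vertebra-completeness probability and
an instance-label value.

Convolutions are 3×3×3 with unit padding, evaluated as im2col + one BLAS
matmul; gradients are derived manually (col2im for the input gradient).  The
whole model is a plain dict of float32 arrays, so checkpoints are
``np.savez`` files and training is bit-reproducible for a fixed seed and
thread count.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

__all__ = ["SpineUNet", "Adam", "sigmoid"]

_OFFSETS = [(dz, dy, dx) for dz in range(3) for dy in range(3) for dx in range(3)]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float32)
    np.negative(x, out=out)
    np.exp(np.clip(out, -60, 60, out=out), out=out)
    out += 1.0
    np.reciprocal(out, out=out)
    return out


def _im2col(x: np.ndarray) -> np.ndarray:
    """(C, D, H, W) → (27*C, D*H*W) patch matrix for a 3³ kernel, pad 1."""
    C, D, H, W = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    cols = np.empty((27 * C, D * H * W), dtype=np.float32)
    for k, (dz, dy, dx) in enumerate(_OFFSETS):
        cols[k * C:(k + 1) * C] = xp[:, dz:dz + D, dy:dy + H, dx:dx + W].reshape(C, -1)
    return cols


def _col2im(dcols: np.ndarray, shape: Tuple[int, int, int, int]) -> np.ndarray:
    C, D, H, W = shape
    dxp = np.zeros((C, D + 2, H + 2, W + 2), dtype=np.float32)
    for k, (dz, dy, dx) in enumerate(_OFFSETS):
        dxp[:, dz:dz + D, dy:dy + H, dx:dx + W] += dcols[k * C:(k + 1) * C].reshape(C, D, H, W)
    return dxp[:, 1:-1, 1:-1, 1:-1]


class _Conv3:
    """3×3×3 convolution + ReLU (ReLU optional), with cached backward."""

    def __init__(self, name: str, c_in: int, c_out: int, relu: bool = True):
        self.name, self.c_in, self.c_out, self.relu = name, c_in, c_out, relu

    def init(self, params: Dict[str, np.ndarray], rng: np.random.Generator) -> None:
        fan_in = 27 * self.c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(self.c_out, fan_in))
        params[self.name + ".w"] = w.astype(np.float32)
        params[self.name + ".b"] = np.zeros(self.c_out, dtype=np.float32)

    def forward(self, params, x: np.ndarray, cache: dict) -> np.ndarray:
        cols = _im2col(x)
        out = params[self.name + ".w"] @ cols + params[self.name + ".b"][:, None]
        out = out.reshape(self.c_out, *x.shape[1:])
        if self.relu:
            np.maximum(out, 0.0, out=out)
        cache[self.name] = (cols, x.shape, out if self.relu else None)
        return out

    def backward(self, params, grads, dout: np.ndarray, cache: dict) -> np.ndarray:
        cols, xshape, relu_out = cache[self.name]
        if self.relu:
            dout = dout * (relu_out > 0)
        dflat = dout.reshape(self.c_out, -1)
        grads[self.name + ".w"] = grads.get(self.name + ".w", 0) + dflat @ cols.T
        grads[self.name + ".b"] = grads.get(self.name + ".b", 0) + dflat.sum(axis=1)
        dcols = params[self.name + ".w"].T @ dflat
        return _col2im(dcols, xshape)


def _maxpool2(x: np.ndarray):
    C, D, H, W = x.shape
    xr = x.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2)
    out = xr.max(axis=(2, 4, 6))
    mask = xr == out[:, :, None, :, None, :, None]
    return out, mask


def _maxpool2_back(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    d = mask * dout[:, :, None, :, None, :, None]
    C, D2, _, H2, _, W2, _ = d.shape
    return d.reshape(C, D2 * 2, H2 * 2, W2 * 2)


def _upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def _upsample2_back(dout: np.ndarray) -> np.ndarray:
    C, D, H, W = dout.shape
    return dout.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2).sum(axis=(2, 4, 6))


class SpineUNet:
    """Three-level 3D U-net with completeness/label compression heads.

    ``widths`` are the channel counts of the three resolution levels.  Input
    patches need even extents divisible by 4.  ``forward`` returns raw logits
    for the three segmentation channels (vertebra, IVD, canal), a completeness
    logit and a label regression value.
    """

    HEAD_HIDDEN = 16

    def __init__(self, in_channels: int = 3, widths: Tuple[int, int, int] = (8, 16, 32),
                 seed: int = 0):
        self.in_channels = in_channels
        self.widths = tuple(widths)
        w1, w2, w3 = self.widths
        self.layers = {
            "enc1": _Conv3("enc1", in_channels, w1),
            "enc2": _Conv3("enc2", w1, w2),
            "bott": _Conv3("bott", w2, w3),
            "dec2": _Conv3("dec2", w3 + w2, w2),
            "dec1": _Conv3("dec1", w2 + w1, w1),
        }
        self.params: Dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        for layer in self.layers.values():
            layer.init(self.params, rng)
        self.params["out.w"] = rng.normal(0.0, np.sqrt(2.0 / w1), size=(3, w1)).astype(np.float32)
        self.params["out.b"] = np.zeros(3, dtype=np.float32)
        self.params["head.w1"] = rng.normal(0.0, np.sqrt(2.0 / w3),
                                            size=(self.HEAD_HIDDEN, w3)).astype(np.float32)
        self.params["head.b1"] = np.zeros(self.HEAD_HIDDEN, dtype=np.float32)
        self.params["head.w2"] = rng.normal(0.0, np.sqrt(2.0 / self.HEAD_HIDDEN),
                                            size=(2, self.HEAD_HIDDEN)).astype(np.float32)
        self.params["head.b2"] = np.zeros(2, dtype=np.float32)

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray, cache: dict | None = None):
        """x: (in_channels, D, H, W) float32 → (seg_logits, comp_logit, label_value)."""
        store = cache if cache is not None else {}
        p = self.params
        e1 = self.layers["enc1"].forward(p, x.astype(np.float32), store)
        p1, m1 = _maxpool2(e1)
        e2 = self.layers["enc2"].forward(p, p1, store)
        p2, m2 = _maxpool2(e2)
        b = self.layers["bott"].forward(p, p2, store)
        u2 = _upsample2(b)
        d2 = self.layers["dec2"].forward(p, np.concatenate([u2, e2]), store)
        u1 = _upsample2(d2)
        d1 = self.layers["dec1"].forward(p, np.concatenate([u1, e1]), store)
        seg = np.einsum("oc,cdhw->odhw", p["out.w"], d1) + p["out.b"][:, None, None, None]

        g = b.reshape(b.shape[0], -1).mean(axis=1)  # global average pool
        h = p["head.w1"] @ g + p["head.b1"]
        hr = np.maximum(h, 0.0)
        head = p["head.w2"] @ hr + p["head.b2"]
        comp_logit, label_value = float(head[0]), float(head[1])

        if cache is not None:
            store["_misc"] = (x.shape, m1, m2, b.shape, d1, g, hr, e1.shape, e2.shape)
        return seg.astype(np.float32), comp_logit, label_value

    # -- backward -----------------------------------------------------------

    def backward(self, dseg: np.ndarray, dcomp: float, dlabel: float, cache: dict
                 ) -> Dict[str, np.ndarray]:
        """Gradients of a scalar loss given d(loss)/d(outputs); returns grad dict."""
        p = self.params
        grads: Dict[str, np.ndarray] = {}
        xshape, m1, m2, bshape, d1, g, hr, e1shape, e2shape = cache["_misc"]

        # heads
        dhead = np.array([dcomp, dlabel], dtype=np.float32)
        grads["head.w2"] = np.outer(dhead, hr)
        grads["head.b2"] = dhead
        dhr = p["head.w2"].T @ dhead
        dh = dhr * (hr > 0)
        grads["head.w1"] = np.outer(dh, g)
        grads["head.b1"] = dh
        dg = p["head.w1"].T @ dh
        nvox_b = int(np.prod(bshape[1:]))
        db_head = np.broadcast_to((dg / nvox_b)[:, None], (bshape[0], nvox_b)).reshape(bshape)

        # segmentation output (1×1×1 conv)
        dflat = dseg.reshape(3, -1)
        d1flat = d1.reshape(d1.shape[0], -1)
        grads["out.w"] = dflat @ d1flat.T
        grads["out.b"] = dflat.sum(axis=1)
        dd1 = np.einsum("oc,odhw->cdhw", p["out.w"], dseg)

        dcat1 = self.layers["dec1"].backward(p, grads, dd1, cache)
        w2ch = self.widths[1]
        du1, de1_skip = dcat1[:w2ch], dcat1[w2ch:]
        dd2 = _upsample2_back(du1)
        dcat2 = self.layers["dec2"].backward(p, grads, dd2, cache)
        w3ch = self.widths[2]
        du2, de2_skip = dcat2[:w3ch], dcat2[w3ch:]
        db = _upsample2_back(du2) + db_head
        dp2 = self.layers["bott"].backward(p, grads, db, cache)
        de2 = _maxpool2_back(dp2, m2) + de2_skip
        dp1 = self.layers["enc2"].backward(p, grads, de2, cache)
        de1 = _maxpool2_back(dp1, m1) + de1_skip
        self.layers["enc1"].backward(p, grads, de1, cache)
        return grads

    # -- persistence ---------------------------------------------------------

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32)


class Adam:
    """Standard Adam on a parameter dict."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float = 3e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            g = np.asarray(g, dtype=np.float32)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
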