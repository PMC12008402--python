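"""Minimal seeded 3D convolutional regression stack on numpy.

Implements exactly the pieces the volumetric regressor needs — strided
3D convolution (via slice-stacked im2col and matmul), batch
normalization, ReLU, global average pooling, inverted dropout and a
linear head — each with hand-derived backward passes, plus Adam.
Tensors are (N, C, H, W, D) float32; H is the superior-inferior en-face
axis, W the horizontal en-face axis, D depth.

The default architecture prepends two fixed en-face coordinate
channels to the input so that channels feeding the global average pool
can encode *where* in the en-face plane a structural feature sits;
without them a GAP head is blind to defect location.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = ["Conv3d", "BatchNorm3d", "ReLU", "GlobalAvgPool", "Dropout",
           "Linear", "Adam", "VolumeRegressor"]

_EPS = 1e-5


class Layer:
    """Base layer: named parameters and matching gradient buffers."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _offsets(k: int):
    return list(itertools.product(range(k), repeat=3))


class Conv3d(Layer):
    """k^3 strided 3D convolution with same-style padding."""

    def __init__(self, c_in: int, c_out: int, *, k: int = 3, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k ** 3
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self.params["w"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)
        ).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def _out_shape(self, s):
        return tuple((dim + 2 * self.pad - self.k) // self.stride + 1 for dim in s)

    def forward(self, x, train):
        n, c, *spatial = x.shape
        so = self._out_shape(spatial)
        p, st, k = self.pad, self.stride, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        slabs = [
            xp[:, :,
               i:i + so[0] * st:st,
               j:j + so[1] * st:st,
               l:l + so[2] * st:st]
            for (i, j, l) in _offsets(k)
        ]
        # cols: (N, C * k^3, L) with kernel-offset major, channel minor
        cols = np.stack(slabs, axis=1).reshape(n, k ** 3 * c, -1)
        self._cache = (cols, x.shape, so)
        y = np.einsum("of,nfl->nol", self.params["w"], cols, optimize=True)
        y += self.params["b"][None, :, None]
        return np.ascontiguousarray(y.reshape(n, self.c_out, *so), dtype=np.float32)

    def backward(self, dy):
        cols, x_shape, so = self._cache
        n = x_shape[0]
        dyf = dy.reshape(n, self.c_out, -1)
        self.grads["w"] = np.einsum("nol,nfl->of", dyf, cols, optimize=True).astype(np.float32)
        self.grads["b"] = dyf.sum(axis=(0, 2)).astype(np.float32)
        dcols = np.einsum("of,nol->nfl", self.params["w"], dyf, optimize=True)
        p, st, k = self.pad, self.stride, self.k
        c = self.c_in
        dxp = np.zeros(
            (n, c, x_shape[2] + 2 * p, x_shape[3] + 2 * p, x_shape[4] + 2 * p),
            dtype=np.float32,
        )
        dcols = dcols.reshape(n, k ** 3, c, *so)
        for m, (i, j, l) in enumerate(_offsets(k)):
            dxp[:, :,
                i:i + so[0] * st:st,
                j:j + so[1] * st:st,
                l:l + so[2] * st:st] += dcols[:, m]
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class BatchNorm3d(Layer):
    def __init__(self, c: int, momentum: float = 0.1):
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self._axes = (0, 2, 3, 4)

    def forward(self, x, train):
        g = self.params["gamma"][None, :, None, None, None]
        b = self.params["beta"][None, :, None, None, None]
        if train:
            mu = x.mean(axis=self._axes)
            var = x.var(axis=self._axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mu[None, :, None, None, None]) * ivar[None, :, None, None, None]
        self._cache = (xhat, ivar, train)
        return (g * xhat + b).astype(np.float32)

    def backward(self, dy):
        xhat, ivar, train = self._cache
        g = self.params["gamma"]
        self.grads["gamma"] = np.einsum("nchwd,nchwd->c", dy, xhat).astype(np.float32)
        self.grads["beta"] = dy.sum(axis=self._axes).astype(np.float32)
        dxhat = dy * g[None, :, None, None, None]
        if not train:
            return (dxhat * ivar[None, :, None, None, None]).astype(np.float32)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        sum_dxhat = dxhat.sum(axis=self._axes)[None, :, None, None, None]
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=self._axes)[None, :, None, None, None]
        dx = (ivar[None, :, None, None, None] / m) * (
            m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat
        )
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return (dy * self._mask).astype(np.float32)


class GlobalAvgPool(Layer):
    """(N, C, H, W, D) -> (N, C) mean over the spatial axes."""

    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4)).astype(np.float32)

    def backward(self, dy):
        n, c, h, w, d = self._shape
        scale = 1.0 / (h * w * d)
        return (np.broadcast_to(dy[:, :, None, None, None], self._shape) * scale).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return (x * self._mask).astype(np.float32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(np.float32)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["w"] = rng.normal(
            0.0, np.sqrt(1.0 / n_in), size=(n_out, n_in)
        ).astype(np.float32)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, train):
        self._x = x
        return (x @ self.params["w"].T + self.params["b"]).astype(np.float32)

    def backward(self, dy):
        self.grads["w"] = (dy.T @ self._x).astype(np.float32)
        self.grads["b"] = dy.sum(axis=0).astype(np.float32)
        return (dy @ self.params["w"]).astype(np.float32)


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, layers, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        self.t += 1
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mhat = self.m[i][k] / (1 - self.b1 ** self.t)
                vhat = self.v[i][k] / (1 - self.b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class ArchSpec:
    channels: tuple[int, ...]
    use_coord_channels: bool = True


ARCHS = {
    # ~110k parameters, 4 stride-2 blocks: the desk-scale default
    "small3dcnn": ArchSpec(channels=(12, 24, 48, 48)),
    # deeper/wider member of the same block family for larger inputs
    "efficientnet3d_b0": ArchSpec(channels=(16, 24, 40, 80, 112)),
}


class VolumeRegressor:
    """Stacked conv+BN+ReLU blocks, GAP, dropout head, direct linear map.

    There is no hidden layer between the dropout and the output: the
    head maps pooled channels straight to the ``n_outputs`` targets.
    """

    def __init__(self, n_outputs: int = 122, arch: str = "small3dcnn",
                 dropout: float = 0.30, seed: int = 0):
        spec = ARCHS[arch]
        rng = np.random.default_rng(seed)
        self.use_coords = spec.use_coord_channels
        c_in = 1 + (2 if self.use_coords else 0)
        self.layers: list[Layer] = []
        for c_out in spec.channels:
            self.layers.append(Conv3d(c_in, c_out, rng=rng))
            self.layers.append(BatchNorm3d(c_out))
            self.layers.append(ReLU())
            c_in = c_out
        self.layers.append(GlobalAvgPool())
        self.layers.append(Dropout(dropout, rng=rng))
        self.layers.append(Linear(c_in, n_outputs, rng=rng))
        self._coord_cache: dict[tuple, np.ndarray] = {}

    # -- plumbing ---------------------------------------------------------
    def _with_coords(self, x: np.ndarray) -> np.ndarray:
        if not self.use_coords:
            return x
        n, _, h, w, d = x.shape
        key = (h, w, d)
        if key not in self._coord_cache:
            cy = np.linspace(-1, 1, h, dtype=np.float32)[:, None, None]
            cx = np.linspace(-1, 1, w, dtype=np.float32)[None, :, None]
            coords = np.stack(
                [np.broadcast_to(cy, (h, w, d)), np.broadcast_to(cx, (h, w, d))]
            )
            self._coord_cache[key] = coords.astype(np.float32)
        coords = np.broadcast_to(self._coord_cache[key][None], (n, 2, h, w, d))
        return np.concatenate([x, coords], axis=1)

    def forward(self, volumes: np.ndarray, train: bool = False) -> np.ndarray:
        """volumes: (N, H, W, D) -> predictions (N, n_outputs)."""
        x = self._with_coords(volumes[:, None].astype(np.float32))
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def __call__(self, volumes: np.ndarray) -> np.ndarray:
        return self.forward(volumes, train=False)

    def n_parameters(self) -> int:
        return sum(p.size for l in self.layers for p in l.params.values())

    # -- state ------------------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for i, l in enumerate(self.layers):
            for k, v in l.params.items():
                state[f"{i}.{k}"] = v.copy()
            if isinstance(l, BatchNorm3d):
                state[f"{i}.running_mean"] = l.running_mean.copy()
                state[f"{i}.running_var"] = l.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, l in enumerate(self.layers):
            for k in l.params:
                l.params[k][...] = state[f"{i}.{k}"]
            if isinstance(l, BatchNorm3d):
                l.running_mean[...] = state[f"{i}.running_mean"]
                l.running_var[...] = state[f"{i}.running_var"]
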