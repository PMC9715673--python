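"""Minimal NumPy neural-network substrate.

Layers, backpropagation, optimizers and checkpoint IO for the small
convolutional classifiers used throughout the package.  Everything is
plain ``float32`` NumPy on NCHW batches; the relevance-propagation module
re-runs forward passes in ``float64`` using the same layer objects.

Only the layer types needed by the dense-block classifiers are provided:
convolution, dense, ReLU, batch normalization, max/average pooling,
global average pooling, and a dense-block composite that concatenates
feature maps along the channel axis.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from pathlib import Path
from typing import Iterable

import numpy as np

DTYPE = np.float32


# ---------------------------------------------------------------------------
# im2col helpers
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, OH*OW, C*kh*kw) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (N,C,OH,OW,kh,kw)
    n, c, oh, ow = windows.shape[:4]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add of patch gradients)."""
    n, c, h, w = x_shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)  # (N,C,kh,kw,OH,OW)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += d[:, :, i, j]
    if pad:
        dxp = dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def _out_hw(h: int, w: int, k: int, stride: int, pad: int) -> tuple[int, int]:
    return (h + 2 * pad - k) // stride + 1, (w + 2 * pad - k) // stride + 1


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: forward caches what backward/relprop need."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        if c_in <= 0 or c_out <= 0:
            raise ValueError(f"Conv2D channels must be positive, got ({c_in}, {c_out})")
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k // 2) if pad is None else pad
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._x_shape = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training=False):
        self._x_shape = x.shape
        self.last_input = x
        cols = _im2col(x, self.k, self.k, self.stride, self.pad)
        self._cols = cols
        wr = self.W.reshape(self.c_out, -1).astype(x.dtype)
        out = cols @ wr.T + self.b.astype(x.dtype)
        oh, ow = _out_hw(x.shape[2], x.shape[3], self.k, self.stride, self.pad)
        return out.transpose(0, 2, 1).reshape(x.shape[0], self.c_out, oh, ow)

    def backward(self, dout):
        n = dout.shape[0]
        dflat = dout.reshape(n, self.c_out, -1).transpose(0, 2, 1)  # (N,P,cout)
        wr = self.W.reshape(self.c_out, -1)
        self.dW[...] = np.tensordot(dflat, self._cols, axes=([0, 1], [0, 1])).reshape(self.W.shape)
        self.db[...] = dflat.sum(axis=(0, 1))
        dcols = dflat @ wr
        return _col2im(dcols, self._x_shape, self.k, self.k, self.stride, self.pad)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out)).astype(DTYPE)
        self.b = np.zeros(d_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training=False):
        self.last_input = x
        return x @ self.W.astype(x.dtype) + self.b.astype(x.dtype)

    def backward(self, dout):
        self.dW[...] = self.last_input.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class ReLU(Layer):
    def forward(self, x, training=False):
        self.last_input = x
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * (self.last_input > 0)


class BatchNorm2D(Layer):
    """Per-channel batch normalization (NCHW), running stats for inference."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def extra_state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, training=False):
        self.last_input = x
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._training = training
        self._mean = mean.astype(x.dtype)
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        self._xhat = (x - self._mean[None, :, None, None]) * self._inv_std[None, :, None, None]
        return (self.gamma.astype(x.dtype)[None, :, None, None] * self._xhat
                + self.beta.astype(x.dtype)[None, :, None, None])

    def backward(self, dout):
        self.dgamma[...] = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.astype(dout.dtype)[None, :, None, None]
        inv = self._inv_std[None, :, None, None]
        if not self._training:
            return dxhat * inv
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        return inv * (dxhat - s1 / n - self._xhat * s2 / n)


class MaxPool2D(Layer):
    """Non-overlapping max pooling; winner-take-all routing in backward."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, training=False):
        s = self.size
        n, c, h, w = x.shape
        if h % s or w % s:
            raise ValueError(f"MaxPool2D requires spatial dims divisible by {s}, got {(h, w)}")
        self.last_input = x
        windows = (x.reshape(n, c, h // s, s, w // s, s)
                    .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // s, w // s, s * s))
        self._argmax = windows.argmax(axis=-1)  # first max wins ties
        return np.take_along_axis(windows, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        s = self.size
        n, c, oh, ow = dout.shape
        d = np.zeros((n, c, oh, ow, s * s), dtype=dout.dtype)
        np.put_along_axis(d, self._argmax[..., None], dout[..., None], axis=-1)
        return (d.reshape(n, c, oh, ow, s, s).transpose(0, 1, 2, 4, 3, 5)
                 .reshape(n, c, oh * s, ow * s))


class AvgPool2D(Layer):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, training=False):
        s = self.size
        n, c, h, w = x.shape
        if h % s or w % s:
            raise ValueError(f"AvgPool2D requires spatial dims divisible by {s}, got {(h, w)}")
        self.last_input = x
        return x.reshape(n, c, h // s, s, w // s, s).mean(axis=(3, 5))

    def backward(self, dout):
        s = self.size
        return np.repeat(np.repeat(dout, s, axis=2), s, axis=3) / (s * s)


class GlobalAvgPool(Layer):
    def forward(self, x, training=False):
        self.last_input = x
        self._hw = x.shape[2] * x.shape[3]
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self.last_input.shape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / self._hw


class DenseLayerUnit(Layer):
    """One dense-block unit producing ``growth`` channels.

    Plain form: (BN-)ReLU-Conv3x3.  Bottleneck form (the DenseNet-121
    plan): BN-ReLU-Conv1x1(4·growth)-BN-ReLU-Conv3x3(growth).
    """

    def __init__(self, c_in: int, growth: int, rng, use_bn: bool = False,
                 bottleneck: bool = False):
        self.sub: list[Layer] = []
        if bottleneck:
            self.sub += [BatchNorm2D(c_in), ReLU(), Conv2D(c_in, 4 * growth, 1, rng=rng),
                         BatchNorm2D(4 * growth), ReLU(), Conv2D(4 * growth, growth, 3, rng=rng)]
            return
        if use_bn:
            self.sub.append(BatchNorm2D(c_in))
        self.sub.append(ReLU())
        self.sub.append(Conv2D(c_in, growth, 3, rng=rng))

    def forward(self, x, training=False):
        for l in self.sub:
            x = l.forward(x, training)
        return x

    def backward(self, dout):
        for l in reversed(self.sub):
            dout = l.backward(dout)
        return dout


class DenseBlock(Layer):
    """Dense connectivity: each unit sees the concatenation of all earlier maps."""

    def __init__(self, c_in: int, n_units: int, growth: int, rng, use_bn: bool = False,
                 bottleneck: bool = False):
        self.c_in, self.growth, self.n_units = c_in, growth, n_units
        self.units = [DenseLayerUnit(c_in + i * growth, growth, rng, use_bn, bottleneck)
                      for i in range(n_units)]
        self.c_out = c_in + n_units * growth

    def params(self):
        out = {}
        for i, u in enumerate(self.units):
            for j, l in enumerate(u.sub):
                for k, v in l.params().items():
                    out[f"u{i}_l{j}_{k}"] = v
        return out

    def grads(self):
        out = {}
        for i, u in enumerate(self.units):
            for j, l in enumerate(u.sub):
                for k, v in l.grads().items():
                    out[f"u{i}_l{j}_{k}"] = v
        return out

    def forward(self, x, training=False):
        self.last_input = x
        feats = [x]
        for u in self.units:
            cat = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=1)
            feats.append(u.forward(cat, training))
        self._feats = feats
        return np.concatenate(feats, axis=1)

    def backward(self, dout):
        # split relevance of the output concat back onto each produced map
        widths = [self.c_in] + [self.growth] * self.n_units
        splits = np.cumsum(widths)[:-1]
        dfeats = list(np.split(dout, splits, axis=1))
        for i in reversed(range(self.n_units)):
            dcat = self.units[i].backward(dfeats[i + 1])
            w = [self.c_in] + [self.growth] * i
            for j, dpart in enumerate(np.split(dcat, np.cumsum(w)[:-1], axis=1)):
                dfeats[j] = dfeats[j] + dpart
        return dfeats[0]


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

class Model:
    """Sequential classifier: layers -> GlobalAvgPool -> Dense(f, 1) logit.

    The penultimate feature vector is the global-average-pooled activation
    entering the final dense layer.
    """

    def __init__(self, layers: list[Layer], architecture_id: str,
                 input_spec: tuple[int, int, int], feature_dim: int):
        self.layers = layers
        self.architecture_id = architecture_id
        self.input_spec = input_spec  # (H, W, C)
        self.feature_dim = feature_dim

    # -- execution ----------------------------------------------------------
    def _check(self, x):
        h, w, c = self.input_spec
        if x.ndim != 4 or x.shape[1:] != (c, h, w):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match input_spec (C,H,W)=({c},{h},{w})")

    def forward(self, x, training: bool = False) -> np.ndarray:
        """Return pre-sigmoid logits, shape (N, 1)."""
        self._check(x)
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dlogit = l.backward(dlogit)
        return dlogit

    def predict_proba(self, x) -> np.ndarray:
        return sigmoid(self.forward(x, training=False))[:, 0]

    def features(self, x) -> np.ndarray:
        """Penultimate (global-pooled) feature vectors, shape (N, feature_dim)."""
        self._check(x)
        for l in self.layers[:-1]:
            x = l.forward(x, training=False)
        return x

    # -- parameter access ---------------------------------------------------
    def named_params(self) -> "OrderedDict[str, np.ndarray]":
        out = OrderedDict()
        for i, l in enumerate(self.layers):
            for k, v in l.params().items():
                out[f"l{i}_{k}"] = v
            if isinstance(l, BatchNorm2D):
                for k, v in l.extra_state().items():
                    out[f"l{i}_{k}"] = v
        return out

    def param_grad_pairs(self):
        pairs = []
        for l in self.layers:
            p, g = l.params(), l.grads()
            pairs.extend((p[k], g[k]) for k in p)
        return pairs

    def get_weights(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict((k, v.copy()) for k, v in self.named_params().items())

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        own = self.named_params()
        if set(own) != set(weights):
            missing = sorted(set(own) ^ set(weights))
            raise ValueError(f"checkpoint incompatible with model; mismatched keys: {missing[:5]}")
        for k, v in own.items():
            if v.shape != weights[k].shape:
                raise ValueError(f"checkpoint shape mismatch at {k}: {v.shape} vs {weights[k].shape}")
            v[...] = weights[k]

    def fingerprint(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for k, v in self.named_params().items():
            h.update(k.encode())
            h.update(np.ascontiguousarray(v).tobytes())
        return h.hexdigest()[:16]

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path, extra: dict | None = None) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.named_params())
        meta = {
            "architecture_id": self.architecture_id,
            "input_spec": list(self.input_spec),
            "feature_dim": self.feature_dim,
            "fingerprint": self.fingerprint(),
        }
        meta.update(extra or {})
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class Optimizer:
    def step(self, pairs: Iterable[tuple[np.ndarray, np.ndarray]]) -> None:  # pragma: no cover
        raise NotImplementedError


class Adadelta(Optimizer):
    """Adadelta with the original parameter-free step size (lr = 1)."""

    def __init__(self, rho: float = 0.95, eps: float = 1e-6, lr: float = 1.0):
        self.rho, self.eps, self.lr = rho, eps, lr
        self._state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, pairs):
        for p, g in pairs:
            key = id(p)
            if key not in self._state:
                self._state[key] = (np.zeros_like(p, dtype=np.float64),
                                    np.zeros_like(p, dtype=np.float64))
            eg2, edx2 = self._state[key]
            eg2[...] = self.rho * eg2 + (1 - self.rho) * g.astype(np.float64) ** 2
            dx = -np.sqrt(edx2 + self.eps) / np.sqrt(eg2 + self.eps) * g
            edx2[...] = self.rho * edx2 + (1 - self.rho) * dx ** 2
            p += (self.lr * dx).astype(p.dtype)


class Adam(Optimizer):
    def __init__(self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._t = 0

    def step(self, pairs):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self._t
        bias2 = 1 - b2 ** self._t
        for p, g in pairs:
            key = id(p)
            if key not in self._state:
                self._state[key] = (np.zeros_like(p, dtype=np.float64),
                                    np.zeros_like(p, dtype=np.float64))
            m, v = self._state[key]
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g.astype(np.float64) ** 2
            p -= (self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)).astype(p.dtype)
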