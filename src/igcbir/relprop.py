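"""Deep Taylor decomposition for the sigmoid-output classifiers.

Relevance starts at the positive part of the pre-sigmoid logit and is
propagated backward layer by layer:

* hidden linear layers (conv/dense) use the z+ rule
  R_j = a_j Σ_k w_jk^+ / (Σ_j' a_j' w_j'k^+) · R_k  (biases excluded, so
  relevance may shrink but never grow);
* the input layer uses the bounded z^B rule with the input domain [0, 1];
* max pooling routes relevance to the winning position, average pooling
  distributes it proportionally to the activations;
* batch normalization is folded into the propagation as a per-channel
  affine rescaling (its positive scale carried into the adjacent step);
* ReLU is transparent.

All propagation runs in float64 on the model's own cached activations;
the resulting per-pixel map is non-negative and, for bias-free ReLU
networks, sums to the propagated output score (conservation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import nn
from .backbone import to_model_input

_EPS = 1e-9


class UnsupportedLayerError(TypeError):
    """A layer type the relevance propagator does not know how to handle."""


@dataclass(frozen=True)
class SaliencyMap:
    relevance: np.ndarray  # 2-D, non-negative
    total_relevance: float
    source_model: str
    source_sample: str = ""

    def __post_init__(self):
        if np.any(self.relevance < 0):
            raise ValueError("saliency relevance must be non-negative")


@dataclass(frozen=True)
class PropagationRule:
    rule_id: str  # "z_plus" or "z_bounded"
    bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.rule_id not in ("z_plus", "z_bounded"):
            raise ValueError(f"unknown rule_id {self.rule_id!r}")
        if self.rule_id == "z_bounded" and not self.bounds[0] < self.bounds[1]:
            raise ValueError(f"z_bounded requires low < high, got {self.bounds}")


# ---------------------------------------------------------------------------
# Per-layer rules
# ---------------------------------------------------------------------------

def _conv_fwd(layer: nn.Conv2D, a: np.ndarray, w: np.ndarray) -> np.ndarray:
    cols = nn_cols = nn._im2col(a, layer.k, layer.k, layer.stride, layer.pad)
    out = nn_cols @ w.reshape(layer.c_out, -1).T
    oh, ow = nn._out_hw(a.shape[2], a.shape[3], layer.k, layer.stride, layer.pad)
    return out.transpose(0, 2, 1).reshape(a.shape[0], layer.c_out, oh, ow)


def _conv_bwd(layer: nn.Conv2D, s: np.ndarray, w: np.ndarray, x_shape) -> np.ndarray:
    n = s.shape[0]
    sflat = s.reshape(n, layer.c_out, -1).transpose(0, 2, 1)
    dcols = sflat @ w.reshape(layer.c_out, -1)
    return nn._col2im(dcols, x_shape, layer.k, layer.k, layer.stride, layer.pad)


def _prop_conv_zplus(layer: nn.Conv2D, R: np.ndarray) -> np.ndarray:
    a = np.maximum(layer.last_input, 0.0)
    wp = np.maximum(layer.W.astype(np.float64), 0.0)
    bp = np.maximum(layer.b.astype(np.float64), 0.0)
    z = _conv_fwd(layer, a, wp) + bp[None, :, None, None] + _EPS
    s = R / z
    return a * _conv_bwd(layer, s, wp, a.shape)


def _prop_conv_zbounded(layer: nn.Conv2D, R: np.ndarray, low: float, high: float) -> np.ndarray:
    x = layer.last_input.astype(np.float64)
    w = layer.W.astype(np.float64)
    wp, wm = np.maximum(w, 0.0), np.minimum(w, 0.0)
    l = np.full_like(x, low)
    h = np.full_like(x, high)
    z = (_conv_fwd(layer, x, w) - _conv_fwd(layer, l, wp) - _conv_fwd(layer, h, wm)
         + np.maximum(layer.b.astype(np.float64), 0.0)[None, :, None, None] + _EPS)
    s = R / z
    return (x * _conv_bwd(layer, s, w, x.shape)
            - l * _conv_bwd(layer, s, wp, x.shape)
            - h * _conv_bwd(layer, s, wm, x.shape))


def _prop_dense_zplus(layer: nn.Dense, R: np.ndarray) -> np.ndarray:
    a = np.maximum(layer.last_input, 0.0)
    wp = np.maximum(layer.W.astype(np.float64), 0.0)
    z = a @ wp + np.maximum(layer.b.astype(np.float64), 0.0) + _EPS
    s = R / z
    return a * (s @ wp.T)


def _prop_maxpool(layer: nn.MaxPool2D, R: np.ndarray) -> np.ndarray:
    # winner-take-all: relevance follows the pooled argmax
    return layer.backward(R)


def _prop_avgpool(layer: nn.AvgPool2D, R: np.ndarray) -> np.ndarray:
    s = layer.size
    a = np.maximum(layer.last_input, 0.0)
    n, c, h, w = a.shape
    denom = a.reshape(n, c, h // s, s, w // s, s).sum(axis=(3, 5)) + _EPS
    return a * np.repeat(np.repeat(R / denom, s, axis=2), s, axis=3)


def _prop_gap(layer: nn.GlobalAvgPool, R: np.ndarray) -> np.ndarray:
    a = np.maximum(layer.last_input, 0.0)
    denom = a.sum(axis=(2, 3)) + _EPS
    return a * (R / denom)[:, :, None, None]


def _prop_batchnorm(layer: nn.BatchNorm2D, R: np.ndarray) -> np.ndarray:
    # per-channel affine y = g·x + c with g = gamma/sqrt(var+eps); z+ on the
    # diagonal positive scale: relevance passes where the folded scale and the
    # activation are positive, is dropped otherwise.
    g = (layer.gamma / np.sqrt(layer.running_var + layer.eps)).astype(np.float64)
    a = np.maximum(layer.last_input, 0.0)
    z = a * np.maximum(g, 0.0)[None, :, None, None]
    return z / (z + _EPS) * R


def _prop_denseblock(layer: nn.DenseBlock, R: np.ndarray) -> np.ndarray:
    widths = [layer.c_in] + [layer.growth] * layer.n_units
    r_feats = list(np.split(R, np.cumsum(widths)[:-1], axis=1))
    for i in reversed(range(layer.n_units)):
        r = r_feats[i + 1]
        for sub in reversed(layer.units[i].sub):
            r = _prop_hidden(sub, r)
        w = [layer.c_in] + [layer.growth] * i
        for j, part in enumerate(np.split(r, np.cumsum(w)[:-1], axis=1)):
            r_feats[j] = r_feats[j] + part
    return r_feats[0]


def _prop_hidden(layer: nn.Layer, R: np.ndarray) -> np.ndarray:
    if isinstance(layer, nn.Conv2D):
        return _prop_conv_zplus(layer, R)
    if isinstance(layer, nn.Dense):
        return _prop_dense_zplus(layer, R)
    if isinstance(layer, nn.ReLU):
        return R
    if isinstance(layer, nn.MaxPool2D):
        return _prop_maxpool(layer, R)
    if isinstance(layer, nn.AvgPool2D):
        return _prop_avgpool(layer, R)
    if isinstance(layer, nn.GlobalAvgPool):
        return _prop_gap(layer, R)
    if isinstance(layer, nn.BatchNorm2D):
        return _prop_batchnorm(layer, R)
    if isinstance(layer, nn.DenseBlock):
        return _prop_denseblock(layer, R)
    raise UnsupportedLayerError(f"no relevance rule for layer type {type(layer).__name__}")


# ---------------------------------------------------------------------------
# Full propagation
# ---------------------------------------------------------------------------

def _propagate(model: nn.Model, x: np.ndarray,
               input_rule: PropagationRule) -> tuple[np.ndarray, list[float]]:
    """Run a float64 forward pass, then the relevance backward pass.

    Returns per-input-element relevance (N,C,H,W) and the layer-wise totals
    from output to input (length = number of layers + 1).
    """
    logit = model.forward(x.astype(np.float64), training=False)
    R = np.maximum(logit, 0.0)  # relevance seed: positive part of the logit
    totals = [float(R.sum())]
    first_conv = next((l for l in model.layers if isinstance(l, nn.Conv2D)), None)
    for layer in reversed(model.layers):
        if layer is first_conv and input_rule.rule_id == "z_bounded":
            R = _prop_conv_zbounded(layer, R, *input_rule.bounds)
        else:
            R = _prop_hidden(layer, R)
        totals.append(float(R.sum()))
    return R, totals


def deep_taylor(model: nn.Model, image: np.ndarray, sample_id: str = "",
                input_rule: PropagationRule | None = None) -> SaliencyMap:
    """Saliency map S(θ, I): non-negative per-pixel relevance, channels summed."""
    input_rule = input_rule or PropagationRule("z_bounded", (0.0, 1.0))
    x = to_model_input(image, model.input_spec)
    R, _ = _propagate(model, x, input_rule)
    rel = np.maximum(R[0].sum(axis=0), 0.0)
    return SaliencyMap(relevance=rel, total_relevance=float(rel.sum()),
                       source_model=model.architecture_id, source_sample=sample_id)


def deep_taylor_batch(model: nn.Model, images: np.ndarray, sample_ids: list[str] | None = None,
                      input_rule: PropagationRule | None = None,
                      chunk: int = 16) -> list[SaliencyMap]:
    """Saliency maps for a stack of images, propagated in small batches."""
    input_rule = input_rule or PropagationRule("z_bounded", (0.0, 1.0))
    images = np.asarray(images)
    sample_ids = sample_ids or [""] * len(images)
    out = []
    for start in range(0, len(images), chunk):
        x = to_model_input(images[start:start + chunk], model.input_spec)
        R, _ = _propagate(model, x, input_rule)
        for j in range(R.shape[0]):
            rel = np.maximum(R[j].sum(axis=0), 0.0)
            out.append(SaliencyMap(relevance=rel, total_relevance=float(rel.sum()),
                                   source_model=model.architecture_id,
                                   source_sample=sample_ids[start + j]))
    return out


def conservation_report(model: nn.Model, image: np.ndarray,
                        input_rule: PropagationRule | None = None) -> pd.DataFrame:
    """Layer-wise relevance totals from output to input.

    One row per propagation step (the first row is the output seed);
    ``increased`` flags steps where total relevance grew, which the z+ and
    bounded rules forbid up to numerical tolerance.
    """
    input_rule = input_rule or PropagationRule("z_bounded", (0.0, 1.0))
    x = to_model_input(image, model.input_spec)
    _, totals = _propagate(model, x, input_rule)
    names = ["output_seed"] + [type(l).__name__ for l in reversed(model.layers)]
    increased = [False] + [totals[i + 1] > totals[i] * (1 + 1e-9) + 1e-12
                           for i in range(len(totals) - 1)]
    return pd.DataFrame({"layer": names, "total_relevance": totals, "increased": increased})


def to_input_image(saliency: SaliencyMap, model_input_spec: tuple[int, int, int],
                   max_value: float | None = None) -> np.ndarray:
    """Rescale a saliency map to [0, 1] and replicate across channels.

    By default the map is rescaled by its own maximum (all-zero maps pass
    through unchanged).  When a set of maps feeds a network whose feature
    distances are compared across images, pass a shared ``max_value`` so
    the maps keep their relative amplitude — total relevance tracks the
    classifier's evidence, and per-map normalization would erase exactly
    the graded signal the saliency-trained retrieval relies on.
    Returns a (C, H, W) float32 array ready to be batched as model input.
    """
    h, w, c = model_input_spec
    if saliency.relevance.shape != (h, w):
        raise ValueError(
            f"saliency shape {saliency.relevance.shape} does not match input_spec {(h, w)}")
    m = saliency.relevance.max() if max_value is None else max_value
    # the default path is bounded by construction; a shared scale must not
    # clip, or amplitudes above the reference set's maximum lose their order
    norm = saliency.relevance / m if m > 0 else saliency.relevance
    return np.repeat(norm[None, :, :], c, axis=0).astype(np.float32)


# ---------------------------------------------------------------------------
# Saliency IO (16-bit PNG + sidecar JSON)
# ---------------------------------------------------------------------------

def write_saliency(saliency: SaliencyMap, path: str | Path) -> None:
    path = Path(path)
    m = float(saliency.relevance.max())
    scaled = (saliency.relevance / m * 65535.0 if m > 0
              else saliency.relevance).astype(np.uint16)
    Image.fromarray(scaled).save(path.with_suffix(".png"))
    path.with_suffix(".json").write_text(json.dumps({
        "sample_id": saliency.source_sample,
        "source_model": saliency.source_model,
        "max_relevance": m,
        "total_relevance": saliency.total_relevance,
    }))


def read_saliency(path: str | Path) -> SaliencyMap:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arr = np.asarray(Image.open(path.with_suffix(".png")), dtype=np.float64)
    rel = arr / 65535.0 * meta["max_relevance"]
    return SaliencyMap(relevance=rel, total_relevance=float(rel.sum()),
                       source_model=meta["source_model"], source_sample=meta["sample_id"])
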