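"""Attention-driven comparator: self-attention plus multi-level attention.

The ATT method classifies with the same dense-block trunk as the plain
backbone, but taps feature maps at several depths, refines each tap with
dot-product self-attention over spatial positions, projects the refined
taps to a common channel width, resizes them (bilinear) to the finest
tap's grid, and fuses them with a per-position softmax gate across
levels.  Global average pooling of the fused map gives the penultimate
embedding A(θ_ATT, I) used for retrieval distances.

This is a faithful-but-configurable variant of the multi-level
dual-attention design the comparator derives from: the reference
architecture is specified only by its tap shapes (for DenseNet-121 at
224² input: [512, 28, 28], [1024, 14, 14], [1024, 7, 7]), which the
``densenet121`` trunk here reproduces exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .backbone import ArchitectureError, _check_input_spec


@dataclass(frozen=True)
class AttentionConfig:
    tap_points: tuple[int, ...] = (0, 1)  # indices into the architecture's tap stages
    tap_channels: tuple[int, ...] | None = None  # expected channels; validated if given
    fusion_dim: int | None = None  # default: finest tap's channel count
    seed: int = 0

    def validate(self) -> None:
        if len(self.tap_points) < 2:
            raise ArchitectureError(f"need >= 2 tap points, got {self.tap_points}")
        if list(self.tap_points) != sorted(set(self.tap_points)):
            raise ArchitectureError(f"tap_points must be strictly increasing, got {self.tap_points}")


# ---------------------------------------------------------------------------
# Attention layers
# ---------------------------------------------------------------------------

class SelfAttention2D(nn.Layer):
    """Residual dot-product self-attention over spatial positions.

    Q/K project to ``d_qk`` channels, V preserves the channel count; the
    softmax-normalized attention matrix re-weights V and the result is
    added back to the input.
    """

    def __init__(self, c: int, d_qk: int, rng: np.random.Generator):
        self.c, self.d_qk = c, d_qk
        sd = np.sqrt(1.0 / c)
        self.Wq = rng.normal(0, sd, (c, d_qk)).astype(nn.DTYPE)
        self.Wk = rng.normal(0, sd, (c, d_qk)).astype(nn.DTYPE)
        self.Wv = rng.normal(0, sd, (c, c)).astype(nn.DTYPE)
        self.dWq = np.zeros_like(self.Wq)
        self.dWk = np.zeros_like(self.Wk)
        self.dWv = np.zeros_like(self.Wv)
        self.last_attention: np.ndarray | None = None  # (N, P, P), rows sum to 1

    def params(self):
        return {"Wq": self.Wq, "Wk": self.Wk, "Wv": self.Wv}

    def grads(self):
        return {"Wq": self.dWq, "Wk": self.dWk, "Wv": self.dWv}

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        self._shape = (n, c, h, w)
        xf = x.reshape(n, c, h * w).transpose(0, 2, 1)  # (N, P, C)
        self._xf = xf
        q = xf @ self.Wq.astype(x.dtype)
        k = xf @ self.Wk.astype(x.dtype)
        v = xf @ self.Wv.astype(x.dtype)
        e = q @ k.transpose(0, 2, 1) / np.sqrt(self.d_qk)
        e -= e.max(axis=-1, keepdims=True)
        a = np.exp(e)
        a /= a.sum(axis=-1, keepdims=True)
        self._q, self._k, self._v, self._a = q, k, v, a
        self.last_attention = a
        out = a @ v  # (N, P, C)
        return x + out.transpose(0, 2, 1).reshape(n, c, h, w)

    def backward(self, dout):
        n, c, h, w = self._shape
        do = dout.reshape(n, c, h * w).transpose(0, 2, 1)  # (N, P, C)
        da = do @ self._v.transpose(0, 2, 1)
        dv = self._a.transpose(0, 2, 1) @ do
        de = self._a * (da - (da * self._a).sum(axis=-1, keepdims=True))
        de /= np.sqrt(self.d_qk)
        dq = de @ self._k
        dk = de.transpose(0, 2, 1) @ self._q
        self.dWq[...] = np.tensordot(self._xf, dq, axes=([0, 1], [0, 1]))
        self.dWk[...] = np.tensordot(self._xf, dk, axes=([0, 1], [0, 1]))
        self.dWv[...] = np.tensordot(self._xf, dv, axes=([0, 1], [0, 1]))
        dxf = dq @ self.Wq.T + dk @ self.Wk.T + dv @ self.Wv.T
        return dout + dxf.transpose(0, 2, 1).reshape(n, c, h, w)


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic separable bilinear interpolation matrix (n_out, n_in)."""
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    for i in range(n_out):
        src = (i + 0.5) * n_in / n_out - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        f = int(np.floor(src))
        t = src - f
        if f + 1 < n_in:
            m[i, f], m[i, f + 1] = 1 - t, t
        else:
            m[i, f] = 1.0
    return m


class MultiLevelFusion(nn.Layer):
    """Project taps to a common width, resize to the finest grid, gate-fuse.

    Gates are a softmax across levels at every spatial position, so they
    sum to one position-wise; fusion is the gated sum followed by ReLU.
    """

    def __init__(self, tap_shapes: list[tuple[int, int, int]], fusion_dim: int,
                 rng: np.random.Generator):
        self.tap_shapes = tap_shapes
        self.fusion_dim = fusion_dim
        self.out_hw = tap_shapes[0][1:]  # finest grid: the shallowest, highest-resolution tap
        self.proj_W = [rng.normal(0, np.sqrt(2.0 / c), (c, fusion_dim)).astype(nn.DTYPE)
                       for c, _, _ in tap_shapes]
        self.proj_b = [np.zeros(fusion_dim, dtype=nn.DTYPE) for _ in tap_shapes]
        self.score_w = [rng.normal(0, np.sqrt(1.0 / fusion_dim), fusion_dim).astype(nn.DTYPE)
                        for _ in tap_shapes]
        self.score_b = [np.zeros(1, dtype=nn.DTYPE) for _ in tap_shapes]
        self._resize = [( _bilinear_matrix(self.out_hw[0], h), _bilinear_matrix(self.out_hw[1], w))
                        for _, h, w in tap_shapes]
        self.last_gates: np.ndarray | None = None  # (N, L, H*, W*), sums to 1 over L

    def params(self):
        out = {}
        for i in range(len(self.tap_shapes)):
            out[f"proj_W{i}"] = self.proj_W[i]
            out[f"proj_b{i}"] = self.proj_b[i]
            out[f"score_w{i}"] = self.score_w[i]
            out[f"score_b{i}"] = self.score_b[i]
        return out

    def grads(self):
        out = {}
        for i in range(len(self.tap_shapes)):
            out[f"proj_W{i}"] = self.dproj_W[i]
            out[f"proj_b{i}"] = self.dproj_b[i]
            out[f"score_w{i}"] = self.dscore_w[i]
            out[f"score_b{i}"] = self.dscore_b[i]
        return out

    def forward(self, taps: list[np.ndarray], training=False):
        n = taps[0].shape[0]
        ho, wo = self.out_hw
        us, scores = [], []
        self._taps = taps
        for i, t in enumerate(taps):
            c, h, w = t.shape[1:]
            tf = t.reshape(n, c, h * w).transpose(0, 2, 1)
            u = tf @ self.proj_W[i].astype(t.dtype) + self.proj_b[i].astype(t.dtype)
            u = u.transpose(0, 2, 1).reshape(n, self.fusion_dim, h, w)
            ah, aw = self._resize[i]
            u = np.einsum("oh,nchw,pw->ncop", ah.astype(t.dtype), u, aw.astype(t.dtype),
                          optimize=True)
            s = np.einsum("nchw,c->nhw", u, self.score_w[i].astype(t.dtype)) + self.score_b[i]
            us.append(u)
            scores.append(s)
        e = np.stack(scores, axis=1)  # (N, L, H*, W*)
        e -= e.max(axis=1, keepdims=True)
        g = np.exp(e)
        g /= g.sum(axis=1, keepdims=True)
        self._us, self._g = us, g
        self.last_gates = g
        fused = sum(g[:, i:i + 1] * us[i] for i in range(len(us)))
        self._fused_pre = fused
        return np.maximum(fused, 0)

    def backward(self, dout) -> list[np.ndarray]:
        dout = dout * (self._fused_pre > 0)
        L = len(self._us)
        n = dout.shape[0]
        self.dproj_W = [np.zeros_like(w) for w in self.proj_W]
        self.dproj_b = [np.zeros_like(b) for b in self.proj_b]
        self.dscore_w = [np.zeros_like(w) for w in self.score_w]
        self.dscore_b = [np.zeros_like(b) for b in self.score_b]
        dscores = np.empty_like(self._g)
        dus = []
        for i in range(L):
            dus.append(self._g[:, i:i + 1] * dout)
            dscores[:, i] = np.einsum("nchw,nchw->nhw", dout, self._us[i])
        dg = dscores
        de = self._g * (dg - (dg * self._g).sum(axis=1, keepdims=True))
        dtaps = []
        for i in range(L):
            du = dus[i] + de[:, i][:, None] * self.score_w[i][None, :, None, None]
            self.dscore_w[i][...] = np.einsum("nchw,nhw->c", self._us[i], de[:, i])
            self.dscore_b[i][...] = de[:, i].sum()
            ah, aw = self._resize[i]
            # adjoint of the separable bilinear resize
            du_small = np.einsum("oh,ncop,pw->nchw", ah.astype(du.dtype), du,
                                 aw.astype(du.dtype), optimize=True)
            c, h, w = self.tap_shapes[i]
            duf = du_small.reshape(n, self.fusion_dim, h * w).transpose(0, 2, 1)
            tf = self._taps[i].reshape(n, c, h * w).transpose(0, 2, 1)
            self.dproj_W[i][...] = np.tensordot(tf, duf, axes=([0, 1], [0, 1]))
            self.dproj_b[i][...] = duf.sum(axis=(0, 1))
            dtf = duf @ self.proj_W[i].T
            dtaps.append(dtf.transpose(0, 2, 1).reshape(n, c, h, w))
        return dtaps


# ---------------------------------------------------------------------------
# Trunk tap stages
# ---------------------------------------------------------------------------

def _tiny_stages(input_spec, rng) -> tuple[list[list[nn.Layer]], list[tuple[int, int, int]]]:
    h, w, _ = input_spec
    seg0 = [nn.Conv2D(1, 16, 3, stride=2, pad=1, rng=rng), nn.ReLU(), nn.MaxPool2D(2),
            nn.DenseBlock(16, 2, 16, rng),
            nn.Conv2D(48, 32, 1, rng=rng), nn.ReLU(), nn.AvgPool2D(2)]
    seg1 = [nn.DenseBlock(32, 2, 16, rng),
            nn.Conv2D(64, 64, 1, rng=rng), nn.ReLU(), nn.AvgPool2D(2)]
    shapes = [(32, h // 8, w // 8), (64, h // 16, w // 16)]
    return [seg0, seg1], shapes


def _densenet121_stages(input_spec, rng) -> tuple[list[list[nn.Layer]], list[tuple[int, int, int]]]:
    h, w, _ = input_spec
    g = 32
    seg0 = [nn.Conv2D(3, 2 * g, 7, stride=2, pad=3, rng=rng),
            nn.BatchNorm2D(2 * g), nn.ReLU(), nn.MaxPool2D(2),
            nn.DenseBlock(2 * g, 6, g, rng, use_bn=True, bottleneck=True),        # 256
            nn.BatchNorm2D(256), nn.ReLU(), nn.Conv2D(256, 128, 1, rng=rng), nn.AvgPool2D(2),
            nn.DenseBlock(128, 12, g, rng, use_bn=True, bottleneck=True)]         # 512 @ h/8
    seg1 = [nn.BatchNorm2D(512), nn.ReLU(), nn.Conv2D(512, 256, 1, rng=rng), nn.AvgPool2D(2),
            nn.DenseBlock(256, 24, g, rng, use_bn=True, bottleneck=True)]         # 1024 @ h/16
    seg2 = [nn.BatchNorm2D(1024), nn.ReLU(), nn.Conv2D(1024, 512, 1, rng=rng), nn.AvgPool2D(2),
            nn.DenseBlock(512, 16, g, rng, use_bn=True, bottleneck=True)]         # 1024 @ h/32
    shapes = [(512, h // 8, w // 8), (1024, h // 16, w // 16), (1024, h // 32, w // 32)]
    return [seg0, seg1, seg2], shapes


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class AttentionModel(nn.Model):
    """Classifier with self-attention taps and multi-level gated fusion.

    Duck-types :class:`igcbir.nn.Model` so the backbone module's ``train``
    works unchanged; ``features`` returns the fused, pooled embedding.
    """

    def __init__(self, segments, att_layers, fusion, architecture_id, input_spec,
                 config: AttentionConfig):
        self.segments = segments
        self.att = att_layers
        self.fusion = fusion
        self.gap = nn.GlobalAvgPool()
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 77])
        self.head = nn.Dense(fusion.fusion_dim, 1, rng=rng)
        flat = [l for seg in segments for l in seg] + list(att_layers) + [fusion, self.gap, self.head]
        super().__init__(flat, architecture_id, tuple(input_spec), fusion.fusion_dim)
        self.attention_config = config

    def forward(self, x, training=False):
        self._check(x)
        taps = []
        h = x
        for seg in self.segments:
            for l in seg:
                h = l.forward(h, training)
            taps.append(h)
        refined = [att.forward(t, training) for att, t in zip(self.att, taps)]
        fused = self.fusion.forward(refined, training)
        return self.head.forward(self.gap.forward(fused, training), training)

    def backward(self, dlogit):
        dfused = self.gap.backward(self.head.backward(dlogit))
        drefined = self.fusion.backward(dfused)
        dtaps = [att.backward(dr) for att, dr in zip(self.att, drefined)]
        d = dtaps[-1]
        for i in reversed(range(len(self.segments))):
            for l in reversed(self.segments[i]):
                d = l.backward(d)
            if i > 0:
                d = d + dtaps[i - 1]
        return d

    def features(self, x):
        self._check(x)
        taps = []
        h = x
        for seg in self.segments:
            for l in seg:
                h = l.forward(h, training=False)
            taps.append(h)
        refined = [att.forward(t, False) for att, t in zip(self.att, taps)]
        return self.gap.forward(self.fusion.forward(refined, False), False)

    def save(self, path, extra=None):
        cfg = self.attention_config
        meta = {"attention": True,
                "attention_config": {"tap_points": list(cfg.tap_points),
                                     "tap_channels": list(cfg.tap_channels) if cfg.tap_channels else None,
                                     "fusion_dim": cfg.fusion_dim,
                                     "seed": cfg.seed}}
        meta.update(extra or {})
        super().save(path, extra=meta)


def build_attention_model(architecture_id: str, input_spec: tuple[int, int, int],
                          config: AttentionConfig | None = None) -> AttentionModel:
    """Construct the untrained ATT classifier for a supported trunk."""
    config = config or AttentionConfig()
    if isinstance(config.tap_points, list):
        config = AttentionConfig(tuple(config.tap_points),
                                 tuple(config.tap_channels) if config.tap_channels else None,
                                 config.fusion_dim, config.seed)
    config.validate()
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 1234])
    if architecture_id == "tiny":
        _check_input_spec(input_spec, 16, 1)
        stages, shapes = _tiny_stages(input_spec, rng)
    elif architecture_id == "densenet121":
        _check_input_spec(input_spec, 32, 3)
        stages, shapes = _densenet121_stages(input_spec, rng)
    else:
        raise ArchitectureError(f"unknown architecture_id {architecture_id!r}")
    if max(config.tap_points) >= len(stages):
        raise ArchitectureError(
            f"tap_points {config.tap_points} out of range for {architecture_id} "
            f"({len(stages)} tap stages)")
    # merge untapped trailing stages into the previous segment is not needed:
    # taps must include consecutive stages ending at the last one
    segments = [stages[i] for i in range(len(stages))]
    tap_idx = list(config.tap_points)
    # collapse: segments between taps are concatenated
    merged, shapes_sel, cur = [], [], []
    for i, seg in enumerate(segments):
        cur.extend(seg)
        if i in tap_idx:
            merged.append(cur)
            shapes_sel.append(shapes[i])
            cur = []
    if cur:  # trailing untapped stages would be dead weight
        raise ArchitectureError(
            f"tap_points must include the deepest stage {len(stages) - 1}, got {config.tap_points}")
    if config.tap_channels is not None:
        expected = tuple(s[0] for s in shapes_sel)
        if tuple(config.tap_channels) != expected:
            raise ArchitectureError(
                f"tap_channels {config.tap_channels} do not match architecture taps {expected}")
    fusion_dim = config.fusion_dim or shapes_sel[0][0]
    att_layers = [SelfAttention2D(c, d_qk=max(8, c // 4), rng=rng) for c, _, _ in shapes_sel]
    fusion = MultiLevelFusion(shapes_sel, fusion_dim, rng)
    return AttentionModel(merged, att_layers, fusion, architecture_id, input_spec, config)


def extract_att_features(model: AttentionModel, image: np.ndarray) -> np.ndarray:
    """Penultimate fused embedding A(θ_ATT, I); deterministic inference."""
    from .backbone import to_model_input
    x = to_model_input(image, model.input_spec)
    feats = model.features(x)
    return feats[0] if np.asarray(image).ndim == 2 else feats
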