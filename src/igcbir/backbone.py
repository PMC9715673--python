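"""Binary-classification CNN backbones and their training protocol.

The retrieval methods all ride on a sigmoid-output convolutional
classifier: global average pooling produces the penultimate feature
vector F(θ, I) used as the image embedding.  Two architectures are
registered:

* ``densenet121`` — the standard DenseNet-121 layer plan (growth 32,
  bottleneck blocks of 6/12/24/16 units, halving transitions), whose
  penultimate width works out to 1024 channels.
* ``tiny`` — a reduced dense-block network (two 2-unit blocks, growth 16)
  sized so the full benchmark trains on a single CPU in minutes.

Training minimizes (optionally class-weighted) binary cross-entropy with
light rotation/translation augmentation; the checkpoint kept is the epoch
with the best validation F1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.metrics import f1_score as _sk_f1

from . import nn

EPS_PROB = 1e-7


class ArchitectureError(ValueError):
    pass


class CheckpointError(ValueError):
    pass


class WeightingError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    batch_size: int = 32
    optimizer: str = "adadelta"  # or "adam"
    learning_rate: float = 1e-4  # used by adam
    class_weighting: bool = True
    augment_rotation_deg: float = 10.0
    augment_translate_frac: float = 0.05
    init_from: str | Path | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.optimizer not in ("adadelta", "adam"):
            raise ValueError(f"optimizer must be 'adadelta' or 'adam', got {self.optimizer!r}")
        if self.optimizer == "adam" and self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0 for adam, got {self.learning_rate}")


@dataclass
class TrainingLog:
    records: pd.DataFrame  # columns: epoch, loss, val_f1, selected
    selected_epoch: int
    init_fingerprint: str | None = None

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Architectures
# ---------------------------------------------------------------------------

def build_backbone(architecture_id: str, input_spec: tuple[int, int, int] | None = None,
                   feature_dim: int = 64, seed: int = 0) -> nn.Model:
    """Construct an untrained classifier ending in GAP -> Dense(f, 1).

    ``input_spec`` is (height, width, channels); the penultimate feature
    width is derived from the layer plan, not asserted.
    """
    if architecture_id == "tiny":
        return _build_tiny(input_spec or (96, 96, 1), feature_dim, seed)
    if architecture_id == "densenet121":
        return _build_densenet121(input_spec or (224, 224, 3), seed)
    raise ArchitectureError(f"unknown architecture_id {architecture_id!r}")


def _check_input_spec(input_spec, divisor, channels):
    h, w, c = input_spec
    if c != channels:
        raise ArchitectureError(f"input_spec channels must be {channels}, got {c}")
    if h < 32 or w < 32 or h % divisor or w % divisor:
        raise ArchitectureError(
            f"input_spec spatial dims must be >= 32 and divisible by {divisor}, got {(h, w)}")


def _build_tiny(input_spec, feature_dim, seed) -> nn.Model:
    _check_input_spec(input_spec, 16, 1)
    if feature_dim < 1:
        raise ArchitectureError(f"feature_dim must be >= 1, got {feature_dim}")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 42])
    layers: list[nn.Layer] = [
        nn.Conv2D(1, 16, 3, stride=2, pad=1, rng=rng), nn.ReLU(), nn.MaxPool2D(2),
        nn.DenseBlock(16, 2, 16, rng),                       # -> 48 channels
        nn.Conv2D(48, 32, 1, rng=rng), nn.ReLU(), nn.AvgPool2D(2),
        nn.DenseBlock(32, 2, 16, rng),                       # -> 64 channels
        nn.Conv2D(64, feature_dim, 1, rng=rng), nn.ReLU(), nn.AvgPool2D(2),
        nn.GlobalAvgPool(),
        nn.Dense(feature_dim, 1, rng=rng),
    ]
    return nn.Model(layers, "tiny", tuple(input_spec), feature_dim)


def _build_densenet121(input_spec, seed) -> nn.Model:
    _check_input_spec(input_spec, 32, 3)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 121])
    growth, plan = 32, (6, 12, 24, 16)
    layers: list[nn.Layer] = [
        nn.Conv2D(3, 2 * growth, 7, stride=2, pad=3, rng=rng),
        nn.BatchNorm2D(2 * growth), nn.ReLU(), nn.MaxPool2D(2),
    ]
    c = 2 * growth
    for bi, n_units in enumerate(plan):
        layers.append(nn.DenseBlock(c, n_units, growth, rng, use_bn=True, bottleneck=True))
        c += n_units * growth
        if bi < len(plan) - 1:  # transition: BN-ReLU-1x1 halving conv-avgpool
            layers += [nn.BatchNorm2D(c), nn.ReLU(), nn.Conv2D(c, c // 2, 1, rng=rng),
                       nn.AvgPool2D(2)]
            c //= 2
    layers += [nn.BatchNorm2D(c), nn.ReLU(), nn.GlobalAvgPool(), nn.Dense(c, 1, rng=rng)]
    return nn.Model(layers, "densenet121", tuple(input_spec), c)


# ---------------------------------------------------------------------------
# Loss and metrics
# ---------------------------------------------------------------------------

def class_weights(labels: np.ndarray) -> tuple[float, float]:
    """Inverse-frequency weights w_c = N / (2 N_c); balanced data gives (1, 1)."""
    labels = np.asarray(labels)
    n_neg = int((labels == 0).sum())
    n_pos = int((labels == 1).sum())
    if n_neg == 0 or n_pos == 0:
        raise WeightingError("class weighting requires both classes in the training data")
    n = n_neg + n_pos
    return n / (2.0 * n_neg), n / (2.0 * n_pos)


def weighted_bce(y, p, weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """Class-weighted binary cross-entropy −w_y (y ln p + (1−y) ln(1−p)).

    With unit weights this is plain binary cross-entropy.  Array inputs
    return the mean over samples; probabilities are clamped to
    [1e−7, 1−1e−7] before the logarithm.
    """
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary (0 or 1)")
    p = np.clip(p, EPS_PROB, 1.0 - EPS_PROB)
    w = np.where(y == 1, weights[1], weights[0])
    loss = -w * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(np.mean(loss))


def f1_score(predictions, labels, threshold: float = 0.5) -> float:
    """F1 = 2 · precision · recall / (precision + recall); 0 when undefined."""
    predictions = np.asarray(predictions, dtype=np.float64)
    labels = np.asarray(labels)
    if predictions.size == 0 or predictions.shape != labels.shape:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    return float(_sk_f1(labels, (predictions >= threshold).astype(int), zero_division=0))


# ---------------------------------------------------------------------------
# Data plumbing
# ---------------------------------------------------------------------------

def to_model_input(images: np.ndarray, input_spec: tuple[int, int, int]) -> np.ndarray:
    """(N,H,W) or (H,W) grayscale -> (N,C,H,W) float32, channel-replicated."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    h, w, c = input_spec
    if images.shape[1:] != (h, w):
        raise ValueError(f"image spatial shape {images.shape[1:]} does not match input_spec {(h, w)}")
    return np.repeat(images[:, None, :, :], c, axis=1)


def samples_to_arrays(samples, input_spec) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(samples, tuple) and len(samples) == 2:
        images, labels = samples
    else:
        images = np.stack([s.image for s in samples])
        labels = np.array([s.label for s in samples])
    return to_model_input(images, input_spec), np.asarray(labels, dtype=np.float64)


def _augment_batch(x: np.ndarray, config: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    if config.augment_rotation_deg == 0 and config.augment_translate_frac == 0:
        return x
    out = np.empty_like(x)
    h, w = x.shape[2], x.shape[3]
    for i in range(x.shape[0]):
        angle = rng.uniform(-config.augment_rotation_deg, config.augment_rotation_deg)
        dy = rng.uniform(-config.augment_translate_frac, config.augment_translate_frac) * h
        dx = rng.uniform(-config.augment_translate_frac, config.augment_translate_frac) * w
        img = ndimage.rotate(x[i, 0], angle, reshape=False, order=1, mode="nearest")
        img = ndimage.shift(img, (dy, dx), order=1, mode="nearest")
        out[i] = img[None]
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(model: nn.Model, train_samples, val_samples,
          config: TrainConfig) -> tuple[nn.Model, TrainingLog]:
    """Train for the configured epochs, returning the best-validation-F1 epoch.

    Ties in validation F1 select the earlier epoch.  ``init_from`` warm-starts
    the weights from a previous checkpoint (cross-condition pretraining).
    """
    config.validate()
    x_tr, y_tr = samples_to_arrays(train_samples, model.input_spec)
    x_va, y_va = samples_to_arrays(val_samples, model.input_spec)
    if len(y_tr) == 0 or len(y_va) == 0:
        raise ValueError("train and validation splits must be non-empty")

    init_fp = None
    if config.init_from is not None:
        ref = load_checkpoint(config.init_from)
        try:
            model.set_weights(ref.get_weights())
        except ValueError as e:
            raise CheckpointError(str(e)) from e
        init_fp = ref.fingerprint()

    if config.class_weighting:
        w = class_weights(y_tr)
    else:
        w = (1.0, 1.0)

    opt = (nn.Adam(lr=config.learning_rate) if config.optimizer == "adam"
           else nn.Adadelta())
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 31337])

    best_f1, best_epoch, best_weights = -1.0, -1, None
    rows = []
    n = len(y_tr)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = _augment_batch(x_tr[idx], config, rng)
            yb = y_tr[idx]
            logits = model.forward(xb, training=True)
            p = nn.sigmoid(logits)[:, 0]
            losses.append(weighted_bce(yb, p, w))
            wb = np.where(yb == 1, w[1], w[0])
            dlogit = (wb * (np.clip(p, EPS_PROB, 1 - EPS_PROB) - yb) / len(yb))[:, None]
            model.backward(dlogit.astype(np.float32))
            opt.step(model.param_grad_pairs())
        val_f1 = f1_score(_predict_in_batches(model, x_va), y_va)
        rows.append({"epoch": epoch, "loss": float(np.mean(losses)), "val_f1": val_f1})
        if val_f1 > best_f1 + 1e-15:
            best_f1, best_epoch = val_f1, epoch
            best_weights = model.get_weights()

    model.set_weights(best_weights)
    df = pd.DataFrame(rows)
    df["selected"] = df["epoch"] == best_epoch
    return model, TrainingLog(records=df, selected_epoch=best_epoch, init_fingerprint=init_fp)


def _predict_in_batches(model: nn.Model, x: np.ndarray, batch: int = 64) -> np.ndarray:
    return np.concatenate([model.predict_proba(x[i:i + batch]) for i in range(0, len(x), batch)])


def extract_features(model: nn.Model, image: np.ndarray) -> np.ndarray:
    """Penultimate feature vector F(θ, I); deterministic inference."""
    x = to_model_input(image, model.input_spec)
    feats = model.features(x)
    return feats[0] if np.asarray(image).ndim == 2 else feats


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: nn.Model, path: str | Path, extra: dict | None = None) -> None:
    model.save(path, extra=extra)


def load_checkpoint(path: str | Path) -> nn.Model:
    path = Path(path)
    meta_path = path.with_suffix(".json")
    npz_path = path.with_suffix(".npz")
    if not meta_path.exists() or not npz_path.exists():
        raise CheckpointError(f"checkpoint files not found at {path}(.json/.npz)")
    meta = json.loads(meta_path.read_text())
    if meta.get("attention"):
        from .attention import build_attention_model, AttentionConfig
        model = build_attention_model(meta["architecture_id"], tuple(meta["input_spec"]),
                                      AttentionConfig(**meta["attention_config"]))
    else:
        model = build_backbone(meta["architecture_id"], tuple(meta["input_spec"]),
                               feature_dim=meta["feature_dim"])
    weights = dict(np.load(npz_path))
    model.set_weights(weights)
    if "saliency_scale" in meta:
        model.saliency_scale = meta["saliency_scale"]
    return model
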