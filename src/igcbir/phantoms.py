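"""Synthetic phantom radiographs with known disease-severity ground truth.

Real chest radiographs vary far more in global appearance (body habitus,
exposure, positioning) than in the localized findings a radiologist ranks
by.  A whole-image similarity measure therefore retrieves "look-alike"
patients rather than disease-similar ones.  This module reproduces that
phenomenon synthetically: each phantom is one of a small set of smooth
elliptical "thorax" archetypes (the dominant, disease-irrelevant factor)
plus, for positive cases, a localized lesion whose contrast and extent
encode a continuous severity in (0, 1].  Severity is the retrieval ground
truth; catalogue images are ranked by |severity − query severity|.

Two lesion models are provided: an ``effusion``-like basal gradient wedge
and a ``pneumonia``-like set of 1–3 soft blobs, mirroring the two
conditions of the benchmark.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage


class PhantomConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


class DataLayoutError(IOError):
    """Manifest on disk is missing files or internally inconsistent."""


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for the synthetic benchmark.

    ``lesion_region`` is a fractional (row0, col0, row1, col1) bounding box;
    lesions never extend outside it.  ``severity_range`` is the interval
    positive severities are drawn from (negatives are exactly 0).
    ``lesion_contrast_at_max`` is the grayscale offset (on a [0, 1] scale)
    of the lesion core at severity 1.
    """

    image_size: int = 96
    background_modes: int = 6
    background_noise_sd: float = 0.02
    lesion_region: tuple[float, float, float, float] = (0.55, 0.25, 0.95, 0.75)
    severity_range: tuple[float, float] = (0.1, 1.0)
    lesion_contrast_at_max: float = 0.45
    class_balance: float = 0.5
    condition: str = "effusion"
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 32:
            raise PhantomConfigError(f"image_size must be >= 32, got {self.image_size}")
        if not (0 < self.class_balance < 1):
            raise PhantomConfigError(f"class_balance must be in (0, 1), got {self.class_balance}")
        if self.background_modes < 1:
            raise PhantomConfigError(f"background_modes must be >= 1, got {self.background_modes}")
        if self.background_noise_sd < 0:
            raise PhantomConfigError(f"background_noise_sd must be >= 0, got {self.background_noise_sd}")
        r0, c0, r1, c1 = self.lesion_region
        if not (0 < r0 < r1 < 1 and 0 < c0 < c1 < 1):
            raise PhantomConfigError(f"lesion_region must be strictly inside image bounds, got {self.lesion_region}")
        lo, hi = self.severity_range
        if not (0 <= lo < hi <= 1):
            raise PhantomConfigError(f"severity_range must satisfy 0 <= lo < hi <= 1, got {self.severity_range}")
        if not (0 < self.lesion_contrast_at_max <= 1):
            raise PhantomConfigError(
                f"lesion_contrast_at_max must be in (0, 1], got {self.lesion_contrast_at_max}")
        if self.condition not in ("effusion", "pneumonia"):
            raise PhantomConfigError(f"condition must be 'effusion' or 'pneumonia', got {self.condition!r}")


@dataclass(frozen=True)
class PhantomSample:
    sample_id: str
    image: np.ndarray  # 2-D grayscale in [0, 1], quantized to 8 bit
    label: int  # 0 = negative, 1 = positive
    severity: float  # 0 iff label == 0
    background_mode: int

    def __post_init__(self):
        if (self.label == 1) != (self.severity > 0):
            raise ValueError(f"{self.sample_id}: label={self.label} inconsistent with severity={self.severity}")


@dataclass(frozen=True)
class QueryCatalogueSplit:
    split_id: str
    query_id: str
    catalogue_ids: tuple[str, ...]  # ordered, rank 1 = most similar (ground truth)

    @property
    def p(self) -> int:
        return len(self.catalogue_ids)

    def __post_init__(self):
        if self.query_id in self.catalogue_ids:
            raise ValueError(f"{self.split_id}: query {self.query_id} appears in its own catalogue")
        if len(set(self.catalogue_ids)) != len(self.catalogue_ids):
            raise ValueError(f"{self.split_id}: duplicate catalogue ids")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _mode_params(mode: int) -> dict:
    """Fixed per-archetype appearance parameters (independent of config.seed)."""
    mrng = np.random.default_rng([9176, mode])
    return {
        "body_intensity": 0.35 + 0.4 * mrng.uniform(),     # widely spread: dominates appearance
        "lung_drop": 0.12 + 0.12 * mrng.uniform(),
        "body_axes": (0.36 + 0.10 * mrng.uniform(), 0.30 + 0.10 * mrng.uniform()),
        "gradient": 0.10 * (mrng.uniform() - 0.5),
        "tilt_deg": 8.0 * (mrng.uniform() - 0.5),
    }


def _smooth_field(rng: np.random.Generator, size: int, amplitude: float) -> np.ndarray:
    coarse = rng.normal(0.0, 1.0, (4, 4))
    f = ndimage.zoom(coarse, size / 4.0, order=3, mode="nearest")[:size, :size]
    return 1.0 + amplitude * f / max(np.abs(f).max(), 1e-9)


def _render_background(config: PhantomConfig, mode: int, rng: np.random.Generator) -> np.ndarray:
    s = config.image_size
    p = _mode_params(mode)
    yy, xx = np.mgrid[0:s, 0:s] / (s - 1.0)
    cy = 0.5 + 0.02 * rng.normal()
    cx = 0.5 + 0.02 * rng.normal()
    ay = p["body_axes"][0] * (1 + 0.04 * rng.normal())
    ax = p["body_axes"][1] * (1 + 0.04 * rng.normal())
    theta = np.deg2rad(p["tilt_deg"] + 2.0 * rng.normal())
    yr = (yy - cy) * np.cos(theta) - (xx - cx) * np.sin(theta)
    xr = (yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    body = np.clip(1.2 - ((yr / ay) ** 2 + (xr / ax) ** 2), 0, 1)
    img = 0.08 + p["body_intensity"] * body
    # two darker "lung" ellipses
    for side in (-1, 1):
        lyr = yr + 0.05
        lxr = xr - side * 0.16
        lung = np.clip(1.0 - ((lyr / (0.55 * ay)) ** 2 + (lxr / (0.38 * ax)) ** 2), 0, 1)
        img -= p["lung_drop"] * lung
    img += p["gradient"] * (yy - 0.5)
    img *= _smooth_field(rng, s, 0.05)
    img += rng.normal(0.0, config.background_noise_sd, (s, s))
    return img


def _lesion_offset(config: PhantomConfig, severity: float, rng: np.random.Generator) -> np.ndarray:
    """Additive lesion field, zero outside ``lesion_region``; its mean over the
    region increases strictly with severity (contrast and extent both scale)."""
    s = config.image_size
    r0, c0, r1, c1 = (np.array(config.lesion_region) * (s - 1)).astype(int)
    out = np.zeros((s, s))
    if severity <= 0:
        return out
    amp = config.lesion_contrast_at_max * (0.3 + 0.7 * severity)
    cols = np.arange(c0, c1 + 1)
    cwin = np.sin(np.pi * (cols - c0) / max(c1 - c0, 1)) ** 0.5  # soft lateral falloff
    if config.condition == "effusion":
        # basal fluid wedge: rises from the bottom of the region with severity
        height = max(2, int(round((0.25 + 0.75 * severity) * (r1 - r0))))
        top = r1 - height
        rows = np.arange(top, r1 + 1)
        ramp = (rows - top) / height
        out[np.ix_(rows, cols)] = amp * ramp[:, None] * cwin[None, :]
    else:
        # pneumonia-like soft blobs; count grows with severity, positions fixed per sample
        n_blobs = 1 + int(2 * severity * 0.999)
        centers = rng.uniform(0.15, 0.85, (3, 2))
        sigmas = rng.uniform(0.10, 0.18, 3)
        yy, xx = np.mgrid[r0:r1 + 1, c0:c1 + 1]
        ny = (yy - r0) / max(r1 - r0, 1)
        nx = (xx - c0) / max(c1 - c0, 1)
        blob_sum = np.zeros_like(ny)
        for k in range(n_blobs):
            d2 = (ny - centers[k, 0]) ** 2 + (nx - centers[k, 1]) ** 2
            blob_sum += np.exp(-d2 / (2 * sigmas[k] ** 2))
        out[r0:r1 + 1, c0:c1 + 1] = amp * np.clip(blob_sum, 0, 1.2) / 1.2
    return out


def render_sample(config: PhantomConfig, sample_id: str, index: int,
                  background_mode: int, label: int, severity: float) -> PhantomSample:
    """Deterministic rendering of one phantom from (config.seed, index)."""
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 7919, index])
    img = _render_background(config, background_mode, rng)
    img = img + _lesion_offset(config, severity, rng)
    img = np.clip(img, 0.0, 1.0)
    img = np.round(img * 255.0) / 255.0  # 8-bit quantization: PNG round trip is exact
    return PhantomSample(sample_id=sample_id, image=img, label=label,
                         severity=severity, background_mode=background_mode)


# ---------------------------------------------------------------------------
# Dataset and splits
# ---------------------------------------------------------------------------

def generate_dataset(config: PhantomConfig, n: int) -> list[PhantomSample]:
    """Generate ``n`` phantoms with exactly ``round(n * class_balance)`` positives."""
    config.validate()
    if n < 2:
        raise PhantomConfigError(f"n must be >= 2, got {n}")
    n_pos = int(round(n * config.class_balance))
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 104729])
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_pos]] = 1
    modes = rng.integers(0, config.background_modes, n)
    lo, hi = config.severity_range
    severities = np.where(labels == 1, rng.uniform(lo, hi, n), 0.0)
    width = max(4, len(str(n - 1)))
    return [
        render_sample(config, f"s{idx:0{width}d}", idx, int(modes[idx]),
                      int(labels[idx]), float(severities[idx]))
        for idx in range(n)
    ]


def ground_truth_ranking(query: PhantomSample, catalogue: list[PhantomSample]) -> list[str]:
    """Catalogue ids sorted by disease similarity to the query.

    Ascending |severity − query severity|; exact ties put same-label items
    first, then ascending sample_id (the ground truth must be a total order).
    """
    if not catalogue:
        raise ValueError("catalogue must be non-empty")
    return [
        s.sample_id
        for s in sorted(catalogue,
                        key=lambda s: (abs(s.severity - query.severity),
                                       0 if s.label == query.label else 1,
                                       s.sample_id))
    ]


def make_splits(samples: list[PhantomSample], n_queries: int, p: int = 10,
                seed: int = 0) -> list[QueryCatalogueSplit]:
    """Draw disjoint query/catalogue sets preserving the pool's class proportion.

    Each split consumes p + 1 samples (1 query + p catalogue images); the
    catalogue positive count matches the pool proportion to within one image.
    The catalogue is stored already ordered by the ground-truth ranking.
    """
    need = n_queries * (p + 1)
    if len(samples) < need:
        raise ValueError(
            f"insufficient samples: need {need} for {n_queries} disjoint splits of p={p}, have {len(samples)}")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 15485863])
    pos = [s for s in samples if s.label == 1]
    neg = [s for s in samples if s.label == 0]
    frac_pos = len(pos) / len(samples)
    cat_pos = int(round(p * frac_pos))
    cat_neg = p - cat_pos
    # queries alternate classes in proportion (largest-remainder assignment)
    q_pos_total = int(round(n_queries * frac_pos))
    q_labels = [1] * q_pos_total + [0] * (n_queries - q_pos_total)
    if len(pos) < q_pos_total + n_queries * cat_pos or len(neg) < (n_queries - q_pos_total) + n_queries * cat_neg:
        raise ValueError("insufficient samples of one class for the requested proportion-preserving splits")
    pos = [pos[i] for i in rng.permutation(len(pos))]
    neg = [neg[i] for i in rng.permutation(len(neg))]
    splits = []
    for qi in range(n_queries):
        query = pos.pop() if q_labels[qi] == 1 else neg.pop()
        catalogue = [pos.pop() for _ in range(cat_pos)] + [neg.pop() for _ in range(cat_neg)]
        order = ground_truth_ranking(query, catalogue)
        splits.append(QueryCatalogueSplit(split_id=f"split{qi:03d}",
                                          query_id=query.sample_id,
                                          catalogue_ids=tuple(order)))
    return splits


# ---------------------------------------------------------------------------
# Manifest IO
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["sample_id", "filename", "label", "severity", "background_mode"]


def write_manifest(samples: list[PhantomSample], splits: list[QueryCatalogueSplit],
                   directory: str | Path) -> None:
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        fname = f"images/{s.sample_id}.png"
        arr = np.round(s.image * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(directory / fname)
        rows.append((s.sample_id, fname, s.label, repr(s.severity), s.background_mode))
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(directory / "manifest.csv", index=False)
    payload = [{"split_id": sp.split_id, "query_id": sp.query_id,
                "catalogue_ids": list(sp.catalogue_ids)} for sp in splits]
    (directory / "splits.json").write_text(json.dumps(payload, indent=1))


def read_manifest(directory: str | Path) -> tuple[list[PhantomSample], list[QueryCatalogueSplit]]:
    directory = Path(directory)
    mpath = directory / "manifest.csv"
    if not mpath.exists():
        raise DataLayoutError(f"missing manifest: {mpath}")
    df = pd.read_csv(mpath, dtype={"sample_id": str, "filename": str},
                     float_precision="round_trip")
    missing = [r.sample_id for r in df.itertuples() if not (directory / r.filename).exists()]
    if missing:
        raise DataLayoutError(f"missing image files for samples: {missing}")
    samples = []
    for r in df.itertuples():
        arr = np.asarray(Image.open(directory / r.filename).convert("L"), dtype=np.float64) / 255.0
        samples.append(PhantomSample(sample_id=r.sample_id, image=arr, label=int(r.label),
                                     severity=float(r.severity), background_mode=int(r.background_mode)))
    known = {s.sample_id for s in samples}
    splits = []
    spath = directory / "splits.json"
    if spath.exists():
        for d in json.loads(spath.read_text()):
            unknown = [i for i in [d["query_id"], *d["catalogue_ids"]] if i not in known]
            if unknown:
                raise DataLayoutError(f"{d['split_id']}: unknown sample ids in split: {unknown}")
            splits.append(QueryCatalogueSplit(split_id=d["split_id"], query_id=d["query_id"],
                                              catalogue_ids=tuple(d["catalogue_ids"])))
    return samples, splits
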