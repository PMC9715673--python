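"""Catalogue ranking under each comparator.

Five methods rank a catalogue against a query:

* ``ssim`` — structural similarity between raw images (descending);
* ``cnn`` — L2 distance between penultimate features of the image-trained
  classifier, d = ||F(θ_CNN, I_t) − F(θ_CNN, I_c)||₂;
* ``cnn_ig`` — ablation: the image-trained classifier fed Deep Taylor
  saliency maps, d = ||F(θ_CNN, S(θ_CNN, I_t)) − F(θ_CNN, S(θ_CNN, I_c))||₂;
* ``ig`` — the interpretability-guided method: a classifier retrained on
  saliency maps, d = ||F(θ_IG, S(θ_CNN, I_t)) − F(θ_IG, S(θ_CNN, I_c))||₂;
* ``att`` — distances between the attention model's fused embeddings.

Exact score ties are broken by ascending sample id so every ranking is a
deterministic permutation of the catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from . import relprop
from .backbone import to_model_input
from .phantoms import QueryCatalogueSplit

METHODS = ("ssim", "cnn", "cnn_ig", "ig", "att")
_REQUIRED_MODELS = {"ssim": (), "cnn": ("cnn",), "cnn_ig": ("cnn",),
                    "ig": ("cnn", "ig"), "att": ("att",)}


class MethodSpecError(ValueError):
    pass


@dataclass
class MethodSpec:
    method_id: str
    models: dict = field(default_factory=dict)  # {"cnn": Model, "ig": Model, "att": Model}
    # shared normalization constant for saliency-map inputs (cnn_ig / ig);
    # should be the scale the IG model was trained with.  When None, the
    # split's own maximum is used.
    saliency_scale: float | None = None

    def validate(self) -> None:
        if self.method_id not in METHODS:
            raise MethodSpecError(f"unknown method_id {self.method_id!r}")
        missing = [m for m in _REQUIRED_MODELS[self.method_id] if m not in self.models]
        if missing:
            raise MethodSpecError(
                f"method {self.method_id!r} requires checkpoint(s) {missing}")


@dataclass(frozen=True)
class RetrievalResult:
    split_id: str
    method_id: str
    ranked_ids: tuple[str, ...]  # rank 1 = retrieved most similar
    scores: tuple[float, ...]  # distance (non-decreasing) or ssim (non-increasing)

    def to_rows(self) -> list[dict]:
        return [{"split_id": self.split_id, "method_id": self.method_id,
                 "rank": i + 1, "sample_id": sid, "score": sc}
                for i, (sid, sc) in enumerate(zip(self.ranked_ids, self.scores))]


def results_to_csv(results: list[RetrievalResult], path) -> None:
    pd.DataFrame([r for res in results for r in res.to_rows()]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pairwise scores
# ---------------------------------------------------------------------------

def ssim(image_a: np.ndarray, image_b: np.ndarray) -> float:
    """Mean local SSIM with the original formulation's defaults.

    11×11 Gaussian window (σ = 1.5), K1 = 0.01, K2 = 0.03, dynamic range 1.
    """
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return float(structural_similarity(
        a, b, gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
        K1=0.01, K2=0.03, data_range=1.0))


def pairwise_distance(feat_a: np.ndarray, feat_b: np.ndarray) -> float:
    """Euclidean distance between two feature vectors."""
    a = np.asarray(feat_a, dtype=np.float64).ravel()
    b = np.asarray(feat_b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"feature lengths differ: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


# ---------------------------------------------------------------------------
# Saliency cache
# ---------------------------------------------------------------------------

class SaliencyCache:
    """Saliency maps keyed by (model fingerprint, sample_id)."""

    def __init__(self):
        self._store: dict[tuple[str, str], relprop.SaliencyMap] = {}

    def get(self, model, sample_id: str, image: np.ndarray) -> relprop.SaliencyMap:
        key = (model.fingerprint(), sample_id)
        if key not in self._store:
            self._store[key] = relprop.deep_taylor(model, image, sample_id=sample_id)
        return self._store[key]


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def _batch_features(model, images_2d: list[np.ndarray]) -> np.ndarray:
    x = to_model_input(np.stack(images_2d), model.input_spec)
    return model.features(x)


def rank_catalogue(split: QueryCatalogueSplit, method: MethodSpec,
                   images: dict[str, np.ndarray],
                   cache: SaliencyCache | None = None) -> RetrievalResult:
    """Rank ``split.catalogue_ids`` against the query under one method.

    ``images`` maps sample ids to 2-D grayscale arrays in [0, 1].
    """
    method.validate()
    ids = list(split.catalogue_ids)
    query = images[split.query_id]

    if method.method_id == "ssim":
        scores = {cid: ssim(query, images[cid]) for cid in ids}
        order = sorted(ids, key=lambda cid: (-scores[cid], cid))
    else:
        if method.method_id == "cnn":
            feat_model = method.models["cnn"]
            inputs = {cid: images[cid] for cid in [split.query_id, *ids]}
        elif method.method_id == "att":
            feat_model = method.models["att"]
            inputs = {cid: images[cid] for cid in [split.query_id, *ids]}
        else:  # cnn_ig / ig: features of the saliency maps
            sal_model = method.models["cnn"]
            feat_model = method.models["cnn" if method.method_id == "cnn_ig" else "ig"]
            cache = cache or SaliencyCache()
            sals = {cid: cache.get(sal_model, cid, images[cid])
                    for cid in [split.query_id, *ids]}
            # one shared scale keeps relative amplitudes comparable; prefer the
            # scale the feature model was trained with
            shared = method.saliency_scale or max(s.relevance.max() for s in sals.values())
            inputs = {cid: relprop.to_input_image(s, feat_model.input_spec,
                                                  max_value=shared or None)[0]
                      for cid, s in sals.items()}
        feats = _batch_features(feat_model, [inputs[c] for c in [split.query_id, *ids]])
        qf = feats[0]
        scores = {cid: pairwise_distance(qf, feats[1 + i]) for i, cid in enumerate(ids)}
        order = sorted(ids, key=lambda cid: (scores[cid], cid))

    result = RetrievalResult(split_id=split.split_id, method_id=method.method_id,
                             ranked_ids=tuple(order),
                             scores=tuple(scores[cid] for cid in order))
    if set(result.ranked_ids) != set(split.catalogue_ids):
        raise RuntimeError(f"{split.split_id}: ranking is not a permutation of the catalogue")
    return result
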