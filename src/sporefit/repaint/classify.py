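"""Per-pixel classification of well crops: background / hyphae / conidia.

Two interchangeable classifiers satisfy the same contract (per-pixel class
probabilities summing to one):

* :class:`RuleBasedClassifier` — deterministic HSV thresholds separating
  dark saturated conidia and bright unsaturated aerial hyphae from
  everything else; the reference and default.
* :class:`LearnedClassifier` — a small multilayer perceptron over local
  color/texture features, trained on annotated crops; stands in for a
  fuller convolutional segmenter at fixture scale.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.color import hsv2rgb, rgb2hsv
from sklearn.neural_network import MLPClassifier

CLASS_BACKGROUND, CLASS_HYPHAE, CLASS_CONIDIA = 0, 1, 2
CLASS_NAMES = ("background", "hyphae", "conidia")
N_CLASSES = 3


class ContractViolationError(RuntimeError):
    """A classifier emitted probabilities that do not normalize."""


@dataclass
class ClassMask:
    """Per-pixel class labels for one 256x256 crop."""

    labels: np.ndarray  # (256, 256) uint8 in {0, 1, 2}

    def __post_init__(self):
        if self.labels.ndim != 2:
            raise ValueError("mask must be a 2-D label image")
        if self.labels.max(initial=0) >= N_CLASSES:
            raise ValueError("labels must be in {0 background, 1 hyphae, 2 conidia}")


@dataclass
class RuleBasedClassifier:
    """Nearest-centroid segmenter over class color anchors.

    Each class is represented by one or more HSV anchor colors — conidia
    dark and saturated green, aerial hyphae bright and unsaturated,
    background covering both the plate housing and uncolonized medium —
    and every pixel takes the class of its nearest anchor.  Distances are
    measured in RGB, where interpolation during crop resizing blends
    colors linearly, so class boundaries in blend zones split at their
    midpoints and coverage stays unbiased.  Deterministic, training-free.
    """

    background_anchors: tuple = ((0.10, 0.05, 0.45), (0.09, 0.38, 0.82))
    hyphae_anchors: tuple = ((0.12, 0.16, 0.97),)
    conidia_anchors: tuple = ((0.33, 0.65, 0.35),)
    kind: str = "rule_based"

    @property
    def metadata(self) -> dict:
        return {"kind": self.kind, "config_digest": _digest(repr(self))}

    def _rgb_anchors(self) -> list:
        out = []
        for cls, anchors in (
            (CLASS_BACKGROUND, self.background_anchors),
            (CLASS_HYPHAE, self.hyphae_anchors),
            (CLASS_CONIDIA, self.conidia_anchors),
        ):
            for hsv in anchors:
                rgb = hsv2rgb(np.array(hsv, dtype=float).reshape(1, 1, 3)).ravel()
                out.append((rgb, cls))
        return out

    def predict_proba(self, crop_pixels: np.ndarray) -> np.ndarray:
        """Classify by the best-fitting two-anchor color blend.

        Resizing interpolates neighboring pixels linearly in RGB, so a
        boundary pixel is a convex combination of two class colors.  For
        every anchor pair the pixel is projected onto the connecting
        segment; the pair with the smallest residual wins and the pixel
        takes the class of the dominant endpoint.  (Plain nearest-anchor
        assignment would mislabel conidia/hyphae blends, whose midpoints
        resemble uncolonized medium.)
        """
        rgb = np.asarray(crop_pixels, dtype=float) / 255.0
        anchors = self._rgb_anchors()
        labels = np.zeros(rgb.shape[:2], dtype=np.uint8)
        best = np.full(rgb.shape[:2], np.inf)
        for i, (ai, ci) in enumerate(anchors):
            for aj, cj in anchors[i:]:
                seg = aj - ai
                denom = float(seg @ seg)
                if denom < 1e-12:
                    t = np.zeros(rgb.shape[:2])
                else:
                    t = np.clip(((rgb - ai) @ seg) / denom, 0.0, 1.0)
                resid = ((rgb - (ai + t[..., None] * seg)) ** 2).sum(axis=-1)
                closer = resid < best
                labels[closer] = np.where(t[closer] < 0.5, ci, cj)
                best[closer] = resid[closer]
        probs = np.zeros(rgb.shape[:2] + (N_CLASSES,))
        for cls in range(N_CLASSES):
            probs[..., cls] = labels == cls
        return probs


@dataclass
class TrainingConfig:
    """Knobs for the learned classifier at fixture scale."""

    hidden_units: int = 16
    max_pixels_per_crop: int = 3000
    max_iter: int = 60
    texture_window: int = 5
    seed: int = 0


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _features(crop_pixels: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel HSV color plus local mean/variance texture channels."""
    hsv = rgb2hsv(crop_pixels)
    feats = [hsv[..., k] for k in range(3)]
    for k in (1, 2):  # saturation/value neighborhoods carry the class signal
        mean = uniform_filter(hsv[..., k], size=window)
        sq = uniform_filter(hsv[..., k] ** 2, size=window)
        feats += [mean, np.sqrt(np.clip(sq - mean**2, 0, None))]
    return np.stack(feats, axis=-1)


@dataclass
class LearnedClassifier:
    """MLP pixel classifier wrapping the shared prediction contract."""

    model: MLPClassifier
    config: TrainingConfig
    kind: str = "learned"

    @property
    def metadata(self) -> dict:
        return {"kind": self.kind, "config_digest": _digest(repr(self.config))}

    @property
    def loss_curve(self) -> list:
        return list(self.model.loss_curve_)

    def predict_proba(self, crop_pixels: np.ndarray) -> np.ndarray:
        X = _features(crop_pixels, self.config.texture_window).reshape(-1, 7)
        raw = self.model.predict_proba(X)
        probs = np.zeros((X.shape[0], N_CLASSES))
        for j, cls in enumerate(self.model.classes_):
            probs[:, int(cls)] = raw[:, j]
        return probs.reshape(crop_pixels.shape[:2] + (N_CLASSES,))


def train_classifier(crops, masks, config: TrainingConfig | None = None) -> LearnedClassifier:
    """Train the learned pixel classifier on annotated crops.

    Parameters
    ----------
    crops : sequence of WellCrop or (256,256,3) arrays
    masks : sequence of ClassMask or (256,256) label arrays
    """
    config = config or TrainingConfig()
    if len(crops) < 2:
        raise ValueError("need at least 2 annotated crops to train")
    if len(crops) != len(masks):
        raise ValueError("crops and masks must align one-to-one")

    rng = np.random.default_rng(config.seed)
    X_parts, y_parts = [], []
    for crop, mask in zip(crops, masks):
        pixels = getattr(crop, "pixels", crop)
        labels = getattr(mask, "labels", mask)
        if labels.shape != pixels.shape[:2]:
            raise ValueError("mask shape does not match its crop")
        feats = _features(pixels, config.texture_window).reshape(-1, 7)
        flat = np.asarray(labels).reshape(-1)
        take = min(config.max_pixels_per_crop, flat.size)
        idx = rng.choice(flat.size, size=take, replace=False)
        X_parts.append(feats[idx])
        y_parts.append(flat[idx])
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)

    present = set(int(c) for c in np.unique(y))
    if len(present) < 2:
        raise ValueError("degenerate training set: only one class present")
    missing = set(range(N_CLASSES)) - present
    if missing:
        warnings.warn(
            f"class(es) {sorted(CLASS_NAMES[m] for m in missing)} absent from training labels"
        )

    model = MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,),
        max_iter=config.max_iter,
        random_state=config.seed,
        early_stopping=False,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        model.fit(X, y)
    return LearnedClassifier(model=model, config=config)


def segment(crop, classifier) -> ClassMask:
    """Argmax segmentation of a crop under any contract-satisfying classifier."""
    pixels = getattr(crop, "pixels", crop)
    probs = classifier.predict_proba(pixels)
    if probs.shape != pixels.shape[:2] + (N_CLASSES,):
        raise ContractViolationError(
            f"classifier emitted shape {probs.shape}, expected {pixels.shape[:2] + (N_CLASSES,)}"
        )
    sums = probs.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ContractViolationError("per-pixel class probabilities must sum to 1")
    return ClassMask(labels=probs.argmax(axis=-1).astype(np.uint8))
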