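"""Trainable per-pixel classifier: organoid contour vs tissue.

The discriminative step of the pipeline.  Sparse user annotations (or, on
synthetic scenes, ground-truth-derived labels) mark two classes on the
enhanced working image — 1 = organoid contour (membrane), 2 = tissue
(immune cells, debris, lumen, plain background) — and a random-forest
ensemble learns the mapping from local image features to class
probabilities.  Contour mimicry by dense immune-cell clusters is rejected
here: clusters share the membrane's brightness but not its texture, so
variance/entropy/co-occurrence features separate them.

Feature families (14 features by default): raw intensity; Gaussian
smoothings σ = 1, 2, 4, 8 px and median filters r = 2, 4 px (environmental
context); gradient magnitude σ = 1, 2 px and a Laplacian-of-Gaussian σ = 2
(morphology/edges); local variance and local entropy in 7×7 windows; and
Haralick-style co-occurrence contrast and homogeneity on a 16-level
quantized image in 15×15 windows.
"""

from __future__ import annotations

import io
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import (gaussian_filter, gaussian_gradient_magnitude,
                           gaussian_laplace, median_filter, uniform_filter)
from skimage.filters.rank import entropy as rank_entropy
from skimage.measure import label as cc_label
from skimage.morphology import footprint_rectangle
from sklearn.ensemble import RandomForestClassifier

from .config import DEFAULT_FEATURES
from .core_io import Calibration
from .errors import ConfigError, TrainingError
from .preprocess import GrayImage

CONTOUR_LABEL = 1
TISSUE_LABEL = 2

_QUANT_LEVELS = 16
_HARALICK_WINDOW = 15
_TEXTURE_WINDOW = 7


@dataclass
class FeatureStack:
    """Per-pixel feature vectors for one image: ``data`` is (H, W, F)."""

    data: np.ndarray
    names: list[str]

    def __post_init__(self):
        if self.data.ndim != 3 or self.data.shape[2] != len(self.names):
            raise ConfigError("feature data and names disagree")

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def flat(self) -> np.ndarray:
        return self.data.reshape(-1, self.data.shape[2])


def _local_variance(px: np.ndarray, window: int) -> np.ndarray:
    mean = uniform_filter(px, window, mode="reflect")
    mean_sq = uniform_filter(px * px, window, mode="reflect")
    return np.maximum(mean_sq - mean * mean, 0.0)


def _quantize(px: np.ndarray, max_value: float, levels: int) -> np.ndarray:
    scaled = np.clip(px / max(max_value, 1e-12), 0.0, 1.0)
    return np.minimum((scaled * levels).astype(np.int32), levels - 1)


def _cooccurrence_maps(px: np.ndarray, max_value: float,
                       window: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window co-occurrence contrast and homogeneity.

    For the two unit offsets (right, down) the quantized level difference
    d(p) = |q(p) − q(p+δ)| is formed and its window statistics
    mean(d²) (contrast) and mean(1/(1+d)) (homogeneity) are averaged over
    the offsets — the sliding-window form of the classic co-occurrence
    statistics, computable with box filters.
    """
    q = _quantize(px, max_value, _QUANT_LEVELS).astype(np.float64)
    contrast = np.zeros_like(q)
    homog = np.zeros_like(q)
    for axis in (0, 1):
        d = np.abs(np.diff(q, axis=axis))
        pad = [(0, 0), (0, 0)]
        pad[axis] = (0, 1)
        d = np.pad(d, pad, mode="edge")
        contrast += uniform_filter(d * d, window, mode="reflect")
        homog += uniform_filter(1.0 / (1.0 + d), window, mode="reflect")
    return contrast / 2.0, homog / 2.0


def extract_features(image: GrayImage,
                     spec: Sequence[str] | None = None) -> FeatureStack:
    """Compute the per-pixel feature stack named by ``spec``."""
    names = list(spec) if spec is not None else list(DEFAULT_FEATURES)
    px = image.pixels
    cache: dict[str, np.ndarray] = {}

    def haralick(which: str) -> np.ndarray:
        if "haralick" not in cache:
            c, h = _cooccurrence_maps(px, image.max_value, _HARALICK_WINDOW)
            cache["haralick"] = c
            cache["haralick_h"] = h
        return cache["haralick" if which == "c" else "haralick_h"]

    def entropy_map() -> np.ndarray:
        if "entropy" not in cache:
            as8 = (np.clip(px / max(image.max_value, 1e-12), 0, 1) * 255).astype(np.uint8)
            cache["entropy"] = rank_entropy(
                as8, footprint_rectangle((_TEXTURE_WINDOW, _TEXTURE_WINDOW))
            ).astype(np.float64)
        return cache["entropy"]

    computed: list[np.ndarray] = []
    for name in names:
        if name == "intensity":
            f = px
        elif name.startswith("gaussian_s"):
            f = gaussian_filter(px, sigma=float(name.removeprefix("gaussian_s")),
                                mode="reflect")
        elif name.startswith("median_r"):
            r = int(name.removeprefix("median_r"))
            f = median_filter(px, size=2 * r + 1, mode="reflect")
        elif name.startswith("gradient_s"):
            f = gaussian_gradient_magnitude(
                px, sigma=float(name.removeprefix("gradient_s")), mode="reflect")
        elif name.startswith("log_s"):
            f = gaussian_laplace(px, sigma=float(name.removeprefix("log_s")),
                                 mode="reflect")
        elif name == "variance_w7":
            f = _local_variance(px, _TEXTURE_WINDOW)
        elif name == "entropy_w7":
            f = entropy_map()
        elif name == "haralick_contrast_w15":
            f = haralick("c")
        elif name == "haralick_homogeneity_w15":
            f = haralick("h")
        else:
            raise ConfigError(f"unknown feature name {name!r}")
        computed.append(f.astype(np.float32))
    data = np.stack(computed, axis=-1)
    if not np.isfinite(data).all():
        raise ConfigError("non-finite values in feature stack")
    return FeatureStack(data=data, names=names)


@dataclass
class PixelClassifier:
    """A trained contour/tissue ensemble plus the feature names it expects."""

    model: RandomForestClassifier
    feature_names: list[str]
    seed: int
    class_labels: list[int] = field(
        default_factory=lambda: [CONTOUR_LABEL, TISSUE_LABEL])

    def predict_proba(self, features: FeatureStack) -> np.ndarray:
        """(H, W, 2) probability maps ordered (contour, tissue)."""
        if features.names != self.feature_names:
            raise ConfigError(
                f"feature mismatch: model expects {self.feature_names}, "
                f"got {features.names}")
        proba = self.model.predict_proba(features.flat())
        order = [list(self.model.classes_).index(c) for c in self.class_labels]
        proba = proba[:, order]
        return proba.reshape(*features.image_shape, 2)

    def save(self, path: str | Path) -> None:
        """Persist as one binary file: JSON header line + pickled model."""
        header = {
            "format": "organocyte-pixel-classifier",
            "version": 1,
            "feature_names": self.feature_names,
            "class_names": ["contour", "tissue"],
            "class_labels": self.class_labels,
            "seed": self.seed,
        }
        buf = io.BytesIO()
        pickle.dump(self.model, buf, protocol=4)
        with open(path, "wb") as fh:
            fh.write(json.dumps(header).encode() + b"\n")
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "PixelClassifier":
        with open(path, "rb") as fh:
            header = json.loads(fh.readline().decode())
            if header.get("format") != "organocyte-pixel-classifier":
                raise ConfigError(f"{path} is not a pixel-classifier file")
            model = pickle.load(fh)
        return cls(model=model, feature_names=header["feature_names"],
                   seed=header["seed"], class_labels=header["class_labels"])


def train_classifier(examples: Sequence[tuple[FeatureStack, np.ndarray]],
                     seed: int,
                     n_trees: int = 100,
                     max_depth: int | None = None,
                     max_pixels_per_class: int = 20000) -> PixelClassifier:
    """Train the contour/tissue forest on pooled annotated pixels.

    ``examples`` pairs each feature stack with an annotation grid
    (0 = unlabeled, 1 = contour, 2 = tissue); unlabeled pixels are ignored.
    Re-training with an enlarged pool is just calling again.  Per-class
    subsampling (``max_pixels_per_class``, seeded) keeps training tractable
    when annotations are dense.
    """
    if not examples:
        raise TrainingError("no annotated examples provided")
    names = examples[0][0].names
    xs, ys = [], []
    for stack, ann in examples:
        if stack.names != names:
            raise ConfigError("feature names differ across training examples")
        ann = np.asarray(ann)
        if ann.shape != stack.image_shape:
            raise ConfigError("annotation shape does not match its image")
        sel = ann > 0
        xs.append(stack.flat()[sel.ravel()])
        ys.append(ann[sel])
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    present = set(np.unique(y)) & {CONTOUR_LABEL, TISSUE_LABEL}
    if present != {CONTOUR_LABEL, TISSUE_LABEL}:
        raise TrainingError(
            f"training pool must contain both classes, found {sorted(present)}")
    rng = np.random.default_rng(seed)
    keep = []
    for c in (CONTOUR_LABEL, TISSUE_LABEL):
        idx = np.nonzero(y == c)[0]
        if idx.size > max_pixels_per_class:
            idx = rng.choice(idx, size=max_pixels_per_class, replace=False)
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    model = RandomForestClassifier(
        n_estimators=n_trees, max_depth=max_depth, random_state=seed,
        n_jobs=1, min_samples_leaf=2)
    model.fit(X[keep], y[keep])
    return PixelClassifier(model=model, feature_names=list(names), seed=seed)


def predict_masks(model: PixelClassifier, features: FeatureStack,
                  prob_threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Threshold class probabilities into disjoint contour/tissue masks.

    contour = P(contour) ≥ threshold; tissue ("background") = the
    complement restricted to P(tissue) ≥ threshold.  Pixels confident in
    neither class belong to neither mask.
    """
    proba = model.predict_proba(features)
    contour = proba[:, :, 0] >= prob_threshold
    background = (~contour) & (proba[:, :, 1] >= prob_threshold)
    return contour, background


def clean_contour_mask(contour: np.ndarray, min_component_area_um2: float,
                       calibration: Calibration) -> np.ndarray:
    """Drop 8-connected contour components smaller than the area threshold."""
    if min_component_area_um2 < 0:
        raise ConfigError("min_component_area_um2 must be >= 0")
    if min_component_area_um2 == 0 or not contour.any():
        return contour.copy()
    lab, n = cc_label(contour, connectivity=2, return_num=True)
    if n == 0:
        return contour.copy()
    areas = np.bincount(lab.ravel())[1:] * calibration.pixel_area_um2
    keep = np.concatenate([[False], areas >= min_component_area_um2])
    return keep[lab]
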