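"""Pixelwise separation of neuronal structure from background.

Features are a mix of multiscale isotropic Laplacian-of-Gaussian responses
and oriented anisotropic (elongated Gaussian second-derivative) responses —
the oriented bank responds selectively to tube-like neurites at each
orientation.  A linear-kernel SVM trained on (image, truth-mask) pairs does
the classification; an Otsu-threshold fallback is available for model-free
runs.  The output mask is cleaned by removing small components and filling
small holes, because seeding and tracing assume connected tubular
foreground.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .io import Image2D

DEFAULT_SCALES = (1.0, 2.0, 4.0)
DEFAULT_N_ORIENT = 8


@dataclass
class BinaryMask:
    """Foreground/background map f; f=0 is background."""

    f: np.ndarray
    provenance: str = "computed"  # computed | supplied

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f).astype(bool)
        if self.f.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.f.shape


@dataclass
class FeatureBank:
    """Per-pixel feature stack.

    Per scale: one isotropic LoG plane, ``n_orient`` oriented planes and —
    when ``include_intensity`` — one Gaussian-smoothed intensity plane.
    The intensity plane is needed to classify flat interiors of bright
    regions, where every derivative feature vanishes.
    """

    features: np.ndarray  # (n_features, h, w)
    scales: tuple[float, ...]
    n_orient: int
    include_intensity: bool = True

    @property
    def n_features(self) -> int:
        return self.features.shape[0]

    def as_matrix(self) -> np.ndarray:
        """Pixels as rows: (h*w, n_features)."""
        return self.features.reshape(self.n_features, -1).T


def _oriented_kernel(scale: float, theta: float, elongation: float = 3.0,
                     truncate: float = 3.0) -> np.ndarray:
    """Second derivative across the short axis of an elongated Gaussian.

    Responds maximally (in magnitude) on the centerline of a bright bar
    aligned with ``theta``; zero-mean so constant regions give zero.
    """
    s_short = scale
    s_long = elongation * scale
    half = int(math.ceil(truncate * s_long))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    ca, sa = math.cos(theta), math.sin(theta)
    u = xx * ca + yy * sa          # along the bar
    v = -xx * sa + yy * ca         # across the bar
    g = np.exp(-(u ** 2) / (2 * s_long ** 2) - (v ** 2) / (2 * s_short ** 2))
    kern = (v ** 2 / s_short ** 4 - 1.0 / s_short ** 2) * g
    kern -= kern.mean()
    # negate so bright ridges give positive responses
    return -kern


def compute_features(img: Image2D, scales=DEFAULT_SCALES,
                     n_orient: int = DEFAULT_N_ORIENT,
                     include_intensity: bool = True) -> FeatureBank:
    """Multiscale isotropic LoG + oriented elongated second-derivative bank.

    For each scale: one (negated) LoG response and ``n_orient`` oriented
    responses at angles k*pi/n_orient, computed by convolution with
    reflected boundary handling; with ``include_intensity`` a
    Gaussian-smoothed intensity plane per scale is appended to the block.
    """
    scales = tuple(float(s) for s in scales)
    if not scales:
        raise ValueError("scales must be non-empty")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    pixels = np.asarray(img.pixels, dtype=float)
    planes = []
    for s in scales:
        planes.append(-ndi.gaussian_laplace(pixels, s, mode="reflect"))
        for k in range(n_orient):
            theta = k * math.pi / n_orient
            kern = _oriented_kernel(s, theta)
            planes.append(ndi.convolve(pixels, kern, mode="reflect"))
        if include_intensity:
            planes.append(ndi.gaussian_filter(pixels, s, mode="reflect"))
    return FeatureBank(np.stack(planes), scales, n_orient, include_intensity)


@dataclass
class ClassifierModel:
    """Serializable pixel classifier plus the feature configuration it expects."""

    pipeline: Pipeline
    scales: tuple[float, ...]
    n_orient: int
    include_intensity: bool = True

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "ClassifierModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, ClassifierModel):
            raise ValueError(f"{path} does not contain a ClassifierModel")
        return model


def train_classifier(features: FeatureBank, labels: BinaryMask,
                     max_per_class: int = 4000, C: float = 1.0,
                     seed: int = 0) -> ClassifierModel:
    """Train the pixelwise linear-SVM on balanced subsampled pixels.

    Training is the expensive one-off step; the resulting model can be
    reused for any image of the same type.  Raises ``ValueError`` if the
    label mask does not contain both classes.
    """
    x = features.as_matrix()
    y = labels.f.ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("labels shape does not match feature image shape")
    if y.all() or not y.any():
        raise ValueError("training labels must contain both classes")
    rng = np.random.default_rng(seed)
    idx_fg = np.flatnonzero(y)
    idx_bg = np.flatnonzero(~y)
    n = min(len(idx_fg), len(idx_bg), max_per_class)
    sel = np.concatenate([
        rng.choice(idx_fg, size=n, replace=False),
        rng.choice(idx_bg, size=n, replace=False),
    ])
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", LinearSVC(C=C, dual=False, random_state=0)),
    ])
    pipe.fit(x[sel], y[sel])
    return ClassifierModel(pipe, features.scales, features.n_orient,
                           features.include_intensity)


def _clean(mask: np.ndarray, min_size: int, max_hole: int) -> np.ndarray:
    # max_size removes objects <= its value, i.e. strictly below min_size
    if min_size > 1:
        mask = remove_small_objects(mask, max_size=min_size - 1)
    if max_hole > 1:
        mask = remove_small_holes(mask, max_size=max_hole - 1)
    return mask


def segment(img: Image2D, model: ClassifierModel | None = None,
            min_size: int = 20, max_hole: int = 10) -> BinaryMask:
    """Binary segmentation of an image; deterministic given (image, model).

    With a trained model, classifies every pixel from the feature bank; with
    ``model=None`` falls back to Otsu intensity thresholding.  Components
    below ``min_size`` px are removed and holes below ``max_hole`` px are
    filled.  A blank (constant) image yields an empty mask.
    """
    pixels = np.asarray(img.pixels, dtype=float)
    if pixels.max() == pixels.min():
        return BinaryMask(np.zeros(pixels.shape, dtype=bool))
    if model is None:
        thr = threshold_otsu(pixels)
        raw = pixels > thr
    else:
        bank = compute_features(img, model.scales, model.n_orient,
                                model.include_intensity)
        raw = model.pipeline.predict(bank.as_matrix()).reshape(pixels.shape)
        raw = raw.astype(bool)
    return BinaryMask(_clean(raw, min_size, max_hole))


def dice_score(mask: np.ndarray, truth: np.ndarray) -> float:
    """Pixel Dice overlap between two boolean masks."""
    mask = np.asarray(mask).astype(bool)
    truth = np.asarray(truth).astype(bool)
    inter = np.logical_and(mask, truth).sum()
    denom = mask.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return 2.0 * inter / denom
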