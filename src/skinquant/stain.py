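"""Binary positive-stain classification.

Two interchangeable routes produce a :class:`PositiveMask`:

* color-range thresholding — a pixel is positive when its RGB Euclidean
  distance to the nearest of one or more operator-picked reference colors is
  within a tolerance (the reproducible analog of an interactive color-range
  selection), optionally followed by a small "coherence" dilation that merges
  fragmented selections;
* a trainable pixel classifier — a small multilayer perceptron over local
  color/texture features, trained on sparse 100x100 um annotated tiles
  composed into a single training montage and applied at a fixed working
  resolution (default 0.91 um/px), mirroring a trainable-segmentation
  workflow in digital-pathology viewers.

The classifier's feature recipe is deliberately minimal and declared here:
per-channel intensity, per-channel Gaussian blur at sigma 1 and 2 px, and
per-channel gradient magnitude, all at the working resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage
from skimage.morphology import dilation, disk
from skimage.transform import resize

from .calibration import ScaleCalibration
from .errors import StainClassificationError
from .geometry import build_epidermis_mask
from .images import CalibratedImage

__all__ = [
    "ColorRangeSpec",
    "PositiveMask",
    "TrainingTile",
    "PixelClassifier",
    "threshold_classify",
    "coherence_expand",
    "apply_mask_edits",
    "compose_training_image",
    "train_pixel_classifier",
    "apply_classifier",
]

DEFAULT_TOLERANCE = 60.0
DEFAULT_WORKING_UM_PER_PX = 0.91
CLASSIFIER_FORMAT_VERSION = 1

LABEL_UNLABELED, LABEL_POSITIVE, LABEL_NEGATIVE = 0, 1, 2


@dataclass(frozen=True)
class ColorRangeSpec:
    """One or more reference RGB colors plus a maximum Euclidean RGB distance.

    Multiple reference colors mirror shift-clicking several target-cell
    colors; tolerance 0 selects exact colors only. The maximum possible RGB
    distance is sqrt(3) * 255 ~ 441.7.
    """

    reference_colors: tuple[tuple[int, int, int], ...]
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        colors = tuple(tuple(int(v) for v in c) for c in self.reference_colors)
        if len(colors) < 1:
            raise StainClassificationError("need at least one reference color")
        for c in colors:
            if len(c) != 3 or any(v < 0 or v > 255 for v in c):
                raise StainClassificationError(f"invalid RGB triplet {c!r}")
        if not (0 <= self.tolerance <= math.sqrt(3) * 255 + 1):
            raise StainClassificationError(f"tolerance out of range: {self.tolerance!r}")
        object.__setattr__(self, "reference_colors", colors)


@dataclass
class PositiveMask:
    """Per-pixel stain classification with its provenance."""

    mask: np.ndarray  # H x W bool
    provenance: str = "threshold"  # threshold | classifier | manual

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise StainClassificationError("mask must be 2-D")
        if self.provenance not in {"threshold", "classifier", "manual"}:
            raise StainClassificationError(f"unknown provenance {self.provenance!r}")

    @property
    def area_px(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class TrainingTile:
    """A square annotated tile at native resolution.

    ``labels`` holds per-pixel classes: 0 unlabeled, 1 positive, 2 negative.
    """

    pixels: np.ndarray  # h x w x 3 uint8
    labels: np.ndarray  # h x w int8
    side_um: float
    calibration: ScaleCalibration

    def __post_init__(self) -> None:
        if self.side_um <= 0:
            raise StainClassificationError("tile side length must be positive")
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != self.pixels.shape[:2]:
            raise StainClassificationError("tile labels must match tile pixels in shape")
        if not np.any(self.labels != LABEL_UNLABELED):
            raise StainClassificationError("tile has no labeled pixels")


def threshold_classify(image: CalibratedImage, spec: ColorRangeSpec) -> PositiveMask:
    """Mark pixels whose RGB distance to the nearest reference color is within
    the tolerance. Monotone in tolerance: a larger tolerance can only add
    pixels."""
    px = image.pixels.astype(np.float64)
    best = np.full(image.shape, np.inf)
    for color in spec.reference_colors:
        d2 = ((px - np.asarray(color, dtype=np.float64)) ** 2).sum(axis=2)
        np.minimum(best, d2, out=best)
    return PositiveMask(best <= spec.tolerance**2, provenance="threshold")


def coherence_expand(mask: PositiveMask, radius_px: int = 2) -> PositiveMask:
    """Dilate the mask by a discrete disk (offsets with dx^2 + dy^2 <= r^2) to
    make a fragmented selection coherent. Extensive (output contains input)
    and monotone in radius."""
    if radius_px < 1:
        raise StainClassificationError("radius_px must be >= 1")
    grown = dilation(mask.mask, footprint=disk(int(radius_px)))
    return PositiveMask(grown, provenance=mask.provenance)


def apply_mask_edits(mask: PositiveMask, edit_polygons) -> PositiveMask:
    """Apply manual corrections as an XOR edit layer: each polygon flips the
    classification of the pixels it covers (the non-interactive counterpart of
    erasing/painting obvious misclassifications)."""
    out = mask.mask.copy()
    for poly in edit_polygons:
        out ^= build_epidermis_mask(poly, out.shape)
    return PositiveMask(out, provenance="manual")


def _resample_tile(tile: TrainingTile, working_um_per_px: float):
    side_wk = max(1, round(tile.side_um / working_um_per_px))
    px = resize(
        tile.pixels.astype(np.float64),
        (side_wk, side_wk, 3),
        order=1,
        anti_aliasing=True,
        preserve_range=True,
    )
    onehot = np.stack([tile.labels == k for k in (0, 1, 2)], axis=-1).astype(np.float64)
    onehot_wk = resize(onehot, (side_wk, side_wk, 3), order=1, anti_aliasing=False,
                       preserve_range=True)
    labels_wk = np.argmax(onehot_wk, axis=-1).astype(np.int8)
    return px, labels_wk


def compose_training_image(
    tiles: list[TrainingTile], working_um_per_px: float = DEFAULT_WORKING_UM_PER_PX
) -> tuple[np.ndarray, np.ndarray]:
    """Resample every tile to the working resolution and assemble a grid
    montage, carrying labels along. Returns ``(pixels, labels)``; montage
    cells not covered by a tile are unlabeled."""
    if not tiles:
        raise StainClassificationError("cannot compose a training image from zero tiles")
    blocks = [_resample_tile(t, working_um_per_px) for t in tiles]
    side = max(b[0].shape[0] for b in blocks)
    ncol = math.ceil(math.sqrt(len(blocks)))
    nrow = math.ceil(len(blocks) / ncol)
    pixels = np.zeros((nrow * side, ncol * side, 3), dtype=np.float64)
    labels = np.full((nrow * side, ncol * side), LABEL_UNLABELED, dtype=np.int8)
    for i, (bpx, blab) in enumerate(blocks):
        r0, c0 = (i // ncol) * side, (i % ncol) * side
        h, w = blab.shape
        pixels[r0 : r0 + h, c0 : c0 + w] = bpx
        labels[r0 : r0 + h, c0 : c0 + w] = blab
    return pixels, labels


def _compute_features(rgb: np.ndarray) -> np.ndarray:
    """Feature stack at working resolution: intensity, Gaussian sigma 1 and 2,
    gradient magnitude — each per channel (12 features)."""
    feats = [rgb[..., k] for k in range(3)]
    for sigma in (1.0, 2.0):
        for k in range(3):
            feats.append(ndimage.gaussian_filter(rgb[..., k], sigma=sigma))
    for k in range(3):
        gr = ndimage.sobel(rgb[..., k], axis=0)
        gc = ndimage.sobel(rgb[..., k], axis=1)
        feats.append(np.hypot(gr, gc))
    return np.stack(feats, axis=-1)


@dataclass
class PixelClassifier:
    """A trained shallow per-pixel stain classifier plus its feature recipe
    and working resolution; refuses to predict before training."""

    working_um_per_px: float = DEFAULT_WORKING_UM_PER_PX
    model: object | None = None
    recipe: dict = field(
        default_factory=lambda: {
            "features": "rgb + gaussian(sigma=1,2) + gradient magnitude, per channel",
            "n_features": 12,
        }
    )
    training_accuracy: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.working_um_per_px <= 0:
            raise StainClassificationError("working resolution must be positive")

    @property
    def is_trained(self) -> bool:
        return self.model is not None

    def save(self, path) -> None:
        joblib.dump(
            {
                "format_version": CLASSIFIER_FORMAT_VERSION,
                "working_um_per_px": self.working_um_per_px,
                "recipe": self.recipe,
                "model": self.model,
                "training_accuracy": self.training_accuracy,
                "seed": self.seed,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "PixelClassifier":
        blob = joblib.load(path)
        if blob.get("format_version") != CLASSIFIER_FORMAT_VERSION:
            raise StainClassificationError(
                f"unsupported classifier file version {blob.get('format_version')!r}"
            )
        return cls(
            working_um_per_px=blob["working_um_per_px"],
            model=blob["model"],
            recipe=blob["recipe"],
            training_accuracy=blob["training_accuracy"],
            seed=blob.get("seed", 0),
        )


def train_pixel_classifier(
    composite_pixels: np.ndarray,
    composite_labels: np.ndarray,
    seed: int = 0,
    working_um_per_px: float = DEFAULT_WORKING_UM_PER_PX,
    hidden_layer_sizes: tuple[int, ...] = (16,),
    max_train_px: int = 20000,
) -> PixelClassifier:
    """Train the MLP pixel classifier on a labeled training montage.

    Requires at least one positive and one negative labeled pixel. Training
    pixels are subsampled (deterministically, from ``seed``) when the montage
    carries more labels than ``max_train_px``; accuracy is reported on all
    labeled pixels.
    """
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    labels = np.asarray(composite_labels)
    feats = _compute_features(np.asarray(composite_pixels, dtype=np.float64))
    labeled = labels != LABEL_UNLABELED
    y_all = labels[labeled]
    if np.unique(y_all).size < 2:
        raise StainClassificationError(
            "single-class training data: need both positive and negative labels"
        )
    x_all = feats[labeled]
    if y_all.size > max_train_px:
        rng = np.random.default_rng(seed)
        idx = rng.choice(y_all.size, size=max_train_px, replace=False)
        x_fit, y_fit = x_all[idx], y_all[idx]
        if np.unique(y_fit).size < 2:  # resample guard for extreme imbalance
            idx = np.concatenate(
                [np.nonzero(y_all == c)[0][: max_train_px // 2] for c in (1, 2)]
            )
            x_fit, y_fit = x_all[idx], y_all[idx]
    else:
        x_fit, y_fit = x_all, y_all
    model = make_pipeline(
        StandardScaler(),
        MLPClassifier(
            hidden_layer_sizes=hidden_layer_sizes,
            max_iter=400,
            random_state=int(seed),
        ),
    )
    model.fit(x_fit, y_fit)
    accuracy = float(np.mean(model.predict(x_all) == y_all))
    return PixelClassifier(
        working_um_per_px=working_um_per_px,
        model=model,
        training_accuracy=accuracy,
        seed=int(seed),
    )


def apply_classifier(image: CalibratedImage, clf: PixelClassifier) -> PositiveMask:
    """Classify every pixel: resample the image to the working resolution
    (area-weighted), predict, and upsample the binary result back to native
    resolution with nearest-neighbor so the mask stays binary."""
    if not clf.is_trained:
        raise StainClassificationError("classifier has not been trained")
    h, w = image.shape
    scale = clf.working_um_per_px * image.calibration.pixels_per_um  # native px per working px
    wk_shape = (max(1, round(h / scale)), max(1, round(w / scale)))
    rgb_wk = resize(
        image.pixels.astype(np.float64),
        (*wk_shape, 3),
        order=1,
        anti_aliasing=scale > 1,
        preserve_range=True,
    )
    feats = _compute_features(rgb_wk)
    pred = clf.model.predict(feats.reshape(-1, feats.shape[-1])).reshape(wk_shape)
    mask_wk = pred == LABEL_POSITIVE
    mask = resize(mask_wk.astype(np.float64), (h, w), order=0, preserve_range=True) > 0.5
    return PositiveMask(mask, provenance="classifier")
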