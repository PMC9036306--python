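"""Calibrated RGB image container and TIFF/PNG reading and writing.

Coordinate convention (package-wide): row-major ``(row, col)``, 0-based, with
the top-left pixel at (0, 0) and pixel centers at integer coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import tifffile

from .calibration import ScaleCalibration
from .errors import ImageIOError

__all__ = ["CalibratedImage", "read_image", "write_image", "write_mask_png"]


@dataclass
class CalibratedImage:
    """An 8-bit RGB raster with a mandatory physical scale.

    Calibration is never guessed from file metadata; the caller supplies it
    (typically from a measured scale bar).
    """

    pixels: np.ndarray  # H x W x 3 uint8
    calibration: ScaleCalibration

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageIOError(f"expected an H x W x 3 RGB array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageIOError("image must have at least one row and one column")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise ImageIOError(f"expected 8-bit channel data, got dtype {px.dtype}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def read_image(path: str | os.PathLike, calibration: ScaleCalibration) -> CalibratedImage:
    """Read a TIFF or PNG file as a calibrated RGB image.

    Grayscale or RGBA input is rejected: the stain-classification layers
    operate on plain 3-channel RGB and silent channel dropping would change
    colors under the caller's feet.
    """
    if calibration is None:
        raise ImageIOError("a ScaleCalibration is required to read an image")
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ImageIOError(f"image file not found: {path}")
    try:
        if path.lower().endswith((".tif", ".tiff")):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize decoder errors
        raise ImageIOError(f"could not decode image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageIOError(
            f"non-RGB image data in {path} (shape {arr.shape}); expected H x W x 3"
        )
    return CalibratedImage(pixels=arr, calibration=calibration)


def write_image(image: CalibratedImage | np.ndarray, path: str | os.PathLike) -> None:
    """Write an RGB image to TIFF or PNG (chosen by file extension)."""
    arr = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
        raise ImageIOError("write_image expects an H x W x 3 uint8 array")
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_mask_png(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a boolean mask as a single-channel 0/255 PNG."""
    mask = np.asarray(mask, dtype=bool)
    iio.imwrite(os.fspath(path), (mask.astype(np.uint8) * 255))
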