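"""Pixel <-> micrometre scale calibration.

All physical units in the package flow through a :class:`ScaleCalibration`,
which is built either directly from a pixels-per-micrometre value or from a
measured scale bar (a length in pixels paired with the physical length it
represents). Geometry is kept in pixel units internally and converted to
micrometres only at reporting time, so this module is the single point where
unit conversion happens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import CalibrationError

__all__ = [
    "ScaleCalibration",
    "calibrate_from_scale_bar",
    "um_to_px",
    "px_to_um",
    "split_dilation_steps",
]


@dataclass(frozen=True)
class ScaleCalibration:
    """Scale of an image, as pixels per micrometre.

    For a slide where a 100 um scale bar spans 220 pixels the calibration is
    2.2 px/um.
    """

    pixels_per_um: float

    def __post_init__(self) -> None:
        if not (self.pixels_per_um > 0) or not math.isfinite(self.pixels_per_um):
            raise CalibrationError(
                f"pixels_per_um must be a positive finite number, got {self.pixels_per_um!r}"
            )

    @property
    def um_per_px(self) -> float:
        return 1.0 / self.pixels_per_um

    def um_to_px(self, distance_um: float) -> float:
        return um_to_px(distance_um, self)

    def px_to_um(self, distance_px: float) -> float:
        return px_to_um(distance_px, self)

    def px2_to_um2(self, area_px: float) -> float:
        """Convert a pixel count (area in px^2) to um^2."""
        return area_px / (self.pixels_per_um**2)


def calibrate_from_scale_bar(bar_length_px: float, bar_length_um: float) -> ScaleCalibration:
    """Build a calibration from a measured scale bar.

    Parameters
    ----------
    bar_length_px : length of the scale bar in pixels.
    bar_length_um : physical length of the scale bar in micrometres.
    """
    if not (bar_length_px > 0) or not (bar_length_um > 0):
        raise CalibrationError(
            "scale bar lengths must both be positive "
            f"(got {bar_length_px!r} px, {bar_length_um!r} um)"
        )
    return ScaleCalibration(pixels_per_um=bar_length_px / bar_length_um)


def um_to_px(distance_um: float, calib: ScaleCalibration) -> float:
    """Convert a nonnegative distance in micrometres to pixels."""
    if distance_um < 0:
        raise CalibrationError(f"distance must be nonnegative, got {distance_um!r} um")
    return distance_um * calib.pixels_per_um


def px_to_um(distance_px: float, calib: ScaleCalibration) -> float:
    """Convert a nonnegative distance in pixels to micrometres."""
    if distance_px < 0:
        raise CalibrationError(f"distance must be nonnegative, got {distance_px!r} px")
    return distance_px / calib.pixels_per_um


def split_dilation_steps(total_px: int, max_step_px: int) -> list[int]:
    """Split a pixel expansion into the fewest near-equal integer steps.

    Some raster editors cap a single "expand selection" operation (Photoshop
    caps it at 500 px), so an 880 px expansion has to be applied as two 440 px
    steps. The returned steps are as equal as possible (pairwise difference at
    most 1), each no larger than ``max_step_px``, and sum to ``total_px``.
    """
    total_px = int(total_px)
    max_step_px = int(max_step_px)
    if total_px < 1 or max_step_px < 1:
        raise CalibrationError(
            f"total_px and max_step_px must be >= 1 (got {total_px}, {max_step_px})"
        )
    n_steps = -(-total_px // max_step_px)  # ceil division
    base, remainder = divmod(total_px, n_steps)
    return [base + 1] * remainder + [base] * (n_steps - remainder)
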