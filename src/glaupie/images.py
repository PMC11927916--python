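"""Core raster containers shared across the pipeline.

Two coordinate systems appear throughout: the Cartesian fundus raster
(x rightward, y downward, 0-based, half-open pixel intervals) and the
polar raster (rows index radius from the disc centre, columns index the
angle swept counterclockwise -- in display convention, y up -- from the
nasal direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

EYE_SIDES = ("OD", "OS")
LABELS = ("G", "S", "N")
AGREEMENT_TIERS = ("3/3", "2/3")


@dataclass
class FundusImage:
    """RGB fundus raster tagged with the eye side it was captured from.

    ``pixels`` is an ``(H, W, 3)`` array, either uint8 in [0, 255] or
    float in [0, 1].  ``eye_side`` is ``"OD"`` (right eye) or ``"OS"``
    (left eye); the polar pipeline mirrors OS images so that the nasal
    side is consistent across eyes.
    """

    pixels: np.ndarray
    eye_side: str = "OD"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"FundusImage requires an (H, W, 3) raster, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("FundusImage must be at least 1x1 pixel")
        if self.eye_side not in EYE_SIDES:
            raise ValueError(f"eye_side must be one of {EYE_SIDES}, got {self.eye_side!r}")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def as_float(self) -> np.ndarray:
        """Pixels as float64 in [0, 1]."""
        px = self.pixels
        if np.issubdtype(px.dtype, np.integer):
            return px.astype(np.float64) / 255.0
        return px.astype(np.float64)

    def as_uint8(self) -> np.ndarray:
        px = self.pixels
        if np.issubdtype(px.dtype, np.integer):
            return px.astype(np.uint8)
        return np.clip(np.round(px * 255.0), 0, 255).astype(np.uint8)

    def copy(self) -> "FundusImage":
        return FundusImage(self.pixels.copy(), self.eye_side)


@dataclass
class PolarImage:
    """Raster indexed by (radius row, angle column) about a disc centre.

    Row 0 is the centre (r = 0) and row ``R_h - 1`` maps to ``r_max``
    source pixels.  Column ``j`` spans the angle ``[j, j+1) * 360 / R_w``
    degrees measured counterclockwise (display convention) from the
    nasal angular origin.
    """

    pixels: np.ndarray
    r_max: float
    source_center: Tuple[float, float]  # (x_c, y_c) in the source raster
    source_shape: Tuple[int, int] = (0, 0)  # (H, W) of the source raster
    source_eye_side: str = "OD"
    angular_origin: str = "nasal"
    direction: str = "counterclockwise"
    nasal_side: str = "right"
    excluded_region: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("PolarImage pixels must be 2-D or (R_h, R_w, 3)")
        if self.R_h < 1 or self.R_w < 1:
            raise ValueError("PolarImage must have R_h, R_w >= 1")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")

    @property
    def R_h(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def R_w(self) -> int:
        return int(self.pixels.shape[1])

    def column_angles_deg(self) -> np.ndarray:
        """Left-edge angle of every column, in degrees from the nasal origin."""
        return np.arange(self.R_w) * 360.0 / self.R_w

    def copy(self) -> "PolarImage":
        return replace(self, pixels=self.pixels.copy())
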