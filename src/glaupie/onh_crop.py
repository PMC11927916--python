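"""Optic-nerve-head crop extraction and CLAHE preprocessing.

The crop window is derived from the disc segmentation by the
centroid-padding rule: the box is centred on the mask centre of mass and
spans ``w_max * (1 + delta)`` by ``h_max * (1 + delta)`` pixels, where
``w_max`` / ``h_max`` are the mask bounding-box extents and ``delta``
(default 0.5) is the padding fraction.  Coordinates are 0-based with
half-open intervals [lo, hi); bounds are floored/ceiled so no disc pixel
is ever lost.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import color, exposure

from .images import FundusImage

logger = logging.getLogger(__name__)


@dataclass
class PaddingBox:
    """Half-open crop window [x_lo, x_hi) x [y_lo, y_hi) around the disc."""

    x_centroid: float
    y_centroid: float
    w_max: int
    h_max: int
    delta: float
    x_lo: int
    x_hi: int
    y_lo: int
    y_hi: int

    @property
    def width(self) -> int:
        return self.x_hi - self.x_lo

    @property
    def height(self) -> int:
        return self.y_hi - self.y_lo

    def mirrored(self, image_width: int) -> "PaddingBox":
        """The box of the horizontally mirrored image ([lo, hi) half-open)."""
        return PaddingBox(
            image_width - 1 - self.x_centroid, self.y_centroid, self.w_max, self.h_max,
            self.delta, image_width - self.x_hi, image_width - self.x_lo,
            self.y_lo, self.y_hi,
        )

    def shifted(self, dx: int, dy: int) -> "PaddingBox":
        return PaddingBox(
            self.x_centroid + dx, self.y_centroid + dy, self.w_max, self.h_max,
            self.delta, self.x_lo + dx, self.x_hi + dx, self.y_lo + dy, self.y_hi + dy,
        )


def compute_padding_box(
    disc_mask: np.ndarray,
    delta: float = 0.5,
    image_shape: Optional[Tuple[int, int]] = None,
) -> PaddingBox:
    """Centroid-padding window from a binary disc mask.

    Parameters
    ----------
    disc_mask
        Binary (H, W) raster; nonzero pixels belong to the optic disc.
    delta
        Padding fraction; the window spans ``(1 + delta)`` times the mask
        bounding box in each dimension.
    image_shape
        Optional (H, W) extent to clip the window to; clipping is logged.
    """
    mask = np.asarray(disc_mask) > 0
    if not mask.any():
        raise ValueError("no disc region: the mask is empty")
    cy, cx = ndimage.center_of_mass(mask)
    ys, xs = np.nonzero(mask)
    w_max = int(xs.max() - xs.min() + 1)
    h_max = int(ys.max() - ys.min() + 1)
    half_w = (w_max / 2.0) * (1.0 + delta)
    half_h = (h_max / 2.0) * (1.0 + delta)
    x_lo, x_hi = math.floor(cx - half_w), math.ceil(cx + half_w)
    y_lo, y_hi = math.floor(cy - half_h), math.ceil(cy + half_h)
    if image_shape is not None:
        h, w = image_shape[:2]
        cx_lo, cx_hi = max(x_lo, 0), min(x_hi, w)
        cy_lo, cy_hi = max(y_lo, 0), min(y_hi, h)
        if (cx_lo, cx_hi, cy_lo, cy_hi) != (x_lo, x_hi, y_lo, y_hi):
            logger.info(
                "padding box clipped to image extent: x [%d, %d) -> [%d, %d), "
                "y [%d, %d) -> [%d, %d)",
                x_lo, x_hi, cx_lo, cx_hi, y_lo, y_hi, cy_lo, cy_hi,
            )
        x_lo, x_hi, y_lo, y_hi = cx_lo, cx_hi, cy_lo, cy_hi
    return PaddingBox(cx, cy, w_max, h_max, delta, x_lo, x_hi, y_lo, y_hi)


def crop_local(image: FundusImage, box: PaddingBox) -> FundusImage:
    """Extract the box from the image; out-of-bounds area is zero-filled."""
    h, w = image.height, image.width
    if box.x_hi <= 0 or box.x_lo >= w or box.y_hi <= 0 or box.y_lo >= h:
        raise ValueError("padding box does not overlap the image")
    out = np.zeros((box.height, box.width, 3), dtype=image.pixels.dtype)
    sx_lo, sx_hi = max(box.x_lo, 0), min(box.x_hi, w)
    sy_lo, sy_hi = max(box.y_lo, 0), min(box.y_hi, h)
    out[sy_lo - box.y_lo : sy_hi - box.y_lo, sx_lo - box.x_lo : sx_hi - box.x_lo] = (
        image.pixels[sy_lo:sy_hi, sx_lo:sx_hi]
    )
    return FundusImage(out, image.eye_side)


def crop_mask(mask: np.ndarray, box: PaddingBox) -> np.ndarray:
    """Crop a single-channel mask with the same zero-fill geometry."""
    mask = np.asarray(mask)
    h, w = mask.shape[:2]
    out = np.zeros((box.height, box.width), dtype=mask.dtype)
    sx_lo, sx_hi = max(box.x_lo, 0), min(box.x_hi, w)
    sy_lo, sy_hi = max(box.y_lo, 0), min(box.y_hi, h)
    out[sy_lo - box.y_lo : sy_hi - box.y_lo, sx_lo - box.x_lo : sx_hi - box.x_lo] = (
        mask[sy_lo:sy_hi, sx_lo:sx_hi]
    )
    return out


def apply_clahe(
    image: FundusImage,
    clip_limit: float = 2.0,
    tile_grid: Tuple[int, int] = (8, 8),
) -> FundusImage:
    """Contrast-limited adaptive histogram equalization on the LAB L channel.

    ``clip_limit`` uses the conventional histogram-clip scale (default
    2.0) and is mapped internally onto the normalized (0, 1] scale of
    the underlying skimage kernel as ``clip_limit / 100``.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    rgb = image.as_float()
    lab = color.rgb2lab(rgb)
    lum = lab[..., 0] / 100.0  # L in [0, 100] -> [0, 1]
    h, w = lum.shape
    kernel = (max(1, h // tile_grid[0]), max(1, w // tile_grid[1]))
    if lum.max() > lum.min():
        lum_eq = exposure.equalize_adapthist(
            np.clip(lum, 0.0, 1.0), kernel_size=kernel,
            clip_limit=min(1.0, clip_limit / 100.0),
        )
    else:
        lum_eq = lum  # constant image: nothing to equalize
    lab_eq = lab.copy()
    lab_eq[..., 0] = lum_eq * 100.0
    with warnings.catch_warnings():
        # boosting L can push saturated pixels slightly out of the sRGB
        # gamut; clipping is the intended behaviour
        warnings.filterwarnings("ignore", message=".*negative Z values.*")
        out = np.clip(color.lab2rgb(lab_eq), 0.0, 1.0)
    if np.issubdtype(image.pixels.dtype, np.integer):
        out = np.round(out * 255.0).astype(np.uint8)
    return FundusImage(out, image.eye_side)
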