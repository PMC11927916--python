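"""Cartesian <-> polar resampling with ISNT-aligned angular conventions.

The polar raster puts radius on rows (row 0 = disc centre, last row =
``r_max``) and angle on columns.  The angular origin is the nasal
direction, and the sweep is counterclockwise in display convention
(y up).  Left-eye (OS) images are first mirrored horizontally so that
the nasal side matches the right-eye (OD) orientation; by default the
nasal direction of an OD-oriented crop is image right (+x), which is
configurable because different capture setups disagree.

Radius r and angle theta of a point relative to the centre follow
r = sqrt(x_d^2 + y_d^2) with x_d = x - x_c, y_d = y - y_c; theta is
computed with the full-quadrant two-argument arctangent so the sweep
covers the full 360 degrees exactly once.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .images import FundusImage, PolarImage

logger = logging.getLogger(__name__)

_NASAL_OFFSETS_DEG = {"right": 0.0, "left": 180.0}


def orient_for_eye(image: FundusImage) -> FundusImage:
    """Return an OD-oriented image: OD unchanged, OS mirrored horizontally."""
    if image.eye_side == "OD":
        return FundusImage(image.pixels.copy(), "OD")
    if image.eye_side == "OS":
        return FundusImage(image.pixels[:, ::-1].copy(), "OD")
    raise ValueError(f"unknown eye_side {image.eye_side!r}")


def _angles_to_cartesian(
    r: np.ndarray, theta_rad: np.ndarray, center: Tuple[float, float], nasal_side: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Map (r, theta-from-nasal, ccw display) to raster (x, y)."""
    offset = np.deg2rad(_NASAL_OFFSETS_DEG[nasal_side])
    ang = theta_rad + offset
    x = center[0] + r * np.cos(ang)
    y = center[1] - r * np.sin(ang)  # display y-up == raster y-down flip
    return x, y


def to_polar(
    image: FundusImage,
    center: Optional[Tuple[float, float]] = None,
    r_max: Optional[float] = None,
    R_h: int = 224,
    R_w: int = 224,
    nasal_side: str = "right",
    order: int = 1,
) -> PolarImage:
    """Resample an OD-oriented crop onto the (radius, angle) grid.

    Output pixel (i, j) samples the Cartesian point at radius
    ``i * r_max / (R_h - 1)`` and angle ``j * 360 / R_w`` degrees
    counterclockwise (display convention) from the nasal direction.
    Samples beyond the image are zero-filled.
    """
    if nasal_side not in _NASAL_OFFSETS_DEG:
        raise ValueError("nasal_side must be 'right' or 'left'")
    px = image.as_float()
    h, w = px.shape[:2]
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    if not (0 <= center[0] <= w - 1 and 0 <= center[1] <= h - 1):
        raise ValueError(f"centre {center} lies outside the image ({w} x {h})")
    if r_max is None:
        r_max = min(h, w) / 2.0
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    max_avail = max(
        center[0], w - 1 - center[0], center[1], h - 1 - center[1]
    )
    if r_max > max_avail + 1:
        logger.warning(
            "r_max %.1f exceeds the image extent around the centre; "
            "out-of-bounds samples are zero-filled", r_max,
        )

    rows = np.arange(R_h, dtype=np.float64)
    r = rows * (r_max / (R_h - 1)) if R_h > 1 else np.zeros(1)
    theta = np.arange(R_w, dtype=np.float64) * (2.0 * np.pi / R_w)
    rr, tt = np.meshgrid(r, theta, indexing="ij")
    x, y = _angles_to_cartesian(rr, tt, center, nasal_side)
    out = np.empty((R_h, R_w, 3), dtype=np.float64)
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(
            px[..., c], [y, x], order=order, mode="constant", cval=0.0
        )
    return PolarImage(
        out,
        r_max=float(r_max),
        source_center=(float(center[0]), float(center[1])),
        source_shape=(h, w),
        source_eye_side=image.eye_side,
        nasal_side=nasal_side,
    )


def from_polar(
    polar: PolarImage,
    out_size: Optional[Tuple[int, int]] = None,
    order: int = 1,
) -> FundusImage:
    """Inverse resampling back onto the Cartesian grid.

    Pixels beyond ``r_max`` are zero.  The output defaults to the source
    raster geometry recorded in the polar image so that
    ``from_polar(to_polar(img))`` reconstructs ``img`` inside the disc.
    """
    if polar.source_center is None or polar.r_max is None:
        raise ValueError("polar image is missing centre / r_max metadata")
    if out_size is None:
        if polar.source_shape == (0, 0):
            raise ValueError("polar image has no source shape; pass out_size")
        h, w = polar.source_shape
        center = polar.source_center
    else:
        h, w = out_size
        center = ((w - 1) / 2.0, (h - 1) / 2.0)

    ys, xs = np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64),
                         indexing="ij")
    dx = xs - center[0]
    dy = center[1] - ys  # display y-up
    rr = np.hypot(dx, dy)
    offset = np.deg2rad(_NASAL_OFFSETS_DEG[polar.nasal_side])
    theta = np.mod(np.arctan2(dy, dx) - offset, 2.0 * np.pi)

    R_h, R_w = polar.R_h, polar.R_w
    row = rr * ((R_h - 1) / polar.r_max)
    col = theta * (R_w / (2.0 * np.pi))
    px = polar.pixels
    if px.ndim == 2:
        px = px[..., None].repeat(3, axis=2)
    # wrap the angular axis so interpolation crosses the nasal seam
    wrapped = np.concatenate([px, px[:, :1]], axis=1)
    out = np.empty((h, w, 3), dtype=np.float64)
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(
            wrapped[..., c], [row, col], order=order, mode="constant", cval=0.0
        )
    out[rr > polar.r_max] = 0.0
    return FundusImage(out, polar.source_eye_side)


def region_angle_mask(
    polar: PolarImage, intervals, h: int, w: int, center: Tuple[float, float]
) -> np.ndarray:
    """Boolean Cartesian mask of the pixels whose angle falls in ``intervals``.

    Helper for sector-localization checks and overlay rendering; the
    angle convention matches :func:`from_polar`.
    """
    ys, xs = np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64),
                         indexing="ij")
    dx = xs - center[0]
    dy = center[1] - ys
    offset = np.deg2rad(_NASAL_OFFSETS_DEG[polar.nasal_side])
    theta = np.degrees(np.mod(np.arctan2(dy, dx) - offset, 2.0 * np.pi))
    mask = np.zeros((h, w), dtype=bool)
    for a, b in intervals:
        mask |= (theta >= a) & (theta < b)
    return mask
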