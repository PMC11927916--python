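"""Synthetic optic-nerve-head fundus generator.

Renders ONH-centred fundus-like crops with elliptical optic disc and
cup, a neuroretinal rim whose angular thickness profile is controlled
per ISNT quadrant, vessel-like curvilinear structures, a low-frequency
background field and additive noise.  Class semantics follow the ISNT
rule: healthy rims order inferior > superior > nasal > temporal; the
glaucoma and suspect presets violate that ordering (and glaucoma adds a
focal notch).  Everything is deterministic for a fixed seed, and a left
eye is the exact horizontal mirror of the right eye generated from the
same seed.

This emulates the geometry a screening pipeline cares about -- rim/CDR
structure, eye sides, label tiers -- not photorealistic retina texture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.morphology import dilation, disk

from .images import AGREEMENT_TIERS, EYE_SIDES, LABELS, FundusImage

logger = logging.getLogger(__name__)

# quadrant mid-angles in the OD-oriented display convention
# (counterclockwise from nasal = image right)
QUADRANT_MID_ANGLES = {"nasal": 0.0, "superior": 90.0, "temporal": 180.0, "inferior": 270.0}

# Class presets: cup-to-disc ratio and rim-thickness multipliers per
# quadrant.  N obeys the ISNT ordering; S shows a borderline
# superior-over-inferior violation; G shows marked inferior thinning
# plus a notch.
CLASS_PRESETS: Dict[str, dict] = {
    "N": {"cup_to_disc_ratio": 0.40,
          "rim_profile": {"inferior": 1.30, "superior": 1.10, "nasal": 0.90, "temporal": 0.70},
          "notch": None},
    "S": {"cup_to_disc_ratio": 0.60,
          "rim_profile": {"inferior": 1.00, "superior": 1.10, "nasal": 0.95, "temporal": 0.80},
          "notch": None},
    "G": {"cup_to_disc_ratio": 0.75,
          "rim_profile": {"inferior": 0.70, "superior": 1.15, "nasal": 1.00, "temporal": 0.85},
          "notch": (270.0, 0.5, 25.0)},  # (angle deg, depth fraction, width deg)
}

_BG_COLOR = np.array([0.72, 0.33, 0.16])
_RIM_COLOR = np.array([0.93, 0.72, 0.42])
_CUP_COLOR = np.array([0.98, 0.88, 0.62])


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic ONH crop."""

    label: str = "N"
    eye_side: str = "OD"
    image_size: int = 448
    disc_radius: float = 100.0
    cup_to_disc_ratio: float = 0.40
    rim_profile: Mapping[str, float] = field(
        default_factory=lambda: dict(CLASS_PRESETS["N"]["rim_profile"])
    )
    notch: Optional[Tuple[float, float, float]] = None
    vessel_count: int = 4
    noise_sd: float = 0.015
    seed: int = 0
    frame_size: Optional[Tuple[int, int]] = None  # (W, H), e.g. (1600, 1216)

    def validate(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if self.eye_side not in EYE_SIDES:
            raise ValueError(f"eye_side must be one of {EYE_SIDES}")
        if not 0.0 < self.cup_to_disc_ratio < 1.0:
            raise ValueError(
                f"cup_to_disc_ratio must lie strictly in (0, 1), got {self.cup_to_disc_ratio}"
            )
        if self.disc_radius <= 2:
            raise ValueError("disc_radius must exceed 2 pixels")
        if 2 * self.disc_radius * 1.1 >= self.image_size:
            raise ValueError(
                f"disc radius {self.disc_radius} exceeds the {self.image_size}-px image bounds"
            )
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be >= 0")
        missing = set(QUADRANT_MID_ANGLES) - set(self.rim_profile)
        if missing:
            raise ValueError(f"rim_profile missing quadrants: {sorted(missing)}")
        mults = np.array([self.rim_profile[q] for q in QUADRANT_MID_ANGLES])
        if (mults <= 0).any():
            raise ValueError("rim_profile multipliers must be positive")
        if (1 - self.cup_to_disc_ratio) * mults.max() / mults.mean() >= 1.0:
            raise ValueError("rim profile too thick: cup would not fit inside the disc")


def spec_for_label(label: str, seed: int = 0, **overrides) -> SynthSpec:
    """Class-preset spec (CDR, rim profile, notch) with optional overrides."""
    preset = CLASS_PRESETS[label]
    kwargs = dict(
        label=label,
        cup_to_disc_ratio=preset["cup_to_disc_ratio"],
        rim_profile=dict(preset["rim_profile"]),
        notch=preset["notch"],
        seed=seed,
    )
    kwargs.update(overrides)
    return SynthSpec(**kwargs)


def _profile_at(spec: SynthSpec, theta_deg: np.ndarray) -> np.ndarray:
    """Smooth periodic rim multiplier at each angle, normalized to mean 1."""
    angles = np.array([0.0, 90.0, 180.0, 270.0, 360.0])
    names = ["nasal", "superior", "temporal", "inferior", "nasal"]
    values = np.array([spec.rim_profile[n] for n in names])
    prof = np.interp(np.mod(theta_deg, 360.0), angles, values)
    prof = prof / np.mean([spec.rim_profile[n] for n in QUADRANT_MID_ANGLES])
    if spec.notch is not None:
        a0, depth, width = spec.notch
        d = np.mod(theta_deg - a0 + 180.0, 360.0) - 180.0
        prof = prof * (1.0 - depth * np.exp(-0.5 * (d / width) ** 2))
    return prof


def _ellipse_radius(theta_deg: np.ndarray, a: float, b: float) -> np.ndarray:
    """Radius of an axis-aligned ellipse (a horizontal, b vertical semi-axis)."""
    t = np.deg2rad(theta_deg)
    return a * b / np.hypot(b * np.cos(t), a * np.sin(t))


def disc_cup_radii(spec: SynthSpec, theta_deg: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Disc and cup boundary radii at each display angle (degrees from +x)."""
    r_disc = _ellipse_radius(theta_deg, 0.92 * spec.disc_radius, spec.disc_radius)
    rim = (1.0 - spec.cup_to_disc_ratio) * r_disc * _profile_at(spec, theta_deg)
    r_cup = np.maximum(r_disc - rim, 1.0)
    return r_disc, r_cup


def _soft_edge(boundary_r: np.ndarray, r: np.ndarray, width: float = 1.5) -> np.ndarray:
    return np.clip((boundary_r - r) / width + 0.5, 0.0, 1.0)


def generate_fundus(spec: SynthSpec) -> Tuple[FundusImage, np.ndarray, np.ndarray]:
    """Render one crop; returns (image, disc mask, cup mask).

    Masks are uint8 0/255 filled ellipse-like regions.  For OS the
    entire output is the exact horizontal mirror of the OD output with
    the same seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    cx = cy = (n - 1) / 2.0

    ys, xs = np.meshgrid(np.arange(n, dtype=np.float64), np.arange(n, dtype=np.float64),
                         indexing="ij")
    dx, dy = xs - cx, cy - ys  # display y-up
    r = np.hypot(dx, dy)
    theta = np.degrees(np.mod(np.arctan2(dy, dx), 2 * np.pi))
    r_disc, r_cup = disc_cup_radii(spec, theta)

    disc_mask = (r <= r_disc).astype(np.uint8) * 255
    cup_mask = (r <= r_cup).astype(np.uint8) * 255

    disc_soft = _soft_edge(r_disc, r)
    cup_soft = _soft_edge(r_cup, r)
    img = np.empty((n, n, 3))
    img[:] = _BG_COLOR
    img += disc_soft[..., None] * (_RIM_COLOR - _BG_COLOR)
    img += cup_soft[..., None] * (_CUP_COLOR - _RIM_COLOR)

    # vessel-like curvilinear structures radiating from the disc
    if spec.vessel_count > 0:
        vmask = np.zeros((n, n), dtype=bool)
        t = np.linspace(0.02, 1.0, 400)
        for _ in range(spec.vessel_count):
            a0 = rng.uniform(0, 2 * np.pi)
            wobble = rng.uniform(0.15, 0.45)
            freq = rng.uniform(1.0, 3.0)
            phase = rng.uniform(0, 2 * np.pi)
            rad = t * (0.75 * n / 2)
            ang = a0 + wobble * np.sin(2 * np.pi * freq * t + phase)
            px = np.clip(np.round(cx + rad * np.cos(ang)).astype(int), 0, n - 1)
            py = np.clip(np.round(cy - rad * np.sin(ang)).astype(int), 0, n - 1)
            vmask[py, px] = True
        vmask = dilation(vmask, disk(max(1, n // 224)))
        vessel_soft = gaussian_filter(vmask.astype(float), 1.0)
        img *= (1.0 - 0.55 * vessel_soft[..., None] * np.array([0.35, 0.8, 0.9]))

    # low-frequency illumination field + pixel noise
    field = gaussian_filter(rng.standard_normal((n, n)), sigma=n / 8.0)
    span = np.ptp(field)
    if span > 0:
        field = (field - field.mean()) / span * 0.08
    img += field[..., None]
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    if spec.frame_size is not None:
        fw, fh = spec.frame_size
        if fw < n or fh < n:
            raise ValueError("frame_size must be at least image_size in both dimensions")
        frame = np.zeros((fh, fw, 3))
        frame[:] = _BG_COLOR * 0.55
        ox, oy = int(0.30 * fw) - n // 2, fh // 2 - n // 2
        ox, oy = max(ox, 0), max(oy, 0)
        frame[oy:oy + n, ox:ox + n] = img
        dm = np.zeros((fh, fw), dtype=np.uint8)
        cm = np.zeros((fh, fw), dtype=np.uint8)
        dm[oy:oy + n, ox:ox + n] = disc_mask
        cm[oy:oy + n, ox:ox + n] = cup_mask
        img, disc_mask, cup_mask = frame, dm, cm

    if spec.eye_side == "OS":
        img = img[:, ::-1].copy()
        disc_mask = disc_mask[:, ::-1].copy()
        cup_mask = cup_mask[:, ::-1].copy()

    image = FundusImage(np.round(img * 255).astype(np.uint8), spec.eye_side)
    return image, disc_mask, cup_mask


def rim_thickness_by_ray(
    disc_mask: np.ndarray,
    cup_mask: np.ndarray,
    angle_deg: float,
    center: Optional[Tuple[float, float]] = None,
    step: float = 0.25,
) -> float:
    """Neuroretinal rim thickness along one ray, measured on the masks.

    The ray leaves ``center`` (default: disc-mask centroid) at
    ``angle_deg`` counterclockwise in display convention from +x, and
    the thickness is the distance between the outermost cup pixel and
    the outermost disc pixel along it.
    """
    disc = np.asarray(disc_mask) > 0
    cup = np.asarray(cup_mask) > 0
    h, w = disc.shape
    if center is None:
        ys, xs = np.nonzero(disc)
        center = (xs.mean(), ys.mean())
    t = np.deg2rad(angle_deg)
    r = np.arange(0.0, max(h, w), step)
    x = np.clip(np.round(center[0] + r * np.cos(t)).astype(int), 0, w - 1)
    y = np.clip(np.round(center[1] - r * np.sin(t)).astype(int), 0, h - 1)
    on_disc = disc[y, x]
    on_cup = cup[y, x]
    if not on_disc.any():
        return 0.0
    disc_extent = r[np.nonzero(on_disc)[0].max()]
    cup_extent = r[np.nonzero(on_cup)[0].max()] if on_cup.any() else 0.0
    return float(disc_extent - cup_extent)


MANIFEST_COLUMNS = ["path", "label", "eye_side", "agreement", "split"]


def _split_counts(n: int, fractions: Tuple[float, float, float]) -> Tuple[int, int, int]:
    """Largest-remainder apportionment of n rows over train/val/test."""
    raw = np.array(fractions, dtype=float) * n / sum(fractions)
    base = np.floor(raw).astype(int)
    rem = raw - base
    for i in np.argsort(-rem)[: n - base.sum()]:
        base[i] += 1
    return tuple(int(x) for x in base)


def generate_cohort(
    n_per_class: Mapping[str, int],
    agreement: str = "3/3",
    seed: int = 0,
    out_dir: Optional[Path] = None,
    image_size: int = 448,
    split_fractions: Tuple[float, float, float] = (0.77, 0.19, 0.04),
    write_images: bool = True,
    **spec_overrides,
) -> pd.DataFrame:
    """Generate a labelled cohort and its manifest.

    Each sample gets a per-sample seed derived from ``seed``, a random
    eye side, and mild jitter of CDR and disc radius around the class
    preset.  Splits are stratified per class by largest-remainder
    apportionment of ``split_fractions``.  When ``write_images`` is
    true, images and 0/255 masks are written as PNG under ``out_dir``.
    """
    if agreement not in AGREEMENT_TIERS:
        raise ValueError(f"agreement must be one of {AGREEMENT_TIERS}")
    if any(v < 0 for v in n_per_class.values()):
        raise ValueError("class counts must be >= 0")
    total = sum(n_per_class.values())
    if total == 0:
        logger.warning("generate_cohort called with zero total samples; empty manifest")
        return pd.DataFrame(columns=MANIFEST_COLUMNS + ["disc_mask", "cup_mask"])
    if write_images and out_dir is None:
        raise ValueError("out_dir is required when write_images is true")

    ss = np.random.SeedSequence(seed)
    child_seeds = (ss.generate_state(total + 1)[1:] % (2 ** 31)).tolist()
    rng = np.random.default_rng(ss)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    idx = 0
    for label in LABELS:
        count = int(n_per_class.get(label, 0))
        n_train, n_val, n_test = _split_counts(count, split_fractions)
        splits = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
        for k in range(count):
            sample_seed = child_seeds[idx]
            srng = np.random.default_rng(sample_seed)
            preset = CLASS_PRESETS[label]
            spec = spec_for_label(
                label,
                seed=sample_seed,
                eye_side="OD" if srng.random() < 0.5 else "OS",
                image_size=image_size,
                disc_radius=image_size / 4.48 * srng.uniform(0.9, 1.1),
                cup_to_disc_ratio=float(np.clip(
                    preset["cup_to_disc_ratio"] + srng.normal(0, 0.03), 0.05, 0.92)),
                vessel_count=int(srng.integers(3, 7)),
                **spec_overrides,
            )
            stem = f"{label}_{idx:04d}"
            row = {
                "path": str(out_dir / f"{stem}.png") if out_dir else f"{stem}.png",
                "label": label,
                "eye_side": spec.eye_side,
                "agreement": agreement,
                "split": splits[k],
                "disc_mask": str(out_dir / f"{stem}_disc.png") if out_dir else f"{stem}_disc.png",
                "cup_mask": str(out_dir / f"{stem}_cup.png") if out_dir else f"{stem}_cup.png",
            }
            if write_images:
                image, disc_mask, cup_mask = generate_fundus(spec)
                Image.fromarray(image.as_uint8()).save(row["path"])
                Image.fromarray(disc_mask).save(row["disc_mask"])
                Image.fromarray(cup_mask).save(row["cup_mask"])
            rows.append(row)
            idx += 1
    return pd.DataFrame(rows)
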