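"""Pie-slice quadrant-exclusion augmentation.

Each ISNT quadrant (inferior, superior, nasal, temporal) occupies a 90
degree angular sector of the optic nerve head.  In the polar raster a
sector is a band of columns, so excluding a quadrant means blanking a
column band -- a pie-shaped cut once warped back to Cartesian space.
Because the angular sweep starts and ends at the nasal direction, the
nasal quadrant is split across the seam: [0, 45) + [315, 360) degrees.

Augmentation policies map (agreement tier, class) to the set of regions
to exclude.  The shipped defaults encode the region-ablation outcome for
each tier: for unanimous-agreement (3/3) data exclude the superior
region for every class and additionally the nasal region for glaucoma
suspects; for majority-agreement (2/3) data exclude the superior and
temporal regions for every class.  Both are plain data and can be
overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .images import PolarImage

logger = logging.getLogger(__name__)

REGION_NAMES = ("inferior", "superior", "nasal", "temporal")


@dataclass(frozen=True)
class ISNTRegion:
    """A named 90-degree quadrant as degree intervals within [0, 360)."""

    name: str
    angular_interval: Tuple[Tuple[float, float], ...]

    def total_degrees(self) -> float:
        return sum(b - a for a, b in self.angular_interval)


def isnt_regions(
    ccw_order: Sequence[str] = ("superior", "temporal", "inferior"),
) -> Dict[str, ISNTRegion]:
    """The four quadrants, given the order met sweeping counterclockwise
    from nasal.

    The nasal quadrant always straddles the seam ([0, 45) + [315, 360)).
    ``ccw_order`` names the three quadrants at 90, 180 and 270 degrees;
    the default places superior at the top of an upright OD-oriented
    image with nasal on the right.
    """
    if sorted(ccw_order) != sorted(set(REGION_NAMES) - {"nasal"}):
        raise ValueError(f"ccw_order must permute {set(REGION_NAMES) - {'nasal'}}")
    regions = {"nasal": ISNTRegion("nasal", ((0.0, 45.0), (315.0, 360.0)))}
    for i, name in enumerate(ccw_order):
        lo = 45.0 + 90.0 * i
        regions[name] = ISNTRegion(name, ((lo, lo + 90.0),))
    return regions


DEFAULT_REGIONS = isnt_regions()


def region_columns(region: ISNTRegion, R_w: int) -> Set[int]:
    """Polar columns whose angular span intersects the region.

    Column j spans [j, j+1) * 360 / R_w degrees.  Intersection is tested
    in exact integer arithmetic so that when R_w is divisible by 8 the
    four quadrants partition the columns with no overlap.
    """
    if R_w < 4:
        raise ValueError("R_w must be at least 4")
    cols: Set[int] = set()
    for a, b in region.angular_interval:
        # column span [j*360, (j+1)*360), interval [a*R_w, b*R_w), both
        # in units of (1/R_w) degrees; a, b are integral degrees here
        a_s, b_s = a * R_w, b * R_w
        for j in range(R_w):
            if j * 360 < b_s and (j + 1) * 360 > a_s:
                cols.add(j)
    return cols


def apply_pie_crop(polar: PolarImage, region: ISNTRegion, fill: float = 0.0) -> PolarImage:
    """Blank the region's column band; all other pixels are unchanged."""
    out = polar.copy()
    cols = sorted(region_columns(region, polar.R_w))
    out.pixels[:, cols] = fill
    out.excluded_region = region.name
    return out


@dataclass
class AugmentPolicy:
    """Mapping (agreement tier, class label) -> region names to exclude."""

    rules: Dict[Tuple[str, str], Tuple[str, ...]]
    regions: Dict[str, ISNTRegion] = field(default_factory=lambda: dict(DEFAULT_REGIONS))

    def __post_init__(self) -> None:
        for key, names in self.rules.items():
            for name in names:
                if name not in self.regions:
                    raise ValueError(f"rule {key} references undefined region {name!r}")

    def regions_for(self, agreement: str, label: str) -> Optional[Tuple[str, ...]]:
        return self.rules.get((agreement, label))


def default_policy_33() -> AugmentPolicy:
    """3/3 tier: superior for all classes, nasal additionally for suspects."""
    return AugmentPolicy({
        ("3/3", "G"): ("superior",),
        ("3/3", "S"): ("superior", "nasal"),
        ("3/3", "N"): ("superior",),
    })


def default_policy_23() -> AugmentPolicy:
    """2/3 tier: superior and temporal for all classes."""
    return AugmentPolicy({
        ("2/3", "G"): ("superior", "temporal"),
        ("2/3", "S"): ("superior", "temporal"),
        ("2/3", "N"): ("superior", "temporal"),
    })


def build_augmented_set(manifest: pd.DataFrame, policy: AugmentPolicy) -> pd.DataFrame:
    """One unmodified row per input row, plus one row per excluded region.

    Only training-split rows are augmented.  Augmented rows carry
    ``excluded_region`` and ``source`` provenance columns; rows whose
    (agreement, class) pair is absent from the policy pass through
    unaugmented (logged).
    """
    rows: List[dict] = []
    for _, row in manifest.iterrows():
        base = row.to_dict()
        base.setdefault("excluded_region", "")
        base.setdefault("source", "")
        rows.append(base)
        if base.get("split") != "train":
            continue
        names = policy.regions_for(base["agreement"], base["label"])
        if names is None:
            logger.info(
                "no augmentation rule for (agreement=%s, label=%s); row passes through",
                base["agreement"], base["label"],
            )
            continue
        for name in names:
            aug = dict(base)
            aug["excluded_region"] = name
            aug["source"] = base["path"]
            rows.append(aug)
    return pd.DataFrame(rows).reset_index(drop=True)


def evaluate_region_ablation(
    train_fn: Callable[[pd.DataFrame, Optional[ISNTRegion]], Dict[str, Dict[str, float]]],
    manifest: pd.DataFrame,
    regions: Iterable[ISNTRegion],
) -> pd.DataFrame:
    """Train one model per excluded region and tabulate deltas vs baseline.

    ``train_fn(manifest, region_or_None)`` must return per-class metric
    dictionaries, e.g. ``{"G": {"f1": ...}, ...}``.  The result has one
    row per (region, class) carrying the metrics and their differences
    against the no-exclusion baseline.
    """
    try:
        baseline = train_fn(manifest, None)
    except Exception as exc:  # noqa: BLE001 - annotate with context
        raise RuntimeError("baseline training failed") from exc
    rows: List[dict] = []
    for cls, mets in baseline.items():
        rows.append({"region": "baseline", "class": cls, **mets,
                     **{f"delta_{k}": 0.0 for k in mets}})
    for region in regions:
        try:
            result = train_fn(manifest, region)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"training failed for region {region.name!r}") from exc
        for cls, mets in result.items():
            base = baseline.get(cls, {})
            rows.append({
                "region": region.name, "class": cls, **mets,
                **{f"delta_{k}": v - base[k] for k, v in mets.items() if k in base},
            })
    return pd.DataFrame(rows)
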