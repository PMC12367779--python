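"""Leaf phenotypic trait extraction from rotated detection boxes.

Given a detected box in its eight-parameter (four-vertex) form with the
canonical ordering of :func:`rotphenex.rotgeom.to_quad` — the edge from the
second to the third vertex spans the long side — the traits are pure
functions of consecutive vertex pairs:

* inclination  ``theta = arctan(|y2 - y3| / |x2 - x3|)``  (degrees, [0, 90]);
* leaf length  ``h = |v2 - v3|``;
* leaf width   ``w = |v3 - v4|``;
* aspect ratio ``h / w``;
* leaf area    ``S = h * w``.

Per-plant summaries add the leaf count (the number of retained detections)
and simple aggregates.  Traits are computed in pixels and optionally scaled
to millimeters through a user-supplied calibration; the absolute-value
arctangent makes the inclination blind to left/right lean, so the signed box
angle is kept alongside it for users who need direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import DegenerateGeometryError, InvalidArgumentError, UndefinedMetricError
from .metrics import r_squared
from .rotgeom import QuadBox, RotatedBox, rotated_nms, to_quad

__all__ = [
    "LeafTraits",
    "PlantSummary",
    "ScaleCalibration",
    "quad_traits",
    "count_leaves",
    "extract_plant",
    "agreement_report",
]

TRAIT_COLUMNS = ("inclination_deg", "length", "width", "aspect", "area")


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-metric scale; lengths multiply by ``mm_per_px``, areas by its square."""

    mm_per_px: float
    source: str = "config"

    def __post_init__(self) -> None:
        if not self.mm_per_px > 0:
            raise InvalidArgumentError("mm_per_px must be > 0")


@dataclass(frozen=True)
class LeafTraits:
    inclination_deg: float
    length: float
    width: float
    aspect: float
    area: float
    confidence: float = 1.0
    signed_theta_deg: float = 0.0
    units: str = "px"

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise InvalidArgumentError("need length >= width > 0")
        if not (0.0 <= self.inclination_deg <= 90.0):
            raise InvalidArgumentError("inclination must lie in [0, 90]")


@dataclass
class PlantSummary:
    leaf_count: int
    leaves: list = field(default_factory=list)

    @property
    def mean_length(self) -> float:
        return sum(l.length for l in self.leaves) / len(self.leaves) if self.leaves else 0.0

    @property
    def max_length(self) -> float:
        return max((l.length for l in self.leaves), default=0.0)

    @property
    def total_area(self) -> float:
        return sum(l.area for l in self.leaves)


def quad_traits(
    quad: QuadBox,
    scale: Optional[ScaleCalibration] = None,
    confidence: float = 1.0,
) -> LeafTraits:
    """Compute the trait record of one leaf from its canonical quad."""
    (x1, y1), (x2, y2), (x3, y3), (x4, y4) = quad.vertices
    dx, dy = x2 - x3, y2 - y3
    h = math.hypot(dx, dy)
    w = math.hypot(x4 - x3, y4 - y3)
    if h <= 0 or w <= 0:
        raise DegenerateGeometryError("quad has a zero-length side")
    inclination = 90.0 if dx == 0 else math.degrees(math.atan(abs(dy) / abs(dx)))
    signed = math.degrees(math.atan2(-dy, dx))
    if signed >= 90.0:
        signed -= 180.0
    elif signed < -90.0:
        signed += 180.0
    if h < w:  # tolerate non-canonical vertex starts
        h, w = w, h
    k = scale.mm_per_px if scale else 1.0
    return LeafTraits(
        inclination_deg=inclination,
        length=h * k,
        width=w * k,
        aspect=h / w,
        area=h * k * w * k,
        confidence=confidence,
        signed_theta_deg=signed,
        units="mm" if scale else "px",
    )


def count_leaves(detections: Sequence[tuple], conf_threshold: float = 0.25) -> int:
    """Number of detections at or above the confidence threshold."""
    return sum(1 for _, score in detections if score >= conf_threshold)


def extract_plant(
    detections: Sequence[tuple],
    scale: Optional[ScaleCalibration] = None,
    conf_threshold: float = 0.25,
    nms_iou: float = 0.45,
    image_name: str = "",
    with_plant_height: bool = False,
) -> tuple[PlantSummary, pd.DataFrame]:
    """Detections of one image -> per-leaf trait table and plant summary.

    Applies rotated NMS, drops detections below the confidence threshold,
    and emits one row per retained leaf: image name, leaf id, confidence,
    the 8 vertex coordinates and the 5 traits.  ``with_plant_height`` adds a
    ``plant_height_derived`` column — the vertical pixel extent over all leaf
    quads, a derived quantity with no counterpart in the trait formula table.
    """
    retained = [
        detections[i]
        for i in rotated_nms(list(detections), iou_threshold=nms_iou)
        if detections[i][1] >= conf_threshold
    ]
    rows = []
    leaves = []
    all_ys: list[float] = []
    for leaf_id, (box, score) in enumerate(retained):
        quad = to_quad(box)
        tr = quad_traits(quad, scale=scale, confidence=score)
        leaves.append(tr)
        row = {"image": image_name, "leaf_id": leaf_id, "confidence": score}
        for vi, (x, y) in enumerate(quad.vertices, start=1):
            row[f"x{vi}"], row[f"y{vi}"] = x, y
            all_ys.append(y)
        for col in TRAIT_COLUMNS:
            row[col] = getattr(tr, col)
        row["signed_theta_deg"] = tr.signed_theta_deg
        row["units"] = tr.units
        rows.append(row)
    table = pd.DataFrame(rows)
    if with_plant_height and rows:
        k = scale.mm_per_px if scale else 1.0
        table["plant_height_derived"] = (max(all_ys) - min(all_ys)) * k
    return PlantSummary(leaf_count=len(retained), leaves=leaves), table


def agreement_report(
    extracted: pd.DataFrame, measured: pd.DataFrame
) -> pd.DataFrame:
    """Per-trait R^2 of extracted vs measured values.

    Both frames must share the trait columns and row order (one row per
    leaf).  Returns a frame indexed by trait with columns ``r2`` and ``n``,
    plus the paired values for scatter plotting stored in ``.attrs``.
    """
    common = [c for c in TRAIT_COLUMNS if c in extracted and c in measured]
    if not common:
        raise UndefinedMetricError("no shared trait columns")
    if len(extracted) != len(measured):
        raise InvalidArgumentError(
            f"length mismatch: {len(extracted)} extracted vs {len(measured)} measured"
        )
    rows = {}
    scatter = {}
    for col in common:
        est = extracted[col].to_numpy(dtype=float)
        tru = measured[col].to_numpy(dtype=float)
        rows[col] = {"r2": r_squared(est, tru), "n": len(est)}
        scatter[col] = (tru, est)
    report = pd.DataFrame(rows).T
    report.attrs["scatter"] = scatter
    return report
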