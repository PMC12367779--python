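"""Exact geometry of rotated (oriented) bounding boxes.

The central object is the five-parameter *long-side* box ``(cx, cy, w, h, theta)``:
``h`` is the long side, ``w`` the short side, and ``theta`` the rotation of the
long side in degrees, measured counterclockwise *on screen* (image coordinates:
origin top-left, x right, y down), normalized to the half-open interval
``[-90, 90)``.  The equivalent eight-parameter form is the :class:`QuadBox` —
the four vertices in a canonical order in which the edge ``v2 -> v3`` spans the
long side, so downstream trait formulas can read length and width directly off
consecutive vertex pairs.

All operations here are pure NumPy; polygon intersection uses Sutherland–Hodgman
clipping with the shoelace formula, which is exact for convex quadrilaterals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateGeometryError, InvalidArgumentError

__all__ = [
    "RotatedBox",
    "QuadBox",
    "wrap_angle",
    "to_quad",
    "from_quad",
    "intersection_area",
    "rotated_iou",
    "rotated_nms",
]


def wrap_angle(theta_deg: float) -> float:
    """Normalize an angle (degrees) to the half-open interval [-90, 90).

    Rotated rectangles are invariant under a 180-degree turn of their long
    side, so angles are identified modulo 180 and a unique representative is
    chosen in [-90, 90).
    """
    if not np.all(np.isfinite(theta_deg)):
        raise InvalidArgumentError(f"angle must be finite, got {theta_deg!r}")
    wrapped = (np.asarray(theta_deg, dtype=float) + 90.0) % 180.0 - 90.0
    if np.ndim(theta_deg) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class RotatedBox:
    """Five-parameter long-side rotated box.

    Parameters are canonicalized on construction: if ``h < w`` the two sides
    are swapped and the angle is shifted by 90 degrees, and the angle is
    wrapped to [-90, 90).  Square boxes (``h == w``) are angle-ambiguous
    modulo 90; their angle is canonicalized to [-45, 45).
    """

    cx: float
    cy: float
    w: float
    h: float
    theta: float

    def __post_init__(self) -> None:
        cx, cy, w, h, theta = (
            float(self.cx),
            float(self.cy),
            float(self.w),
            float(self.h),
            float(self.theta),
        )
        if not all(math.isfinite(v) for v in (cx, cy, w, h, theta)):
            raise InvalidArgumentError("box parameters must be finite")
        if w <= 0 or h <= 0:
            raise InvalidArgumentError(f"box sides must be positive, got w={w}, h={h}")
        if h < w:
            w, h = h, w
            theta = theta + 90.0
        theta = wrap_angle(theta)
        if h == w:
            # square: angle identifiable only mod 90
            theta = (theta + 45.0) % 90.0 - 45.0
        object.__setattr__(self, "cx", cx)
        object.__setattr__(self, "cy", cy)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "theta", theta)

    @property
    def area(self) -> float:
        return self.w * self.h

    def translated(self, dx: float, dy: float) -> "RotatedBox":
        return RotatedBox(self.cx + dx, self.cy + dy, self.w, self.h, self.theta)


@dataclass(frozen=True)
class QuadBox:
    """Eight-parameter form: four (x, y) vertices in consecutive order.

    For quads produced by :func:`to_quad` the order is canonical: screen-
    counterclockwise with ``v2 -> v3`` a long side and ``v3 -> v4`` a short
    side.
    """

    vertices: tuple = field()

    def __init__(self, vertices: Iterable[Sequence[float]]):
        verts = tuple((float(x), float(y)) for x, y in vertices)
        if len(verts) != 4:
            raise InvalidArgumentError(f"a quad needs 4 vertices, got {len(verts)}")
        object.__setattr__(self, "vertices", verts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)

    @property
    def area(self) -> float:
        return abs(_signed_area(self.as_array()))


def _signed_area(pts: np.ndarray) -> float:
    """Shoelace signed area (math convention; negative = screen-CCW)."""
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _axes(theta_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors of the box frame in image coordinates (y down).

    Returns ``(s, u)`` where ``u`` is the long-side direction at screen-CCW
    angle ``theta`` from +x and ``s`` the short-side direction.
    """
    t = math.radians(theta_deg)
    u = np.array([math.cos(t), -math.sin(t)])
    s = np.array([math.sin(t), math.cos(t)])
    return s, u


def to_quad(box: RotatedBox) -> QuadBox:
    """Convert a five-parameter box to its canonical four-vertex form."""
    s, u = _axes(box.theta)
    c = np.array([box.cx, box.cy])
    hw, hh = box.w / 2.0, box.h / 2.0
    # box-frame corners (short-axis coord, long-axis coord), consecutive
    # screen-CCW starting at (-w/2, -h/2)
    local = [(-hw, -hh), (hw, -hh), (hw, hh), (-hw, hh)]
    verts = [c + xi * s + eta * u for xi, eta in local]
    return QuadBox(verts)


def _min_area_rect(points: np.ndarray) -> RotatedBox:
    """Minimum-area enclosing rotated rectangle of a small convex point set.

    Rotating-calipers over hull edge directions; used as the fallback for
    nearly-degenerate quads and by the synthetic-data recovery oracle.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 points")
    try:
        from scipy.spatial import ConvexHull

        hull = pts[ConvexHull(pts).vertices]
    except Exception as exc:  # collinear input
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    best = None
    for i in range(len(hull)):
        edge = hull[(i + 1) % len(hull)] - hull[i]
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        u = edge / norm
        v = np.array([-u[1], u[0]])
        pu = hull @ u
        pv = hull @ v
        du, dv = pu.max() - pu.min(), pv.max() - pv.min()
        area = du * dv
        if best is None or area < best[0]:
            center = (pu.max() + pu.min()) / 2.0 * u + (pv.max() + pv.min()) / 2.0 * v
            # screen-CCW angle of the long direction
            long_dir = u if du >= dv else v
            theta = math.degrees(math.atan2(-long_dir[1], long_dir[0]))
            w, h = (dv, du) if du >= dv else (du, dv)
            best = (area, center, w, h, theta)
    if best is None or best[0] <= 0:
        raise DegenerateGeometryError("zero-area point set")
    _, center, w, h, theta = best
    if w <= 0:
        raise DegenerateGeometryError("degenerate (collinear) quad")
    return RotatedBox(center[0], center[1], w, h, theta)


def from_quad(quad: QuadBox, rect_tol: float = 1e-3) -> RotatedBox:
    """Recover the five-parameter box from four vertices.

    For a (near-)rectangle in any cyclic order the sides are measured
    directly; if the vertices deviate from a rectangle by more than
    ``rect_tol`` (relative side/diagonal mismatch) the minimum-area enclosing
    rotated rectangle is fitted instead.
    """
    pts = quad.as_array()
    if abs(_signed_area(pts)) <= 0.0:
        raise DegenerateGeometryError("quad has zero area")
    center = pts.mean(axis=0)
    e1 = pts[1] - pts[0]
    e2 = pts[2] - pts[1]
    l1, l2 = np.hypot(*e1), np.hypot(*e2)
    d1 = np.hypot(*(pts[2] - pts[0]))
    d2 = np.hypot(*(pts[3] - pts[1]))
    scale = max(l1, l2)
    if scale <= 0:
        raise DegenerateGeometryError("degenerate quad side")
    # rectangle check: opposite sides equal and diagonals equal
    l3 = np.hypot(*(pts[3] - pts[2]))
    l4 = np.hypot(*(pts[0] - pts[3]))
    if (
        abs(l1 - l3) > rect_tol * scale
        or abs(l2 - l4) > rect_tol * scale
        or abs(d1 - d2) > rect_tol * scale
    ):
        return _min_area_rect(pts)
    if l1 >= l2:
        long_edge, w, h = e1, l2, l1
    else:
        long_edge, w, h = e2, l1, l2
    theta = math.degrees(math.atan2(-long_edge[1], long_edge[0]))
    return RotatedBox(center[0], center[1], w, h, theta)


def _clip_polygon(subject: np.ndarray, clip: np.ndarray) -> np.ndarray:
    """Sutherland–Hodgman: clip convex polygon ``subject`` by convex ``clip``."""
    # orient the clip polygon consistently (math-CCW) so "inside" is one-sided
    if _signed_area(clip) < 0:
        clip = clip[::-1]
    output = subject
    n = len(clip)
    for i in range(n):
        if len(output) == 0:
            break
        a, b = clip[i], clip[(i + 1) % n]
        edge = b - a
        # cross > 0 => point left of edge (inside for CCW clip polygon)
        rel = output - a
        d = edge[0] * rel[:, 1] - edge[1] * rel[:, 0]
        result = []
        m = len(output)
        for j in range(m):
            cur, nxt = output[j], output[(j + 1) % m]
            dc, dn = d[j], d[(j + 1) % m]
            if dc >= 0:
                result.append(cur)
            if (dc > 0) != (dn > 0) and dc != dn:
                t = dc / (dc - dn)
                result.append(cur + t * (nxt - cur))
        output = np.asarray(result) if result else np.empty((0, 2))
    return output


def intersection_area(a: QuadBox, b: QuadBox) -> float:
    """Area of the convex intersection of two convex quads, in px^2."""
    poly = _clip_polygon(a.as_array(), b.as_array())
    if len(poly) < 3:
        return 0.0
    return abs(_signed_area(poly))


def rotated_iou(a: RotatedBox, b: RotatedBox) -> float:
    """Intersection-over-union of two rotated boxes."""
    area_a, area_b = a.area, b.area
    if area_a <= 0 and area_b <= 0:
        raise InvalidArgumentError("both boxes have zero area")
    inter = intersection_area(to_quad(a), to_quad(b))
    union = area_a + area_b - inter
    if union <= 0:
        return 0.0
    return min(1.0, inter / union)


def rotated_nms(
    detections: Sequence[tuple],
    iou_threshold: float = 0.45,
) -> list[int]:
    """Greedy non-maximum suppression on scored rotated boxes.

    ``detections`` is a sequence of ``(RotatedBox, score)``; returns the
    indices (into the input) of the kept detections, in descending score
    order.  A detection is suppressed if its rotated IoU with an
    already-kept detection exceeds ``iou_threshold``.
    """
    if not detections:
        return []
    order = sorted(range(len(detections)), key=lambda i: -detections[i][1])
    kept: list[int] = []
    for i in order:
        box_i = detections[i][0]
        if all(rotated_iou(box_i, detections[j][0]) <= iou_threshold for j in kept):
            kept.append(i)
    return kept
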