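"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: polygon
areas come from shapely, rasterized IoU from dense point-in-polygon grids,
and minimum-area rectangles from shapely's oriented envelope.
"""

from __future__ import annotations

import numpy as np
import pytest
import shapely

from rotphenex.rotgeom import RotatedBox


def random_box(rng, canvas=640.0, w_range=(4.0, 30.0), h_factor=(1.5, 8.0)):
    w = rng.uniform(*w_range)
    h = w * rng.uniform(*h_factor)
    return RotatedBox(
        rng.uniform(0.1 * canvas, 0.9 * canvas),
        rng.uniform(0.1 * canvas, 0.9 * canvas),
        w,
        h,
        rng.uniform(-90.0, 90.0),
    )


def shapely_poly(box: RotatedBox):
    from rotphenex.rotgeom import to_quad

    return shapely.Polygon(to_quad(box).vertices)


def raster_iou(a: RotatedBox, b: RotatedBox, n: int = 1000) -> float:
    """IoU via dense rasterization of the intersection membership.

    Box areas are exact (w*h); only the intersection is sampled, on an
    n-by-n sub-pixel grid over the overlap of the two axis-aligned extents,
    so the quantization error stays well below 1e-3 of the IoU.
    """
    from rotphenex.rotgeom import to_quad

    qa = np.asarray(to_quad(a).vertices)
    qb = np.asarray(to_quad(b).vertices)
    lo = np.maximum(qa.min(axis=0), qb.min(axis=0))
    hi = np.minimum(qa.max(axis=0), qb.max(axis=0))
    union = a.area + b.area
    if np.any(hi <= lo):
        return 0.0
    dx = (hi[0] - lo[0]) / n
    dy = (hi[1] - lo[1]) / n
    xs = lo[0] + (np.arange(n) + 0.5) * dx
    ys = lo[1] + (np.arange(n) + 0.5) * dy
    cell = dx * dy
    X, Y = np.meshgrid(xs, ys)
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)

    def inside(quad):
        ok = np.ones(len(pts), dtype=bool)
        m = len(quad)
        # orientation from the exact shoelace sign decides the inside side
        shoelace = sum(
            quad[i][0] * quad[(i + 1) % m][1] - quad[(i + 1) % m][0] * quad[i][1]
            for i in range(m)
        )
        sign = 1.0 if shoelace > 0 else -1.0
        for i in range(m):
            e = quad[(i + 1) % m] - quad[i]
            rel = pts - quad[i]
            d = e[0] * rel[:, 1] - e[1] * rel[:, 0]
            ok &= sign * d >= 0
        return ok

    inter = float(np.count_nonzero(inside(qa) & inside(qb))) * cell
    return inter / (union - inter) if union > inter else 1.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
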