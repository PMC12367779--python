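"""Joint image + rotated-label augmentation.

Every transform moves the annotation boxes by the *same* rigid map applied to
the pixels: centers are mapped by the transform and the box angle is updated
analytically (a screen-counterclockwise image rotation by ``a`` degrees adds
``a`` to the box angle; a flip negates it).  Side lengths are never rescaled,
so box areas are preserved exactly.

The default expansion recipe is one variant per rotation in
{45, 90, 135, 180} degrees plus the original, i.e. a 5x expansion: 244 source
images become 1220.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .annotations import Annotation, ImageRecord
from .errors import InvalidArgumentError
from .rotgeom import RotatedBox, wrap_angle

logger = logging.getLogger(__name__)

__all__ = [
    "AugmentSpec",
    "rotate_record",
    "flip_record",
    "adjust_brightness",
    "denoise",
    "random_crop",
    "expand_dataset",
]


@dataclass
class AugmentSpec:
    """Configuration of the dataset-expansion recipe."""

    rotations: tuple = (45.0, 90.0, 135.0, 180.0)
    flip_horizontal: bool = False
    flip_vertical: bool = False
    brightness_range: tuple[float, float] | None = None
    denoise: bool = False
    crop: tuple[int, int] | None = None  # (size, count)
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(np.isfinite(a) for a in self.rotations):
            raise InvalidArgumentError("rotation angles must be finite")
        if self.brightness_range is not None and min(self.brightness_range) <= 0:
            raise InvalidArgumentError("brightness factors must be > 0")


def _map_annotations(
    record: ImageRecord,
    new_size: tuple[int, int],
    point_map,
    dtheta: float,
    negate: bool = False,
) -> list[Annotation]:
    out = []
    new_w, new_h = new_size
    for ann in record.annotations:
        b = ann.box
        cx, cy = point_map(b.cx, b.cy)
        theta = wrap_angle((-b.theta if negate else b.theta) + dtheta)
        if not (0 <= cx < new_w and 0 <= cy < new_h):
            logger.info("dropping box centered (%.1f, %.1f): outside canvas", cx, cy)
            continue
        out.append(replace(ann, box=RotatedBox(cx, cy, b.w, b.h, theta)))
    return out


def rotate_record(record: ImageRecord, angle_deg: float) -> ImageRecord:
    """Rotate image and labels screen-counterclockwise about the image center.

    Multiples of 90 degrees are exact (``np.rot90``); other angles expand the
    canvas to contain the rotated image, padding with black.  Boxes whose
    mapped center leaves the canvas are dropped (logged).
    """
    img = record.load_image()
    H, W = img.shape[:2]
    a = angle_deg % 360.0
    t = math.radians(a)
    cos_a, sin_a = math.cos(t), math.sin(t)

    if a % 90.0 == 0:
        k = int(a // 90) % 4
        # np.rot90 with k=1 maps img[0, W-1] to out[0, 0]: top-right to
        # top-left, i.e. screen-counterclockwise, matching point_map below
        new_img = np.ascontiguousarray(np.rot90(img, k=k))
        new_W, new_H = (W, H) if k % 2 == 0 else (H, W)
    else:
        new_W = math.ceil(W * abs(cos_a) + H * abs(sin_a))
        new_H = math.ceil(W * abs(sin_a) + H * abs(cos_a))
        # inverse map for affine_transform: output pixel -> input pixel,
        # rotation screen-CW by a about the canvas centers (rows, cols)
        c_in = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
        c_out = np.array([(new_H - 1) / 2.0, (new_W - 1) / 2.0])
        # screen-CCW rotation by a maps input (x, y) with x right/y down;
        # in (row, col) = (y, x) order the forward matrix is:
        fwd = np.array([[cos_a, -sin_a], [sin_a, cos_a]])
        inv = fwd.T
        offset = c_in - inv @ c_out
        channels = [
            ndimage.affine_transform(
                img[..., ch].astype(float), inv, offset=offset,
                output_shape=(new_H, new_W), order=1, cval=0.0,
            )
            for ch in range(img.shape[2])
        ]
        new_img = np.clip(np.stack(channels, axis=-1), 0, 255).astype(img.dtype)

    def point_map(x: float, y: float) -> tuple[float, float]:
        dx, dy = x - (W - 1) / 2.0, y - (H - 1) / 2.0
        # screen-CCW by a in y-down coordinates
        nx = dx * cos_a + dy * sin_a
        ny = -dx * sin_a + dy * cos_a
        return nx + (new_W - 1) / 2.0, ny + (new_H - 1) / 2.0

    anns = _map_annotations(record, (new_W, new_H), point_map, dtheta=a)
    return ImageRecord(record.image_path, new_W, new_H, anns, image=new_img)


def flip_record(record: ImageRecord, axis: str) -> ImageRecord:
    """Mirror the record horizontally (left-right) or vertically (up-down)."""
    img = record.load_image()
    H, W = img.shape[:2]
    if axis == "horizontal":
        new_img = img[:, ::-1].copy()
        point_map = lambda x, y: ((W - 1) - x, y)
    elif axis == "vertical":
        new_img = img[::-1].copy()
        point_map = lambda x, y: (x, (H - 1) - y)
    else:
        raise InvalidArgumentError(f"axis must be horizontal|vertical, got {axis!r}")
    anns = _map_annotations(record, (W, H), point_map, dtheta=0.0, negate=True)
    return ImageRecord(record.image_path, W, H, anns, image=new_img)


def adjust_brightness(record: ImageRecord, factor: float) -> ImageRecord:
    """Multiplicative brightness scaling, clipped to the uint8 range."""
    if not factor > 0:
        raise InvalidArgumentError("brightness factor must be > 0")
    img = record.load_image()
    new_img = np.clip(img.astype(float) * factor, 0, 255).astype(img.dtype)
    return replace(record, image=new_img, annotations=list(record.annotations))


def denoise(record: ImageRecord) -> ImageRecord:
    """3x3 median filter applied per channel; labels unchanged."""
    img = record.load_image()
    new_img = np.stack(
        [ndimage.median_filter(img[..., c], size=3) for c in range(img.shape[2])],
        axis=-1,
    )
    return replace(record, image=new_img, annotations=list(record.annotations))


def random_crop(record: ImageRecord, size: int, seed: int = 0) -> ImageRecord:
    """Crop a random ``size x size`` window; keep boxes whose center survives."""
    img = record.load_image()
    H, W = img.shape[:2]
    if size > min(W, H):
        raise InvalidArgumentError(f"crop size {size} exceeds canvas {W}x{H}")
    rng = np.random.default_rng(seed)
    x0 = int(rng.integers(0, W - size + 1))
    y0 = int(rng.integers(0, H - size + 1))
    new_img = img[y0 : y0 + size, x0 : x0 + size].copy()
    anns = _map_annotations(
        record, (size, size), lambda x, y: (x - x0, y - y0), dtheta=0.0
    )
    return ImageRecord(record.image_path, size, size, anns, image=new_img)


def expand_dataset(
    records: Iterable[ImageRecord], spec: AugmentSpec | None = None
) -> list[ImageRecord]:
    """Emit the original plus one variant per configured operation.

    With the default spec (rotations 45/90/135/180, nothing else) each record
    yields 5 outputs, reproducing the 244 -> 1220 expansion.
    """
    spec = spec or AugmentSpec()
    rng = np.random.default_rng(spec.seed)
    out: list[ImageRecord] = []
    for record in records:
        variants = [record]
        for angle in spec.rotations:
            variants.append(rotate_record(record, angle))
        if spec.flip_horizontal:
            variants.append(flip_record(record, "horizontal"))
        if spec.flip_vertical:
            variants.append(flip_record(record, "vertical"))
        if spec.brightness_range is not None:
            lo, hi = spec.brightness_range
            variants.append(adjust_brightness(record, float(rng.uniform(lo, hi))))
        if spec.denoise:
            variants.append(denoise(record))
        if spec.crop is not None:
            size, count = spec.crop
            for _ in range(count):
                variants.append(random_crop(record, size, seed=int(rng.integers(2**31))))
        out.extend(variants)
    return out
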