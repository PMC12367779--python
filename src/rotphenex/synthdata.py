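"""Synthetic seedling scenes with exact rotated-box ground truth.

No public wheat-seedling dataset with rotated-box labels accompanies this
problem, so this module renders the study conditions directly: dark-background
pot images containing narrow, high-aspect-ratio elongated blades at arbitrary
orientations, each with a known five-parameter box.  Leaves are drawn as
filled elongated blades (a superellipse in the box frame, tapering toward
both tips and touching all four sides of its box), green-dominant on a
near-black background, with optional Gaussian pixel noise.

Everything is deterministic under the scene seed, which makes these scenes
usable both as test fixtures and as training data for the desk-scale
overfitting experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .annotations import Annotation, ImageRecord, write_dota
from .errors import InvalidArgumentError, PlacementError
from .rotgeom import RotatedBox, rotated_iou

__all__ = ["SceneSpec", "generate_scene", "generate_dataset", "load_manifest"]

_BACKGROUND = np.array([16.0, 20.0, 14.0])  # darkroom near-black, slight green
_LEAF_COLOR = np.array([52.0, 140.0, 58.0])


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene family.

    Defaults describe the imaging conditions the package targets: a 640x640
    crop, a handful of long narrow blades (aspect ratio >= 3) at arbitrary
    orientations, mild sensor noise, and overlap permitted up to a moderate
    IoU so that occlusion between leaves occurs.
    """

    canvas: tuple[int, int] = (640, 640)  # (W, H)
    n_leaves: tuple[int, int] = (4, 12)  # inclusive range, or set both equal
    length_range: tuple[float, float] = (80.0, 240.0)
    aspect_range: tuple[float, float] = (3.0, 8.0)
    angle_range: tuple[float, float] = (-90.0, 90.0)
    overlap_allowed: bool = True
    max_overlap_iou: float = 0.4
    noise_sigma: float = 3.0
    grayscale: bool = False
    seed: int = 0
    margin: float = 0.08  # keep box centers this fraction away from the border

    def __post_init__(self) -> None:
        if self.aspect_range[0] <= 1:
            raise InvalidArgumentError("aspect ratio lower bound must be > 1")
        if self.n_leaves[0] < 0 or self.n_leaves[1] < self.n_leaves[0]:
            raise InvalidArgumentError("invalid n_leaves range")
        if min(self.length_range) <= 0:
            raise InvalidArgumentError("leaf length must be positive")


def _render_leaf(img: np.ndarray, box: RotatedBox, color: np.ndarray, rng) -> None:
    """Rasterize one blade as the superellipse |2*eta/h|^4 + |2*xi/w|^4 <= 1
    in the box frame: a convex blade that tapers toward both tips yet stays
    wide enough near them to rasterize faithfully, so the minimum rotated
    rectangle of the rendered mask recovers the stored box to about a pixel."""
    H, W = img.shape[:2]
    t = np.radians(box.theta)
    # evaluate only inside the box's axis-aligned bounding window
    half = 0.5 * np.hypot(box.h, box.w)
    x0, x1 = max(0, int(box.cx - half)), min(W, int(box.cx + half) + 2)
    y0, y1 = max(0, int(box.cy - half)), min(H, int(box.cy + half) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = xs - box.cx
    dy = ys - box.cy
    eta = dx * np.cos(t) - dy * np.sin(t)  # along the long side
    xi = dx * np.sin(t) + dy * np.cos(t)  # along the short side
    inside = (2 * eta / box.h) ** 4 + (2 * xi / box.w) ** 4 <= 1.0
    shade = 1.0 + 0.15 * (eta / (box.h / 2))  # mild base-to-tip gradient
    patch = img[y0:y1, x0:x1]
    patch[inside] = np.clip(color * shade[inside, None], 0, 255)


def _sample_box(spec: SceneSpec, rng) -> RotatedBox:
    W, H = spec.canvas
    h = float(rng.uniform(*spec.length_range))
    aspect = float(rng.uniform(*spec.aspect_range))
    w = max(2.0, h / aspect)
    theta = float(rng.uniform(*spec.angle_range))
    mx, my = spec.margin * W, spec.margin * H
    cx = float(rng.uniform(mx, W - mx))
    cy = float(rng.uniform(my, H - my))
    return RotatedBox(cx, cy, w, h, theta)


def generate_scene(spec: SceneSpec, seed: Optional[int] = None) -> tuple[np.ndarray, ImageRecord]:
    """Render one scene; returns (H x W x 3 uint8 image, ImageRecord).

    Leaves are placed sequentially; when overlap is constrained, a candidate
    whose rotated IoU with any placed box exceeds the ceiling is re-sampled
    up to 100 times before a :class:`PlacementError` is raised.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    W, H = spec.canvas
    img = np.ones((H, W, 3), dtype=float) * _BACKGROUND
    n = int(rng.integers(spec.n_leaves[0], spec.n_leaves[1] + 1))

    ceiling = spec.max_overlap_iou if spec.overlap_allowed else 0.0
    boxes: list[RotatedBox] = []
    for _ in range(n):
        for attempt in range(100):
            cand = _sample_box(spec, rng)
            if all(rotated_iou(cand, b) <= ceiling for b in boxes):
                boxes.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place leaf {len(boxes) + 1}/{n} at overlap <= {ceiling}"
            )

    for box in boxes:
        jitter = rng.uniform(0.85, 1.15, size=3)
        _render_leaf(img, box, _LEAF_COLOR * jitter, rng)

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    if spec.grayscale:
        gray = (0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2])
        img = np.repeat(gray[..., None].astype(np.uint8), 3, axis=2)

    annotations = [Annotation(b, "leaf", 0) for b in boxes]
    record = ImageRecord(None, W, H, annotations, image=img)
    return img, record


def generate_dataset(n_images: int, spec: SceneSpec, out_dir) -> dict:
    """Write ``n_images`` scenes (PNG + DOTA labels) plus a JSON manifest."""
    from PIL import Image

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    entries = []
    root = np.random.default_rng(spec.seed)
    seeds = root.integers(0, 2**31 - 1, size=n_images)
    for i in range(n_images):
        img, record = generate_scene(spec, seed=int(seeds[i]))
        name = f"scene_{i:04d}"
        img_path = out_dir / "images" / f"{name}.png"
        lbl_path = out_dir / "labels" / f"{name}.txt"
        Image.fromarray(img).save(img_path)
        record.image_path = img_path
        write_dota(record, lbl_path)
        entries.append(
            {
                "name": name,
                "image": str(img_path.relative_to(out_dir)),
                "label": str(lbl_path.relative_to(out_dir)),
                "width": record.width,
                "height": record.height,
                "n_leaves": len(record.annotations),
                "seed": int(seeds[i]),
            }
        )
    manifest = {"n_images": n_images, "canvas": list(spec.canvas), "entries": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_manifest(out_dir) -> list[ImageRecord]:
    """Reload a generated dataset as ImageRecords (labels re-read from DOTA)."""
    from .annotations import read_dota

    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    records = []
    for entry in manifest["entries"]:
        rec = read_dota(out_dir / entry["label"], (entry["width"], entry["height"]))
        rec.image_path = out_dir / entry["image"]
        records.append(rec)
    return records
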