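"""Rotated-box annotation I/O: roLabelImg PASCAL-VOC XML and DOTA text.

Two dialects are supported:

* **roLabelImg XML** — PASCAL-VOC-style files with ``robndbox`` elements
  carrying ``cx, cy, w, h, angle``.  The tool stores the angle in radians in
  ``[0, 2*pi)`` (screen-clockwise) and its ``(w, h)`` are edge lengths along
  the box's local x/y axes, *not* sorted by length.  Reading converts to the
  package's canonical long-side five-parameter form.
* **DOTA text** — one object per line, ``x1 y1 x2 y2 x3 y3 x4 y4 label
  difficult``, vertices in the canonical order of :func:`rotphenex.rotgeom.to_quad`
  (edge v2->v3 is a long side), coordinates printed with one decimal place.

``split_dataset`` implements the 7:2:1 train/test/val bookkeeping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from lxml import etree

from .errors import AnnotationFormatError, InvalidArgumentError
from .rotgeom import QuadBox, RotatedBox, from_quad, to_quad, wrap_angle

logger = logging.getLogger(__name__)

__all__ = [
    "Annotation",
    "ImageRecord",
    "read_rolabelimg",
    "write_rolabelimg",
    "read_dota",
    "write_dota",
    "split_dataset",
]


@dataclass
class Annotation:
    """One labeled rotated box (ground truth for a single leaf)."""

    box: RotatedBox
    label: str = "leaf"
    difficult: int = 0

    def __post_init__(self) -> None:
        if not self.label:
            raise InvalidArgumentError("label must be non-empty")
        if self.difficult not in (0, 1):
            raise InvalidArgumentError("difficult flag must be 0 or 1")


@dataclass
class ImageRecord:
    """An image plus its rotated-box annotations.

    ``image`` optionally holds the decoded pixels (H x W x 3 uint8) for
    in-memory pipelines; file-based pipelines carry only ``image_path``.
    """

    image_path: Optional[Path]
    width: int
    height: int
    annotations: list = field(default_factory=list)
    image: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for ann in self.annotations:
            b = ann.box
            if not (0 <= b.cx < self.width and 0 <= b.cy < self.height):
                logger.warning(
                    "box center (%.1f, %.1f) outside %dx%d canvas in %s",
                    b.cx, b.cy, self.width, self.height, self.image_path,
                )

    def load_image(self) -> np.ndarray:
        if self.image is not None:
            return self.image
        from PIL import Image

        if self.image_path is None:
            raise InvalidArgumentError("record has neither pixels nor an image path")
        with Image.open(self.image_path) as im:
            self.image = np.asarray(im.convert("RGB"))
        return self.image


# --------------------------------------------------------------------------
# roLabelImg XML dialect


def _rolabelimg_to_canonical(cx, cy, w_t, h_t, angle_rad) -> RotatedBox:
    """Convert the tool's (unsorted, screen-clockwise-radians) box to long-side form."""
    deg = math.degrees(angle_rad)
    if w_t >= h_t:
        # long side along the tool's local x axis
        return RotatedBox(cx, cy, w=h_t, h=w_t, theta=wrap_angle(-deg))
    return RotatedBox(cx, cy, w=w_t, h=h_t, theta=wrap_angle(-deg - 90.0))


def _canonical_to_rolabelimg(box: RotatedBox) -> tuple[float, float, float, float, float]:
    """Inverse dialect conversion: long side written along the tool's local x."""
    angle = math.radians(-box.theta) % (2.0 * math.pi)
    return box.cx, box.cy, box.h, box.w, angle


def read_rolabelimg(xml_path) -> ImageRecord:
    """Read a roLabelImg PASCAL-VOC-style XML file."""
    xml_path = Path(xml_path)
    try:
        tree = etree.parse(str(xml_path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise AnnotationFormatError(f"cannot parse {xml_path}: {exc}") from exc
    root = tree.getroot()

    def _text(parent, tag, cast=str):
        el = parent.find(tag)
        if el is None or el.text is None:
            raise AnnotationFormatError(f"{xml_path}: missing element <{tag}>")
        try:
            return cast(el.text)
        except ValueError as exc:
            raise AnnotationFormatError(f"{xml_path}: bad value in <{tag}>") from exc

    size = root.find("size")
    if size is None:
        raise AnnotationFormatError(f"{xml_path}: missing element <size>")
    width = _text(size, "width", int)
    height = _text(size, "height", int)
    filename_el = root.find("filename")
    image_path = None
    if filename_el is not None and filename_el.text:
        image_path = xml_path.parent / filename_el.text

    annotations = []
    for obj in root.findall("object"):
        label = _text(obj, "name")
        diff_el = obj.find("difficult")
        difficult = int(diff_el.text) if diff_el is not None and diff_el.text else 0
        rb = obj.find("robndbox")
        if rb is None:
            raise AnnotationFormatError(f"{xml_path}: object without <robndbox>")
        cx = _text(rb, "cx", float)
        cy = _text(rb, "cy", float)
        w = _text(rb, "w", float)
        h = _text(rb, "h", float)
        angle = _text(rb, "angle", float)
        annotations.append(
            Annotation(_rolabelimg_to_canonical(cx, cy, w, h, angle), label, difficult)
        )
    return ImageRecord(image_path, width, height, annotations)


def write_rolabelimg(record: ImageRecord, xml_path) -> None:
    """Write a record in roLabelImg's XML dialect."""
    xml_path = Path(xml_path)
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = xml_path.parent.name
    etree.SubElement(root, "filename").text = (
        record.image_path.name if record.image_path else xml_path.stem + ".png"
    )
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(record.width)
    etree.SubElement(size, "height").text = str(record.height)
    etree.SubElement(size, "depth").text = "3"
    for ann in record.annotations:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "type").text = "robndbox"
        etree.SubElement(obj, "name").text = ann.label
        etree.SubElement(obj, "difficult").text = str(ann.difficult)
        rb = etree.SubElement(obj, "robndbox")
        cx, cy, w, h, angle = _canonical_to_rolabelimg(ann.box)
        etree.SubElement(rb, "cx").text = f"{cx:.6f}"
        etree.SubElement(rb, "cy").text = f"{cy:.6f}"
        etree.SubElement(rb, "w").text = f"{w:.6f}"
        etree.SubElement(rb, "h").text = f"{h:.6f}"
        etree.SubElement(rb, "angle").text = f"{angle:.8f}"
    xml_path.write_bytes(etree.tostring(root, pretty_print=True))


# --------------------------------------------------------------------------
# DOTA text dialect


def write_dota(record: ImageRecord, txt_path) -> None:
    """Write the record's boxes as DOTA task-1 lines (1-decimal coordinates)."""
    lines = []
    for ann in record.annotations:
        quad = to_quad(ann.box)
        coords = " ".join(f"{v:.1f}" for xy in quad.vertices for v in xy)
        lines.append(f"{coords} {ann.label} {ann.difficult}")
    Path(txt_path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_dota(txt_path, image_size: tuple[int, int]) -> ImageRecord:
    """Read a DOTA text file; ``image_size`` is (width, height) in pixels."""
    txt_path = Path(txt_path)
    width, height = image_size
    annotations = []
    for lineno, line in enumerate(txt_path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("imagesource", "gsd")):
            continue
        tokens = line.split()
        if len(tokens) != 10:
            raise AnnotationFormatError(
                f"{txt_path}:{lineno}: expected 10 tokens, got {len(tokens)}"
            )
        try:
            coords = [float(t) for t in tokens[:8]]
            difficult = int(tokens[9])
        except ValueError as exc:
            raise AnnotationFormatError(f"{txt_path}:{lineno}: {exc}") from exc
        quad = QuadBox(list(zip(coords[0::2], coords[1::2])))
        annotations.append(Annotation(from_quad(quad), tokens[8], difficult))
    return ImageRecord(None, width, height, annotations)


# --------------------------------------------------------------------------
# dataset split


def split_dataset(
    items: Sequence,
    ratios: tuple[float, float, float] = (7, 2, 1),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Deterministic seeded shuffle-and-split into (train, test, val).

    Split sizes are ``round(n * r_i / sum(r))`` with the rounding remainder
    assigned to the training set, so 1220 items at 7:2:1 give 854/244/122.
    """
    if any(r <= 0 for r in ratios):
        raise InvalidArgumentError("split ratios must be positive")
    items = list(items)
    n = len(items)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    total = float(sum(ratios))
    n_test = round(n * ratios[1] / total)
    n_val = round(n * ratios[2] / total)
    n_train = n - n_test - n_val
    idx_train = order[:n_train]
    idx_test = order[n_train : n_train + n_test]
    idx_val = order[n_train + n_test :]
    return (
        [items[i] for i in idx_train],
        [items[i] for i in idx_test],
        [items[i] for i in idx_val],
    )
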