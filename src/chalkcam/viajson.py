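"""VGG Image Annotator (VIA) polygon IO and rasterization.

Chalk-area ground truth is exchanged as VIA v2 JSON: per image, polygon
regions whose shape_attributes carry ``all_points_x`` / ``all_points_y``
vertex lists in pixel coordinates. The reader accepts a v2 project
(``_via_img_metadata``), a bare image-metadata dict, or a region-list
export; v1-style dicts are tolerated by key sniffing. Non-polygon region
shapes (rect, circle, ...) are skipped with a logged warning.

Rasterization convention: pixel (i, j) belongs to the polygon iff its
center (j + 0.5, i + 0.5) lies inside under the even-odd rule. The area of
a rasterized polygon then matches its geometric area to about half the
perimeter in pixels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PolygonAnnotation",
    "read_via_annotations",
    "write_via_annotations",
    "rasterize_polygon",
]


@dataclass
class PolygonAnnotation:
    image_id: str
    polygons: list[list[tuple[float, float]]] = field(default_factory=list)


def _regions_of(entry: dict) -> list:
    regions = entry.get("regions", [])
    if isinstance(regions, dict):  # v1 keyed regions
        regions = [regions[k] for k in sorted(regions)]
    return regions


def read_via_annotations(path) -> list[PolygonAnnotation]:
    """Parse a VIA JSON file into per-image polygon lists."""
    try:
        with open(path, "r", encoding="utf-8") as f:
            data = json.load(f)
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: malformed JSON at line {e.lineno}, column {e.colno}: {e.msg}")
    if isinstance(data, dict) and "_via_img_metadata" in data:
        data = data["_via_img_metadata"]
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a VIA project or image-metadata object")
    out = []
    for key, entry in data.items():
        if not isinstance(entry, dict):
            continue
        image_id = entry.get("filename", key)
        polygons = []
        for region in _regions_of(entry):
            shape = region.get("shape_attributes", {})
            if shape.get("name") != "polygon":
                logger.warning(
                    "%s: skipping non-polygon region (%s) on %s",
                    path, shape.get("name", "?"), image_id,
                )
                continue
            xs = shape.get("all_points_x", [])
            ys = shape.get("all_points_y", [])
            polygons.append([(float(x), float(y)) for x, y in zip(xs, ys)])
        out.append(PolygonAnnotation(image_id=image_id, polygons=polygons))
    return out


def write_via_annotations(annotations: list[PolygonAnnotation], path) -> None:
    """Write annotations as a VIA v2 project file."""
    metadata = {}
    for ann in annotations:
        regions = [
            {
                "shape_attributes": {
                    "name": "polygon",
                    "all_points_x": [float(x) for x, _ in poly],
                    "all_points_y": [float(y) for _, y in poly],
                },
                "region_attributes": {"label": "chalk"},
            }
            for poly in ann.polygons
        ]
        metadata[f"{ann.image_id}-1"] = {
            "filename": ann.image_id,
            "size": -1,
            "regions": regions,
            "file_attributes": {},
        }
    doc = {"_via_settings": {}, "_via_img_metadata": metadata, "_via_attributes": {}}
    with open(path, "w", encoding="utf-8") as f:
        json.dump(doc, f, indent=1, sort_keys=True)


def rasterize_polygon(polygon, image_hw: tuple[int, int]) -> np.ndarray:
    """Even-odd rasterization of one polygon at pixel centers.

    ``polygon`` is an ordered (x, y) vertex list (implicitly closed).
    A pixel is set iff a ray from its center crosses the polygon boundary an
    odd number of times; geometry outside the image is clipped by virtue of
    only testing in-image pixel centers.
    """
    verts = np.asarray(polygon, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValidationError("a polygon needs at least 3 (x, y) vertices")
    h, w = image_hw
    xc = np.arange(w) + 0.5
    yc = np.arange(h) + 0.5
    xs, ys = verts[:, 0], verts[:, 1]
    x2, y2 = np.roll(xs, -1), np.roll(ys, -1)
    inside = np.zeros((h, w), dtype=bool)
    for x1, y1, xx2, yy2 in zip(xs, ys, x2, y2):
        if y1 == yy2:
            continue  # horizontal edge: no vertical crossing
        crosses = (y1 > yc) != (yy2 > yc)  # (H,)
        if not crosses.any():
            continue
        xint = x1 + (yc - y1) * (xx2 - x1) / (yy2 - y1)  # (H,)
        hit = crosses[:, None] & (xc[None, :] < xint[:, None])
        inside ^= hit
    return inside
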