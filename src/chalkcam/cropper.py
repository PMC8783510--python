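"""Plate-scan preprocessing: find and crop individual grains.

Pipeline for one scanned plate: convert to grayscale, run Canny edge
detection, close broken contours, fill them, and take the bounding box of
every connected component large enough to be a grain. Crops are extracted
from the original RGB scan; grains whose box touches the plate border are
"truncated" and, by default, dropped and counted rather than analyzed.

Coordinates are 0-based with half-open boxes [x0, x1) x [y0, y1); box lists
are ordered top-to-bottom then left-to-right and are deterministic for
identical input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, filters

from .errors import EmptyMaskError, ValidationError
from .imaging import to_grayscale

__all__ = [
    "BoundingBox",
    "GrainImage",
    "GrainMask",
    "EdgeParams",
    "detect_grain_boxes",
    "crop_grains",
    "grain_area_mask",
]


@dataclass(frozen=True)
class BoundingBox:
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValidationError(f"degenerate box {(self.x0, self.y0, self.x1, self.y1)}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def touches_border(self, shape_hw: tuple[int, int]) -> bool:
        h, w = shape_hw
        return self.x0 <= 0 or self.y0 <= 0 or self.x1 >= w or self.y1 >= h


@dataclass
class GrainImage:
    """One cropped grain with provenance."""

    pixels: np.ndarray  # (H, W, 3) uint8, dims equal the (padded) box dims
    source_plate: str
    box: BoundingBox
    truncated: bool = False
    grain_id: str = ""


@dataclass
class GrainMask:
    """Binary grain-foreground raster and its pixel count Z (the denominator
    of the chalkiness score)."""

    mask: np.ndarray
    Z: int


@dataclass(frozen=True)
class EdgeParams:
    """Canny configuration. When low/high are None they are auto-set from
    the median gray value m as (0.67 m, 1.33 m) — a standard parameter-free
    default for high-contrast scans."""

    sigma: float = 1.4
    low: float | None = None
    high: float | None = None
    min_area: int = 200
    close_iterations: int = 2


def detect_grain_boxes(gray: np.ndarray, params: EdgeParams = EdgeParams()) -> list[BoundingBox]:
    """Detect per-grain bounding boxes on a grayscale plate image."""
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValidationError("detect_grain_boxes expects a single-channel image")
    m = float(np.median(gray))
    low = params.low if params.low is not None else 0.67 * m
    high = params.high if params.high is not None else 1.33 * m
    # Work in a padded frame: canny suppresses a border band and the closing
    # erosion treats outside-image as background, either of which would break
    # the contour of a grain lying close to (but not on) the plate border.
    p = int(np.ceil(2 * params.sigma)) + 2 + params.close_iterations
    gpad = np.pad(gray, p, mode="edge")
    edges = feature.canny(gpad, sigma=params.sigma, low_threshold=low, high_threshold=high)
    closed = ndimage.binary_closing(
        edges, structure=np.ones((3, 3), bool), iterations=params.close_iterations
    )[p:-p, p:-p]
    if float(gray.max() - gray.min()) > 0:
        # Close contours cut by the image border: a grain truncated by the
        # scan edge has no gradient along the border line, so mark bright
        # border pixels as edges (after morphological closing, which would
        # erode them) to let fill_holes produce a solid component whose box
        # then touches the border.
        t = filters.threshold_otsu(gray)
        # 2-px band: canny suppresses a 2-px boundary margin, so a 1-px line
        # would not connect to the open contour arc
        for sl in (np.s_[0:2, :], np.s_[-2:, :], np.s_[:, 0:2], np.s_[:, -2:]):
            closed[sl] |= gray[sl] > t
    filled = ndimage.binary_fill_holes(closed)
    labels, n = ndimage.label(filled, structure=np.ones((3, 3), int))
    boxes = []
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        region = labels[sl] > 0
        if int(region.sum()) < params.min_area:
            continue
        boxes.append(BoundingBox(x0=sl[1].start, y0=sl[0].start, x1=sl[1].stop, y1=sl[0].stop))
    boxes.sort(key=lambda b: (b.y0, b.x0))
    return boxes


def crop_grains(
    image: np.ndarray,
    boxes: list[BoundingBox],
    exclude_truncated: bool = True,
    pad: int = 0,
    source_plate: str = "plate",
) -> tuple[list[GrainImage], int]:
    """Extract one GrainImage per box; returns (crops, n_truncated_dropped).

    Boxes touching the image border are truncated grains; with
    ``exclude_truncated`` they are dropped and counted. Crops are padded by
    ``pad`` pixels per side (clipped to the image). Grain ids are
    deterministic: ``<plate>_<y0>_<x0>`` of the unpadded box.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError("crop_grains expects an (H, W, 3) RGB image")
    h, w = image.shape[:2]
    crops: list[GrainImage] = []
    n_truncated = 0
    for box in boxes:
        truncated = box.touches_border((h, w))
        if truncated and exclude_truncated:
            n_truncated += 1
            continue
        x0, y0 = max(box.x0 - pad, 0), max(box.y0 - pad, 0)
        x1, y1 = min(box.x1 + pad, w), min(box.y1 + pad, h)
        crops.append(
            GrainImage(
                pixels=image[y0:y1, x0:x1].copy(),
                source_plate=source_plate,
                box=BoundingBox(x0, y0, x1, y1),
                truncated=truncated,
                grain_id=f"{source_plate}_{box.y0:04d}_{box.x0:04d}",
            )
        )
    return crops, n_truncated


def grain_area_mask(grain: GrainImage | np.ndarray, min_contrast: float = 30.0) -> GrainMask:
    """Grain-foreground mask of a crop: Otsu threshold on the grayscale
    image, keep the largest connected component, fill holes.

    Degenerate crops: a uniform bright crop is all foreground; a uniform or
    near-uniform dark crop has no grain and raises :class:`EmptyMaskError`.
    """
    pixels = grain.pixels if isinstance(grain, GrainImage) else np.asarray(grain)
    if pixels.size == 0:
        raise ValidationError("empty grain image")
    gray = to_grayscale(pixels)
    if float(gray.max() - gray.min()) < min_contrast:
        if gray.min() >= 128.0:
            mask = np.ones(gray.shape, dtype=bool)
            return GrainMask(mask=mask, Z=int(mask.sum()))
        raise EmptyMaskError("crop has no detectable grain foreground")
    t = filters.threshold_otsu(gray)
    fg = gray > t
    if not fg.any():
        raise EmptyMaskError("crop has no detectable grain foreground")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), int))
    largest = np.argmax(ndimage.sum_labels(fg, labels, index=range(1, n + 1))) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    return GrainMask(mask=mask, Z=int(mask.sum()))
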