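"""Synthetic grain, plate and dataset generator.

Emulates scanned plates of rice grains as the pipeline assumes them: bright
elliptical grains on a near-black scanner background, 25-30 per plate, none
touching, each grain optionally carrying one soft-boundary bright blob that
plays the role of a chalky region (chalk in real grains is an opaque patch of
loosely packed starch with inherently soft boundaries). Every generated
object comes with exact ground truth: binary grain and chalk masks, a chalk
outline polygon, bounding boxes and a chalky/non-chalky label, so the
cropper, classifier, CAM engine, quantifier and evaluation modules are all
testable without any real scans.

Conventions: rasters are row-major, coordinates 0-based, boxes half-open
[x0, x1) x [y0, y1). The chalk blob's binary ground truth is its support at
half of the peak added brightness — the natural binary outline of a blurred
blob (the half-peak contour of a symmetrically blurred shape tracks the
pre-blur boundary).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .errors import CapacityError, ValidationError
from .imaging import write_image

__all__ = [
    "GrainSpec",
    "GrainTruth",
    "PlateLayout",
    "generate_grain",
    "generate_plate",
    "generate_dataset",
    "default_spec_sampler",
]

BACKGROUND_LEVEL = 10.0  # mean scanner background gray; +-5 per-grain jitter


@dataclass(frozen=True)
class GrainSpec:
    """Parameters of one rendered grain.

    grain_axes are the full pixel lengths (major, minor) of the grain
    ellipse; chalk_fraction is the target chalk area as a fraction of grain
    area; chalk_peak the peak added brightness of the blob; blur_sigma the
    Gaussian smoothing that gives the chalk its soft boundary.
    """

    grain_axes: tuple[float, float] = (44.0, 26.0)
    grain_intensity: float = 145.0
    chalk_present: bool = False
    chalk_fraction: float = 0.0
    chalk_peak: float = 80.0
    blur_sigma: float = 2.0
    noise_sd: float = 5.0
    rng_seed: int = 0

    def validate(self) -> None:
        major, minor = self.grain_axes
        if not (major > 0 and minor > 0):
            raise ValidationError("grain_axes must be positive")
        if not (0.0 <= self.chalk_fraction < 1.0):
            raise ValidationError("chalk_fraction must lie in [0, 1)")
        if not self.chalk_present and self.chalk_fraction != 0.0:
            raise ValidationError("chalk_fraction must be 0 for non-chalky grains")
        if self.chalk_present and self.chalk_fraction <= 0.0:
            raise ValidationError("chalky grains need chalk_fraction > 0")
        if self.noise_sd < 0 or self.blur_sigma < 0 or self.chalk_peak < 0:
            raise ValidationError("noise_sd, blur_sigma and chalk_peak must be >= 0")
        if not (0 < self.grain_intensity <= 255):
            raise ValidationError("grain_intensity must lie in (0, 255]")


@dataclass
class GrainTruth:
    """Ground truth for one grain: label, masks and chalk outline polygon."""

    label: str  # "chalky" | "non-chalky"
    grain_mask: np.ndarray
    chalk_mask: np.ndarray
    chalk_polygon: list[tuple[float, float]] = field(default_factory=list)


@dataclass(frozen=True)
class PlateLayout:
    plate_size: tuple[int, int] = (640, 640)  # (H, W)
    n_grains: int = 27
    min_gap: int = 6
    allow_border_truncation: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_grains < 0:
            raise ValidationError("n_grains must be >= 0")
        if self.min_gap < 1:
            raise ValidationError("min_gap must be >= 1 so grains cannot touch")
        if self.plate_size[0] < 1 or self.plate_size[1] < 1:
            raise ValidationError("plate_size must be positive")


def _mask_to_polygon(mask: np.ndarray, max_vertices: int = 100) -> list[tuple[float, float]]:
    """Outline a binary mask with a marching-squares contour, decimated to at
    most ``max_vertices`` (x, y) vertices — mimics a 10-100-click manual
    polygon around a chalk region."""
    if not mask.any():
        return []
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)
    step = max(1, int(np.ceil(len(contour) / max_vertices)))
    pts = contour[::step]
    # find_contours yields (row, col); polygons are (x, y)
    return [(float(c), float(r)) for r, c in pts]


def generate_grain(spec: GrainSpec) -> tuple[np.ndarray, GrainTruth]:
    """Render one grain crop and its ground truth.

    Returns an (H, W, 3) uint8 image whose foreground is an ellipse at
    ``grain_intensity`` on a near-black background. When chalk is present, a
    blurred bright elliptical blob is added inside the grain; its half-peak
    support covers ``chalk_fraction`` of the grain area (the blob is a
    sqrt(chalk_fraction)-scaled copy of the grain ellipse, randomly offset,
    so the target area is met by construction). Identical spec, identical
    seed => byte-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    a = spec.grain_axes[0] / 2.0  # semi-major
    b = spec.grain_axes[1] / 2.0  # semi-minor
    margin = int(np.ceil(4 * spec.blur_sigma + 4))
    side = int(np.ceil(spec.grain_axes[0])) + 2 * margin
    h = w = side
    cy = cx = side / 2.0
    theta = rng.uniform(-np.pi / 8, np.pi / 8)  # slight random tilt
    yy, xx = np.mgrid[0:h, 0:w]
    xs = (xx + 0.5) - cx
    ys = (yy + 0.5) - cy
    xr = xs * np.cos(theta) + ys * np.sin(theta)
    yr = -xs * np.sin(theta) + ys * np.cos(theta)
    grain_mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0

    background = BACKGROUND_LEVEL + rng.uniform(-5.0, 5.0)
    img = np.full((h, w), background, dtype=np.float64)
    img[grain_mask] = spec.grain_intensity

    chalk_mask = np.zeros((h, w), dtype=bool)
    if spec.chalk_present:
        s = np.sqrt(spec.chalk_fraction)
        # Blob center offset in the grain's normalized elliptical frame; the
        # 0.9 factor keeps the blob's half-peak contour clear of the rim.
        u = rng.uniform(0.0, 0.9 * (1.0 - s))
        phi = rng.uniform(0.0, 2 * np.pi)
        ox, oy = u * np.cos(phi), u * np.sin(phi)
        blob = ((xr / a - ox) / s) ** 2 + ((yr / b - oy) / s) ** 2 <= 1.0
        soft = ndimage.gaussian_filter(blob.astype(np.float64), spec.blur_sigma)
        peak = soft.max()
        if peak > 0:
            added = spec.chalk_peak * soft / peak
            half = spec.chalk_peak / 2.0
            # 1-unit guard band below the half-peak contour so chalk pixels
            # stay strictly brighter than non-chalk grain pixels even after
            # 8-bit quantization of the rendered image
            added = np.where((added >= half - 1.0) & (added < half), half - 1.0, added)
            chalk_mask = (added >= half) & grain_mask
            img = img + added * grain_mask
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    rgb = np.repeat(img[:, :, None], 3, axis=2)

    label = "chalky" if chalk_mask.any() else "non-chalky"
    truth = GrainTruth(
        label=label,
        grain_mask=grain_mask,
        chalk_mask=chalk_mask,
        chalk_polygon=_mask_to_polygon(chalk_mask),
    )
    return rgb, truth


def _crop_truth(truth: GrainTruth, y0: int, y1: int, x0: int, x1: int) -> GrainTruth:
    gm = truth.grain_mask[y0:y1, x0:x1]
    cm = truth.chalk_mask[y0:y1, x0:x1]
    return GrainTruth(
        label="chalky" if cm.any() else "non-chalky",
        grain_mask=gm,
        chalk_mask=cm,
        chalk_polygon=_mask_to_polygon(cm),
    )


def generate_plate(
    layout: PlateLayout, grain_specs: Sequence[GrainSpec]
) -> tuple[np.ndarray, list[tuple[tuple[int, int, int, int], GrainTruth]]]:
    """Compose grains onto one plate.

    Returns the plate image and, per grain, its tight bounding box
    (x0, y0, x1, y1, half-open, exactly enclosing the grain foreground) and
    crop-local ground truth. Grain bounding boxes are separated by at least
    ``min_gap`` pixels. With ``allow_border_truncation`` the first grain is
    deliberately pushed over the plate border to exercise truncation
    handling downstream.
    """
    layout.validate()
    if len(grain_specs) != layout.n_grains:
        raise ValidationError("need exactly one GrainSpec per grain in the layout")
    rng = np.random.default_rng(layout.rng_seed)
    ph, pw = layout.plate_size
    plate = np.full((ph, pw), BACKGROUND_LEVEL, dtype=np.float64)
    plate += rng.normal(0.0, 2.0, size=plate.shape)

    placed: list[tuple[int, int, int, int]] = []  # expanded boxes, plate coords
    out: list[tuple[tuple[int, int, int, int], GrainTruth]] = []
    gap = layout.min_gap
    for gi, spec in enumerate(grain_specs):
        img, truth = generate_grain(spec)
        rows = np.flatnonzero(truth.grain_mask.any(axis=1))
        cols = np.flatnonzero(truth.grain_mask.any(axis=0))
        gy0, gy1 = int(rows[0]), int(rows[-1]) + 1
        gx0, gx1 = int(cols[0]), int(cols[-1]) + 1
        bh, bw = gy1 - gy0, gx1 - gx0
        truncate_this = layout.allow_border_truncation and gi == 0
        for attempt in range(400):
            if truncate_this:
                # slide the grain half off a randomly chosen border
                side_pick = rng.integers(0, 4)
                if side_pick == 0:
                    y, x = -bh // 2, rng.integers(gap, max(pw - bw - gap, gap + 1))
                elif side_pick == 1:
                    y, x = ph - bh // 2, rng.integers(gap, max(pw - bw - gap, gap + 1))
                elif side_pick == 2:
                    y, x = rng.integers(gap, max(ph - bh - gap, gap + 1)), -bw // 2
                else:
                    y, x = rng.integers(gap, max(ph - bh - gap, gap + 1)), pw - bw // 2
            else:
                if ph - bh - 1 <= 1 or pw - bw - 1 <= 1:
                    raise CapacityError("grain larger than plate")
                y = int(rng.integers(1, ph - bh - 1))
                x = int(rng.integers(1, pw - bw - 1))
            box = (x - gap, y - gap, x + bw + gap, y + bh + gap)
            if all(
                box[2] <= o[0] or o[2] <= box[0] or box[3] <= o[1] or o[3] <= box[1]
                for o in placed
            ):
                break
        else:
            raise CapacityError(
                f"could not place grain {gi} after bounded retries; "
                "reduce n_grains, grain size or min_gap"
            )
        placed.append(box)

        # Paste: crop pixel (gy0+r, gx0+c) lands on plate pixel (y+r, x+c);
        # clip to the plate and max-blend (grain pixels dominate background).
        py0, py1 = max(y, 0), min(y + bh, ph)
        px0, px1 = max(x, 0), min(x + bw, pw)
        if py1 <= py0 or px1 <= px0:
            continue  # grain entirely outside the plate
        sy0, sx0 = gy0 + (py0 - y), gx0 + (px0 - x)
        sy1, sx1 = sy0 + (py1 - py0), sx0 + (px1 - px0)
        sub = img[sy0:sy1, sx0:sx1, 0].astype(np.float64)
        plate[py0:py1, px0:px1] = np.maximum(plate[py0:py1, px0:px1], sub)

        local = _crop_truth(truth, sy0, sy1, sx0, sx1)
        if not local.grain_mask.any():
            continue
        # re-tighten the box: clipping can leave empty rows/columns
        rr = np.flatnonzero(local.grain_mask.any(axis=1))
        cc = np.flatnonzero(local.grain_mask.any(axis=0))
        ty0, ty1 = int(rr[0]), int(rr[-1]) + 1
        tx0, tx1 = int(cc[0]), int(cc[-1]) + 1
        local = _crop_truth(local, ty0, ty1, tx0, tx1)
        out.append(((px0 + tx0, py0 + ty0, px0 + tx1, py0 + ty1), local))

    plate8 = np.clip(np.round(plate), 0, 255).astype(np.uint8)
    return np.repeat(plate8[:, :, None], 3, axis=2), out


def default_spec_sampler(rng: np.random.Generator, index: int) -> GrainSpec:
    """Study-condition sampler: alternating chalky/non-chalky (an exactly
    balanced set), chalk_fraction uniform on [0.2, 0.5], mild jitter on grain
    geometry and intensity."""
    chalky = index % 2 == 0
    frac = float(rng.uniform(0.2, 0.5)) if chalky else 0.0
    return GrainSpec(
        grain_axes=(float(rng.uniform(40, 48)), float(rng.uniform(22, 28))),
        grain_intensity=float(rng.uniform(130, 160)),
        chalk_present=chalky,
        chalk_fraction=frac,
        chalk_peak=float(rng.uniform(70, 90)),
        blur_sigma=2.0,
        noise_sd=5.0,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


def _assign_splits(n: int, split_ratio: tuple[float, float, float], rng: np.random.Generator) -> list[str]:
    if abs(sum(split_ratio) - 1.0) > 1e-9:
        raise ValidationError("split_ratio must sum to 1")
    order = rng.permutation(n)
    n_train = int(round(split_ratio[0] * n))
    n_dev = int(round(split_ratio[1] * n))
    splits = [""] * n
    for rank, idx in enumerate(order):
        if rank < n_train:
            splits[idx] = "train"
        elif rank < n_train + n_dev:
            splits[idx] = "dev"
        else:
            splits[idx] = "test"
    return splits


def generate_dataset(
    n_plates: int,
    layout: PlateLayout,
    out_dir,
    spec_sampler: Callable[[np.random.Generator, int], GrainSpec] = default_spec_sampler,
    split_ratio: tuple[float, float, float] = (0.5, 0.25, 0.25),
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Write a full synthetic dataset: per-grain PNG crops, a CSV manifest
    (path, label, split, plate, box coordinates) and a VIA-v2 JSON with the
    chalk polygons of every chalky grain. Splits are disjoint by grain.
    Returns the manifest as a DataFrame (also written to manifest.csv)."""
    from .viajson import PolygonAnnotation, write_via_annotations

    out_dir = Path(out_dir)
    crops_dir = out_dir / "crops"
    crops_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(rng_seed)

    rows = []
    annotations = []
    gidx = 0
    for p in range(n_plates):
        plate_layout = replace(layout, rng_seed=int(rng.integers(0, 2**31 - 1)))
        specs = [spec_sampler(rng, gidx + i) for i in range(layout.n_grains)]
        plate, items = generate_plate(plate_layout, specs)
        plate_id = f"plate{p:03d}"
        for (x0, y0, x1, y1), truth in items:
            crop = plate[y0:y1, x0:x1]
            name = f"{plate_id}_{y0:04d}_{x0:04d}.png"
            write_image(crop, crops_dir / name)
            rows.append(
                {
                    "path": f"crops/{name}",
                    "label": truth.label,
                    "split": "",
                    "plate": plate_id,
                    "box_x0": x0,
                    "box_y0": y0,
                    "box_x1": x1,
                    "box_y1": y1,
                }
            )
            if truth.label == "chalky":
                annotations.append(PolygonAnnotation(image_id=name, polygons=[truth.chalk_polygon]))
            gidx += 1

    splits = _assign_splits(len(rows), split_ratio, rng)
    for row, split in zip(rows, splits):
        row["split"] = split
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    write_via_annotations(annotations, out_dir / "annotations.json")
    return manifest


def manifest_hash(path) -> str:
    """SHA-256 of a manifest file; used to assert byte-level determinism."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
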