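"""Shared raster helpers.

The bilinear resize here is corner-aligned: output sample positions are
``linspace(0, in-1, out)`` along each axis, so the four corner values of the
input are reproduced exactly in the output. This is deliberately hand-rolled
rather than delegated, because downstream heatmap binarization and scoring
must be bit-reproducible across library versions; the convention is stated
once here and used for every resize in the package (images, heatmaps, masks).
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from .errors import ValidationError

__all__ = ["bilinear_resize", "resize_rgb", "to_grayscale", "read_image", "write_image"]

# ITU-R BT.601 luminance weights — the classic 0.299/0.587/0.114 triple.
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """RGB (H, W, 3) -> float grayscale (H, W) via BT.601 luminance."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError(f"expected an (H, W, 3) RGB raster, got shape {image.shape}")
    return image.astype(np.float64) @ _LUMA


def bilinear_resize(arr: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Resize a 2-D array with corner-aligned bilinear interpolation."""
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError("bilinear_resize expects a 2-D array")
    h, w = arr.shape
    ho, wo = out_hw
    if ho < 1 or wo < 1:
        raise ValidationError("output dimensions must be positive")
    ys = np.linspace(0.0, h - 1.0, ho) if ho > 1 else np.array([0.0])
    xs = np.linspace(0.0, w - 1.0, wo) if wo > 1 else np.array([0.0])
    y0 = np.clip(np.floor(ys).astype(int), 0, max(h - 2, 0))
    x0 = np.clip(np.floor(xs).astype(int), 0, max(w - 2, 0))
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    fy = (ys - y0)[:, None]
    fx = (xs - x0)[None, :]
    a = arr[np.ix_(y0, x0)]
    b = arr[np.ix_(y0, x1)]
    c = arr[np.ix_(y1, x0)]
    d = arr[np.ix_(y1, x1)]
    return (a * (1 - fy) * (1 - fx) + b * (1 - fy) * fx + c * fy * (1 - fx) + d * fy * fx)


def resize_rgb(image: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Per-channel bilinear resize of an (H, W, 3) image; float64 output."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError(f"expected an (H, W, 3) RGB raster, got shape {image.shape}")
    return np.stack([bilinear_resize(image[..., k], out_hw) for k in range(3)], axis=-1)


def read_image(path) -> np.ndarray:
    """Load a TIFF/JPEG/PNG image as (H, W, 3) uint8 RGB."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(image: np.ndarray, path) -> None:
    image = np.asarray(image)
    if image.dtype != np.uint8:
        image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    Image.fromarray(image).save(path)
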