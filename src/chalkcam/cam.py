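"""Class-activation heatmaps: Grad-CAM, Grad-CAM++ and Score-CAM.

Grad-CAM, for a class of interest c (here: chalky) and a chosen
convolutional layer with feature maps f^k (k = 1..K, N spatial positions
each), computes per-map importance weights as the spatial average of the
exact gradient of the class logit y^c (not the softmax output):

    w_k^c = (1/N) * sum_ij  d y^c / d f^k_ij

and the heatmap as the ReLU of the weighted sum of feature maps,

    H^c = ReLU( sum_k w_k^c f^k ),

then resizes H^c to the model input size with corner-aligned bilinear
interpolation (H^c_final). ReLU cancels negative evidence so the heatmap is
nonnegative everywhere.

Grad-CAM++ replaces the uniform spatial average by pixel-wise coefficients
built from second- and third-order terms of the logit gradient (closed form
under the standard elementwise-power approximation):

    alpha_ij^k = g_ij^2 / (2 g_ij^2 + (sum_ab f^k_ab) g_ij^3),   g = dy^c/df^k
    w_k^c = sum_ij alpha_ij^k * ReLU(g_ij)

Score-CAM is gradient-free: each activation map is upsampled to input size,
min-max normalized to [0, 1], used to mask the input, and weighted by the
softmax (across maps) of the class-c logit of the masked input. Constant
maps, for which the min-max mask is ill-defined, receive weight exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import ModelHandle, preprocess
from .errors import ValidationError
from .imaging import bilinear_resize

__all__ = [
    "FeatureStack",
    "CamWeights",
    "Heatmap",
    "gradcam_weights",
    "gradcam_heatmap",
    "gradcampp_heatmap",
    "scorecam_weights",
    "scorecam_heatmap",
    "compute_heatmap",
    "finite_difference_weights",
    "CAM_METHODS",
]


@dataclass
class FeatureStack:
    maps: np.ndarray  # (K, H_f, W_f)
    layer_name: str

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    @property
    def N(self) -> int:
        return self.maps.shape[1] * self.maps.shape[2]


@dataclass
class CamWeights:
    w: np.ndarray  # (K,)
    class_index: int
    layer_name: str


@dataclass
class Heatmap:
    raw: np.ndarray  # (H_f, W_f), >= 0
    final: np.ndarray  # (H_in, W_in), >= 0
    layer_name: str
    class_index: int
    method: str


def _as_input(handle: ModelHandle, image) -> np.ndarray:
    """Accept a GrainImage, an (H, W, 3) uint8 crop, or an already
    preprocessed (3, H_in, W_in) float array."""
    pixels = getattr(image, "pixels", image)
    pixels = np.asarray(pixels)
    if pixels.ndim == 3 and pixels.shape[0] == 3 and pixels.dtype != np.uint8:
        return pixels.astype(np.float32)
    return preprocess(pixels, handle.input_size)


def _finalize(handle: ModelHandle, raw: np.ndarray, layer: str, class_index: int, method: str) -> Heatmap:
    final = bilinear_resize(raw, handle.input_size)
    # bilinear interpolation of a nonnegative map is nonnegative up to
    # float round-off; clamp so the contract holds exactly
    np.maximum(final, 0.0, out=final)
    return Heatmap(raw=raw, final=final, layer_name=layer, class_index=class_index, method=method)


def gradcam_weights(handle: ModelHandle, image, class_index: int, layer: str) -> CamWeights:
    """Grad-CAM importance weights: spatial mean of d y^c / d f^k."""
    x = _as_input(handle, image)
    _, grads = handle.net.logit_gradients(x, class_index, layer)
    return CamWeights(w=grads.mean(axis=(1, 2)), class_index=class_index, layer_name=layer)


def gradcam_heatmap(handle: ModelHandle, image, class_index: int, layer: str) -> Heatmap:
    x = _as_input(handle, image)
    feats, grads = handle.net.logit_gradients(x, class_index, layer)
    w = grads.mean(axis=(1, 2))
    raw = np.maximum(np.tensordot(w, feats.astype(np.float64), axes=1), 0.0)
    return _finalize(handle, raw, layer, class_index, "gradcam")


def gradcampp_heatmap(handle: ModelHandle, image, class_index: int, layer: str) -> Heatmap:
    x = _as_input(handle, image)
    feats, grads = handle.net.logit_gradients(x, class_index, layer)
    f = feats.astype(np.float64)
    g = grads.astype(np.float64)
    g2 = g * g
    g3 = g2 * g
    denom = 2.0 * g2 + f.sum(axis=(1, 2), keepdims=True) * g3
    alpha = np.divide(g2, denom, out=np.zeros_like(g2), where=denom != 0.0)
    w = (alpha * np.maximum(g, 0.0)).sum(axis=(1, 2))
    raw = np.maximum(np.tensordot(w, f, axes=1), 0.0)
    return _finalize(handle, raw, layer, class_index, "gradcam++")


def scorecam_weights(
    handle: ModelHandle, image, class_index: int, layer: str, batch: int = 32
) -> tuple[np.ndarray, np.ndarray]:
    """Score-CAM map weights and the feature stack they apply to.

    Each map is upsampled, min-max normalized and used to mask the input;
    its weight is the softmax (across maps) of the class-c logit of the
    masked input. Constant maps get weight exactly 0.
    """
    x = _as_input(handle, image)
    handle.net.forward(x[None], cache=True)
    feats = handle.net.features(layer)[0].astype(np.float64)
    k = feats.shape[0]

    masks = np.zeros((k,) + tuple(handle.input_size), dtype=np.float64)
    valid = np.zeros(k, dtype=bool)
    for i in range(k):
        if float(feats[i].max()) <= float(feats[i].min()):
            continue  # constant map: min-max mask ill-defined -> weight 0
        up = bilinear_resize(feats[i], handle.input_size)
        lo, hi = float(up.min()), float(up.max())
        if hi > lo:
            masks[i] = (up - lo) / (hi - lo)
            valid[i] = True
    weights = np.zeros(k, dtype=np.float64)
    vidx = np.flatnonzero(valid)
    if len(vidx):
        scores = np.empty(len(vidx), dtype=np.float64)
        for start in range(0, len(vidx), batch):
            sel = vidx[start:start + batch]
            masked = x[None] * masks[sel][:, None]  # (b, 3, H, W)
            out = handle.net.forward(masked.astype(np.float32))
            scores[start:start + batch] = out[:, class_index]
        e = np.exp(scores - scores.max())
        weights[vidx] = e / e.sum()
    return weights, feats


def scorecam_heatmap(
    handle: ModelHandle, image, class_index: int, layer: str, batch: int = 32
) -> Heatmap:
    weights, feats = scorecam_weights(handle, image, class_index, layer, batch)
    raw = np.maximum(np.tensordot(weights, feats, axes=1), 0.0)
    return _finalize(handle, raw, layer, class_index, "scorecam")


CAM_METHODS = {
    "gradcam": gradcam_heatmap,
    "gradcam++": gradcampp_heatmap,
    "scorecam": scorecam_heatmap,
}


def compute_heatmap(handle: ModelHandle, image, class_index: int, layer: str, method: str = "gradcam") -> Heatmap:
    try:
        fn = CAM_METHODS[method]
    except KeyError:
        raise ValidationError(f"unknown CAM method {method!r}; choose from {sorted(CAM_METHODS)}")
    return fn(handle, image, class_index, layer)


def finite_difference_weights(
    handle: ModelHandle, image, class_index: int, layer: str, eps: float = 1e-3, batch: int = 16
) -> np.ndarray:
    """Independent numerical estimate of the Grad-CAM weights.

    Perturbs every feature-map position by +-eps, reruns the network from
    the layer onward, and averages the central-difference estimates of
    d y^c / d f^k_ij over positions. Batched for speed; exact up to O(eps^2)
    away from ReLU/maxpool kinks.
    """
    x = _as_input(handle, image)
    handle.net.forward(x[None], cache=True)
    feats = handle.net.features(layer)[0]
    k, hf, wf = feats.shape
    n = hf * wf
    flat = feats.reshape(k * n).astype(np.float64)
    grads = np.empty(k * n, dtype=np.float64)
    total = k * n
    for start in range(0, total, batch):
        stop = min(start + batch, total)
        b = stop - start
        plus = np.repeat(flat[None], b, axis=0)
        minus = plus.copy()
        cols = np.arange(start, stop)
        plus[np.arange(b), cols] += eps
        minus[np.arange(b), cols] -= eps
        stacked = np.concatenate([plus, minus]).reshape(2 * b, k, hf, wf)
        out = handle.net.forward_from(layer, stacked.astype(np.float32))[:, class_index]
        grads[start:stop] = (out[:b].astype(np.float64) - out[b:].astype(np.float64)) / (2 * eps)
    return grads.reshape(k, n).mean(axis=1)
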