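"""Minimal CNN engine with exact backpropagation, written on numpy.

This module provides the pieces needed by the chalkiness classifier and the
class-activation-mapping engine:

* forward passes that cache the activations of named convolutional blocks
  (the feature maps ``f^k`` a CAM method weights and sums),
* exact gradients of a chosen output logit ``y^c`` with respect to those
  feature maps (the quantity Grad-CAM spatially averages), and
* truncated forward passes that restart the network from a named block's
  activations (used by Score-CAM's masked-input scoring and by
  finite-difference verification of the analytic gradients).

Everything is float32, seeded, and free of threading or fused-kernel
nondeterminism, so fixed seed + fixed data implies bit-identical training
trajectories on a given BLAS.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = ["TinyCNN", "softmax", "cross_entropy_grad"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


# ---------------------------------------------------------------- layers


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    """Stack k*k shifted views of a padded batch into (B, C*k*k, H*W)."""
    b, c, hp, wp = xp.shape
    h, w = hp - k + 1, wp - k + 1
    cols = np.empty((b, c, k * k, h, w), dtype=xp.dtype)
    idx = 0
    for di in range(k):
        for dj in range(k):
            cols[:, :, idx] = xp[:, :, di:di + h, dj:dj + w]
            idx += 1
    return cols.reshape(b, c * k * k, h * w)


class _Conv2d:
    """3x3 same-padding convolution (stride 1)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        self.k = k
        self.pad = k // 2
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.w = (rng.standard_normal((c_out, fan_in)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        cols = _im2col(xp, self.k)
        out = np.matmul(self.w, cols) + self.b[:, None]
        if cache:
            self._cols = cols
            self._in_shape = x.shape
        return out.reshape(b, -1, h, w)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, c_out, h, w = gout.shape
        g = gout.reshape(b, c_out, h * w)
        self.gw = np.einsum("bof,bcf->oc", g, self._cols).astype(np.float32)
        self.gb = g.sum(axis=(0, 2)).astype(np.float32)
        gcols = np.matmul(self.w.T, g)  # (B, C*k*k, H*W)
        _, c_in, hin, win = self._in_shape
        gcols = gcols.reshape(b, c_in, self.k * self.k, h, w)
        gxp = np.zeros((b, c_in, hin + 2 * self.pad, win + 2 * self.pad), dtype=np.float32)
        idx = 0
        for di in range(self.k):
            for dj in range(self.k):
                gxp[:, :, di:di + h, dj:dj + w] += gcols[:, :, idx]
                idx += 1
        p = self.pad
        return gxp[:, :, p:p + hin, p:p + win]

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class _ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if cache:
            self._mask = x > 0.0
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask

    def params(self):
        return []


class _MaxPool2:
    """2x2 non-overlapping max pooling; ties route the gradient to the
    first (row-major) maximum so backward is a function, not a relation."""

    def __init__(self):
        self._idx = None
        self._in_shape = None

    @staticmethod
    def _windows(x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        return (
            x.reshape(b, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, h // 2, w // 2, 4)
        )

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        xw = self._windows(x)
        idx = xw.argmax(axis=-1)
        out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        if cache:
            self._idx = idx
            self._in_shape = x.shape
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, c, ho, wo = gout.shape
        g4 = np.zeros((b, c, ho, wo, 4), dtype=np.float32)
        np.put_along_axis(g4, self._idx[..., None], gout[..., None], axis=-1)
        return (
            g4.reshape(b, c, ho, wo, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(self._in_shape)
        )

    def params(self):
        return []


class _GlobalAvgPool:
    def __init__(self):
        self._in_shape = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        if cache:
            self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._in_shape
        return np.broadcast_to(gout[:, :, None, None], self._in_shape) / (h * w)

    def params(self):
        return []


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / n_in)
        self.w = (rng.standard_normal((n_out, n_in)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        if cache:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.gw = (gout.T @ self._x).astype(np.float32)
        self.gb = gout.sum(axis=0).astype(np.float32)
        return gout @ self.w

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


# ----------------------------------------------------------------- model


class TinyCNN:
    """Three conv blocks (3x3 conv -> ReLU -> 2x2 maxpool), global average
    pooling and a 2-logit head.

    With the default 64x64 input the named block outputs are::

        block1: 8 maps of 32x32
        block2: 16 maps of 16x16
        block3: 32 maps of  8x8

    The block outputs are the feature stacks the CAM engine consumes.
    """

    def __init__(
        self,
        in_channels: int = 3,
        channels: Sequence[int] = (8, 16, 32),
        input_size: tuple[int, int] = (64, 64),
        n_classes: int = 2,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.input_size = tuple(input_size)
        self.channels = tuple(channels)
        self.n_classes = n_classes
        self.layers: list = []
        self.layer_names: list[str] = []
        self._feature_after: dict[str, int] = {}
        c_prev = in_channels
        for i, c in enumerate(channels, start=1):
            self.layers += [_Conv2d(c_prev, c, rng), _ReLU(), _MaxPool2()]
            name = f"block{i}"
            self.layer_names.append(name)
            self._feature_after[name] = len(self.layers)  # index past the pool
            c_prev = c
        self.layers.append(_GlobalAvgPool())
        self.layers.append(_Linear(c_prev, n_classes, rng))
        self._features: dict[str, np.ndarray] = {}
        self._feature_grads: dict[str, np.ndarray] = {}

    # -- inspection ------------------------------------------------------

    def _check_layer(self, name: str) -> int:
        if name not in self._feature_after:
            raise ConfigurationError(
                f"unknown layer {name!r}; inspectable layers: {self.layer_names}"
            )
        return self._feature_after[name]

    def feature_shape(self, name: str) -> tuple[int, int, int]:
        """(K, H_f, W_f) of a block's feature stack for the model input size."""
        self._check_layer(name)
        i = self.layer_names.index(name)
        h, w = self.input_size
        for _ in range(i + 1):
            h, w = h // 2, w // 2
        return self.channels[i], h, w

    # -- forward / backward ---------------------------------------------

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        """Run the network; ``x`` is (B, C, H, W) float32. When ``cache`` is
        true, activations are retained for :meth:`backward` and the named
        block outputs are stored for CAM use."""
        x = np.asarray(x, dtype=np.float32)
        self._features = {}
        cut = {v: k for k, v in self._feature_after.items()}
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, cache)
            if cache and (i + 1) in cut:
                self._features[cut[i + 1]] = x
        return x

    def forward_from(self, layer_name: str, feats: np.ndarray) -> np.ndarray:
        """Truncated forward pass: treat ``feats`` (B, K, H_f, W_f) as the
        output of ``layer_name`` and run the remaining layers."""
        start = self._check_layer(layer_name)
        x = np.asarray(feats, dtype=np.float32)
        for layer in self.layers[start:]:
            x = layer.forward(x, cache=False)
        return x

    def backward(self, grad_logits: np.ndarray) -> None:
        """Backpropagate from the logits; fills parameter gradients and
        records the gradient arriving at every named block output."""
        g = np.asarray(grad_logits, dtype=np.float32)
        self._feature_grads = {}
        cut = {v: k for k, v in self._feature_after.items()}
        for i in range(len(self.layers) - 1, -1, -1):
            if (i + 1) in cut:
                self._feature_grads[cut[i + 1]] = g
            g = self.layers[i].backward(g)

    def features(self, name: str) -> np.ndarray:
        self._check_layer(name)
        return self._features[name]

    def feature_grad(self, name: str) -> np.ndarray:
        self._check_layer(name)
        return self._feature_grads[name]

    def logit_gradients(self, x: np.ndarray, class_index: int, layer_name: str) -> tuple[np.ndarray, np.ndarray]:
        """Feature stack and exact d(y^c)/d(f) for one image (C, H, W).

        The backward pass starts from the raw class logit, not the softmax
        output, so the gradients are those of ``y^c`` itself.
        """
        self._check_layer(layer_name)
        logits = self.forward(x[None], cache=True)
        seed = np.zeros_like(logits)
        seed[0, class_index] = 1.0
        self.backward(seed)
        return self._features[layer_name][0], self._feature_grads[layer_name][0]

    # -- parameters ------------------------------------------------------

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ConfigurationError("checkpoint does not match this architecture")
        for (p, _), s in zip(params, state):
            if p.shape != s.shape:
                raise ConfigurationError("checkpoint does not match this architecture")
            p[...] = s


class SGD:
    """Plain SGD with classical momentum."""

    def __init__(self, model: TinyCNN, lr: float, momentum: float = 0.9):
        self.lr = lr
        self.momentum = momentum
        self.model = model
        self.velocity = [np.zeros_like(p) for p, _ in model.parameters()]

    def step(self) -> None:
        for v, (p, g) in zip(self.velocity, self.model.parameters()):
            v *= self.momentum
            v -= self.lr * g
            p += v
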