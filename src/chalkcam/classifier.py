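"""Binary chalky/non-chalky grain classification.

A backbone CNN is trained on image-level labels only; the trained handle
also exposes the feature maps and logit gradients the CAM engine needs, so
the same model that classifies a grain can explain *where* it saw chalk.

Class convention used everywhere: non-chalky = index 0, chalky = index 1;
"chalky" is the class of interest c for all heatmap computations. Ties in
the argmax break toward the lower index (non-chalky).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ValidationError
from .imaging import read_image, resize_rgb
from .nn import SGD, TinyCNN, cross_entropy_grad, softmax

__all__ = [
    "ModelHandle",
    "TrainConfig",
    "ClassificationReport",
    "build_backbone",
    "train",
    "predict",
    "classification_metrics",
    "save_checkpoint",
    "load_checkpoint",
    "load_split",
    "preprocess",
]

CLASS_INDEX = {"non-chalky": 0, "chalky": 1}
CLASS_NAMES = ("non-chalky", "chalky")

BATCH_SIZE_GRID = (16, 32, 64)
LEARNING_RATE_GRID = (0.1, 0.01, 0.001, 0.0001, 0.00001)


def round2(x: float) -> float:
    """Round half-up to 2 decimals — the convention of every reported %."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ModelHandle:
    net: TinyCNN
    backbone_name: str = "tiny"
    input_size: tuple[int, int] = (64, 64)
    class_index_map: dict = field(default_factory=lambda: dict(CLASS_INDEX))

    @property
    def layer_names(self) -> list[str]:
        return list(self.net.layer_names)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 0.01
    max_epochs: int = 30
    momentum: float = 0.9
    rng_seed: int = 0
    selection_metric: str = "f1_chalky_dev"

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValidationError("batch_size and max_epochs must be >= 1")


@dataclass
class ClassificationReport:
    """Accuracy and per-class precision/recall/F1 as percentages, plus the
    confusion counts they are computed from (chalky is the positive class
    for the chalky row, and vice versa)."""

    accuracy: float
    per_class: dict  # {"chalky": {"precision":..., "recall":..., "f1":...}, ...}
    confusion: dict  # {"tp":..., "fp":..., "fn":..., "tn":...} w.r.t. chalky

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "per_class": self.per_class, "confusion": self.confusion}


def build_backbone(
    name: str = "tiny", pretrained: bool = False, input_size: tuple[int, int] = (64, 64), seed: int = 0
) -> ModelHandle:
    """Construct a classification backbone.

    Only the CPU-trainable "tiny" backbone (three 3x3-conv/ReLU/2x2-maxpool
    blocks with 8/16/32 channels, global average pooling, 2-logit head) ships
    with the package; it has no pretrained weights. Other architecture names
    raise a configuration error.
    """
    if name != "tiny":
        raise ConfigurationError(
            f"unknown backbone {name!r}: no deep-learning runtime or pretrained "
            "weights are bundled; the built-in backbone is 'tiny'"
        )
    if pretrained:
        raise ConfigurationError("the tiny backbone has no pretrained weights")
    net = TinyCNN(input_size=tuple(input_size), seed=seed)
    return ModelHandle(net=net, backbone_name=name, input_size=tuple(input_size))


def preprocess(image: np.ndarray, input_size: tuple[int, int]) -> np.ndarray:
    """uint8 (H, W, 3) crop -> float32 (3, H_in, W_in) in [-1, 1].

    Crops are resized to the backbone input size by direct bilinear resize
    without aspect preservation.
    """
    resized = resize_rgb(image, input_size) / 255.0
    return ((resized - 0.5) / 0.5).transpose(2, 0, 1).astype(np.float32)


def load_split(
    manifest: pd.DataFrame, split: str, input_size: tuple[int, int], root=None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load one manifest split as (X, y, paths); X is (N, 3, H, W) float32."""
    sub = manifest[manifest["split"] == split]
    xs, ys, paths = [], [], []
    for _, row in sub.iterrows():
        p = Path(row["path"])
        if root is not None and not p.is_absolute():
            p = Path(root) / p
        xs.append(preprocess(read_image(p), input_size))
        ys.append(CLASS_INDEX[row["label"]])
        paths.append(str(row["path"]))
    if not xs:
        return np.zeros((0, 3) + tuple(input_size), np.float32), np.zeros(0, int), []
    return np.stack(xs), np.asarray(ys), paths


@dataclass
class TrainResult:
    handle: ModelHandle
    log: list[dict]
    best_epoch: int
    best_dev_f1: float


def _chalky_f1(pred: np.ndarray, true: np.ndarray) -> float:
    tp = int(((pred == 1) & (true == 1)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0


def _predict_array(net: TinyCNN, x: np.ndarray, batch: int = 64) -> np.ndarray:
    out = [net.forward(x[i:i + batch]) for i in range(0, len(x), batch)]
    return np.concatenate(out) if out else np.zeros((0, 2), np.float32)


def train(
    handle: ModelHandle,
    manifest: pd.DataFrame | str | Path,
    config: TrainConfig = TrainConfig(),
    root=None,
) -> TrainResult:
    """Train with SGD + momentum on cross-entropy; after each epoch evaluate
    on the dev split and retain the checkpoint with the best chalky F1.

    The log records per-epoch training loss and dev metrics; fixed seed and
    data give a reproducible trajectory.
    """
    config.validate()
    if not isinstance(manifest, pd.DataFrame):
        if root is None:
            root = Path(manifest).parent
        manifest = pd.read_csv(manifest)
    x_train, y_train, _ = load_split(manifest, "train", handle.input_size, root)
    x_dev, y_dev, _ = load_split(manifest, "dev", handle.input_size, root)
    if len(np.unique(y_train)) < 2:
        raise DataError("training split must contain both chalky and non-chalky grains")

    rng = np.random.default_rng(config.rng_seed)
    opt = SGD(handle.net, lr=config.learning_rate, momentum=config.momentum)
    log: list[dict] = []
    best_f1, best_epoch, best_state = -1.0, -1, handle.net.get_state()
    n = len(x_train)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = handle.net.forward(x_train[idx], cache=True)
            loss, grad = cross_entropy_grad(logits, y_train[idx])
            handle.net.backward(grad)
            opt.step()
            losses.append(loss)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if len(x_dev):
            dev_pred = _predict_array(handle.net, x_dev).argmax(axis=1)
            f1 = _chalky_f1(dev_pred, y_dev)
            entry["dev_f1_chalky"] = f1
            entry["dev_accuracy"] = float((dev_pred == y_dev).mean())
            if f1 > best_f1:
                best_f1, best_epoch = f1, epoch
                best_state = handle.net.get_state()
        log.append(entry)
    if best_epoch >= 0:
        handle.net.set_state(best_state)
    else:  # no dev split: keep the final weights
        best_epoch, best_f1 = config.max_epochs - 1, float("nan")
    return TrainResult(handle=handle, log=log, best_epoch=best_epoch, best_dev_f1=best_f1)


def predict(handle: ModelHandle, grain) -> tuple[str, np.ndarray]:
    """Classify one grain; returns (label, raw logits). The logits are kept
    unsoftmaxed for CAM use; equal logits break toward non-chalky."""
    pixels = getattr(grain, "pixels", grain)
    x = preprocess(np.asarray(pixels), handle.input_size)
    logits = handle.net.forward(x[None])[0]
    label = CLASS_NAMES[int(np.argmax(logits))]  # argmax -> first max -> index 0 on ties
    return label, logits


def classification_metrics(pred_labels: Sequence[str], true_labels: Sequence[str]) -> ClassificationReport:
    """Accuracy and per-class precision/recall/F1 (%, half-up to 2 decimals);
    any 0/0 is reported as 0.00."""
    if len(pred_labels) == 0 or len(pred_labels) != len(true_labels):
        raise ValidationError("need equal-length, non-empty label lists")
    pred = np.asarray([CLASS_INDEX[p] for p in pred_labels])
    true = np.asarray([CLASS_INDEX[t] for t in true_labels])
    per_class = {}
    for cname, c in CLASS_INDEX.items():
        tp = int(((pred == c) & (true == c)).sum())
        fp = int(((pred == c) & (true != c)).sum())
        fn = int(((pred != c) & (true == c)).sum())
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[cname] = {
            "precision": round2(100 * prec),
            "recall": round2(100 * rec),
            "f1": round2(100 * f1),
        }
    tp = int(((pred == 1) & (true == 1)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())
    return ClassificationReport(
        accuracy=round2(100 * float((pred == true).mean())),
        per_class=per_class,
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )


def probabilities(logits: np.ndarray) -> np.ndarray:
    return softmax(np.asarray(logits, dtype=np.float64))


def save_checkpoint(handle: ModelHandle, path) -> None:
    """Persist weights (npz) plus a JSON header describing the handle."""
    path = Path(path)
    state = handle.net.get_state()
    meta = {
        "backbone_name": handle.backbone_name,
        "input_size": list(handle.input_size),
        "class_index_map": handle.class_index_map,
        "layer_names": handle.layer_names,
    }
    with open(path, "wb") as f:  # keep the exact filename (np.savez appends .npz)
        np.savez(f, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **{f"p{i}": s for i, s in enumerate(state)})


def load_checkpoint(path) -> ModelHandle:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        state = [data[f"p{i}"] for i in range(len(data.files) - 1)]
    handle = build_backbone(meta["backbone_name"], input_size=tuple(meta["input_size"]))
    handle.net.set_state(state)
    return handle
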