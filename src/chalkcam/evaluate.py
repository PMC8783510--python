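"""Localization metrics, layer/threshold grid search, group aggregation.

Metrics for weakly supervised chalk localization on ground-truth chalky
grains:

* IoU — |pred ∩ truth| / |pred ∪ truth| between binary chalk masks;
* average IoU (%) over a set of chalky grains;
* GT-known localization accuracy (%) — fraction of ground-truth chalky
  grains whose IoU >= 0.5, independent of the classifier's prediction;
* localization accuracy (%) — fraction whose predicted label is correct AND
  IoU >= 0.5 (hence never above the GT-known figure).

The 0.5 cutoff is applied inclusively. All percentages are rounded half-up
to 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cam import compute_heatmap
from .classifier import CLASS_INDEX, ModelHandle, predict, preprocess, round2
from .errors import ValidationError
from .quantify import ThresholdConfig, binarize_heatmap

__all__ = [
    "LocalizationResult",
    "GridResult",
    "iou",
    "average_iou",
    "gt_known_loc_acc",
    "loc_acc",
    "evaluate_localization",
    "grid_search",
    "aggregate_by_group",
    "DEFAULT_THRESHOLDS",
]

# the grid-search default follows the tuning protocol: 10%..80% step 10
DEFAULT_THRESHOLDS = (10, 20, 30, 40, 50, 60, 70, 80)


def iou(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    pred = np.asarray(pred_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if pred.shape != truth.shape:
        raise ValidationError("masks must share dimensions")
    if not truth.any():
        raise ValidationError("ground-truth chalk mask must be non-empty")
    union = np.logical_or(pred, truth).sum()
    return float(np.logical_and(pred, truth).sum() / union)


def average_iou(ious: Sequence[float]) -> float:
    if len(ious) == 0:
        raise ValidationError("need at least one IoU value")
    return round2(100.0 * float(np.mean(ious)))


def gt_known_loc_acc(ious: Sequence[float]) -> tuple[float, int, int]:
    """(percent, numerator, denominator): share of grains with IoU >= 0.5."""
    if len(ious) == 0:
        raise ValidationError("need at least one IoU value")
    num = int(sum(1 for v in ious if v >= 0.5))
    return round2(100.0 * num / len(ious)), num, len(ious)


def loc_acc(
    ious: Sequence[float], pred_labels: Sequence[str], true_labels: Sequence[str]
) -> tuple[float, int, int]:
    """Correct label AND IoU >= 0.5; all true labels must be chalky."""
    if not (len(ious) == len(pred_labels) == len(true_labels)) or len(ious) == 0:
        raise ValidationError("ious, pred_labels and true_labels must align and be non-empty")
    if any(t != "chalky" for t in true_labels):
        raise ValidationError("localization accuracy is defined on ground-truth chalky grains")
    num = int(sum(1 for v, p, t in zip(ious, pred_labels, true_labels) if p == t and v >= 0.5))
    return round2(100.0 * num / len(ious)), num, len(ious)


@dataclass
class LocalizationResult:
    ious: list[float]
    avg_iou: float
    gt_known_acc: float
    gt_known_counts: tuple[int, int]
    loc_accuracy: float
    loc_counts: tuple[int, int]
    layer: str
    threshold: float

    def as_dict(self) -> dict:
        return {
            "avg_iou": self.avg_iou,
            "gt_known_loc_acc": self.gt_known_acc,
            "gt_known_counts": list(self.gt_known_counts),
            "loc_acc": self.loc_accuracy,
            "loc_counts": list(self.loc_counts),
            "layer": self.layer,
            "threshold": self.threshold,
            "n": len(self.ious),
        }


@dataclass
class GridResult:
    matrix: pd.DataFrame  # rows: layers, columns: thresholds, values: avg IoU %
    best_layer: str
    best_threshold: float
    ious: dict = field(default_factory=dict)  # (layer, T) -> per-grain IoUs


def _heatmaps_by_layer(handle: ModelHandle, grains, layers, method: str):
    """One heatmap per (grain, layer); heatmaps are reused across thresholds."""
    chalky = CLASS_INDEX["chalky"]
    maps = {layer: [] for layer in layers}
    for grain in grains:
        x = preprocess(np.asarray(getattr(grain, "pixels", grain)), handle.input_size)
        for layer in layers:
            maps[layer].append(compute_heatmap(handle, x, chalky, layer, method))
    return maps


def _truth_in_input_frame(truth_mask: np.ndarray, input_size) -> np.ndarray:
    from .imaging import bilinear_resize

    if truth_mask.shape == tuple(input_size):
        return truth_mask.astype(bool)
    return bilinear_resize(truth_mask.astype(np.float64), tuple(input_size)) >= 0.5


def grid_search(
    handle: ModelHandle,
    grains_with_truth: Sequence[tuple[object, np.ndarray]],
    layers: Sequence[str],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    method: str = "gradcam",
) -> GridResult:
    """Average IoU for every (layer, T) cell on a development set of chalky
    grains with ground-truth chalk masks; the best cell maximizes average
    IoU, ties broken toward the lower layer index, then the lower T."""
    if len(layers) == 0 or len(thresholds) == 0:
        raise ValidationError("layer and threshold grids must be non-empty")
    if len(grains_with_truth) == 0:
        raise ValidationError("grid search needs at least one grain with ground truth")
    grains = [g for g, _ in grains_with_truth]
    truths = [
        _truth_in_input_frame(np.asarray(t), handle.input_size) for _, t in grains_with_truth
    ]
    maps = _heatmaps_by_layer(handle, grains, layers, method)
    matrix = pd.DataFrame(index=list(layers), columns=list(thresholds), dtype=float)
    all_ious: dict = {}
    best = (-1.0, 0, 0)
    for li, layer in enumerate(layers):
        for ti, t in enumerate(thresholds):
            cfg = ThresholdConfig(T=float(t), layer_name=layer)
            ious = [
                iou(binarize_heatmap(hm, cfg), truth)
                for hm, truth in zip(maps[layer], truths)
            ]
            avg = average_iou(ious)
            matrix.iloc[li, ti] = avg
            all_ious[(layer, float(t))] = ious
            if avg > best[0]:
                best = (avg, li, ti)
    return GridResult(
        matrix=matrix,
        best_layer=list(layers)[best[1]],
        best_threshold=float(list(thresholds)[best[2]]),
        ious=all_ious,
    )


def evaluate_localization(
    handle: ModelHandle,
    grains_with_truth: Sequence[tuple[object, np.ndarray]],
    layer: str,
    threshold: float,
    method: str = "gradcam",
) -> LocalizationResult:
    """Full localization evaluation of ground-truth chalky grains at one
    (layer, T): per-grain IoU, average IoU, GT-known and prediction-gated
    localization accuracy."""
    if len(grains_with_truth) == 0:
        raise ValidationError("evaluation needs at least one grain")
    cfg = ThresholdConfig(T=float(threshold), layer_name=layer)
    ious, preds = [], []
    for grain, truth in grains_with_truth:
        pixels = np.asarray(getattr(grain, "pixels", grain))
        label, _ = predict(handle, pixels)
        preds.append(label)
        hm = compute_heatmap(
            handle, preprocess(pixels, handle.input_size), CLASS_INDEX["chalky"], layer, method
        )
        truth_in = _truth_in_input_frame(np.asarray(truth), handle.input_size)
        ious.append(iou(binarize_heatmap(hm, cfg), truth_in))
    gt_pct, gt_num, gt_den = gt_known_loc_acc(ious)
    loc_pct, loc_num, loc_den = loc_acc(ious, preds, ["chalky"] * len(preds))
    return LocalizationResult(
        ious=ious,
        avg_iou=average_iou(ious),
        gt_known_acc=gt_pct,
        gt_known_counts=(gt_num, gt_den),
        loc_accuracy=loc_pct,
        loc_counts=(loc_num, loc_den),
        layer=layer,
        threshold=float(threshold),
    )


def aggregate_by_group(records: pd.DataFrame | list, group_keys: Sequence[str]) -> pd.DataFrame:
    """Per-group mean ± SEM of chalk_area_percent and chalky_score.

    ``records`` is a ChalkRecord list or DataFrame carrying the group keys
    as columns (e.g. genotype, panicle, treatment). SEM = sd / sqrt(n) with
    sample sd (ddof=1); a single-record group reports SEM as NaN. Empty
    groups are never emitted.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.as_row() for r in records])
    for key in group_keys:
        if key not in records.columns:
            raise ValidationError(f"unknown group key {key!r}")
    for col in ("chalk_area_percent", "chalky_score"):
        if col not in records.columns:
            raise ValidationError(f"records are missing the {col!r} column")

    def _sem(v: pd.Series) -> float:
        return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")

    grouped = records.groupby(list(group_keys), dropna=False, sort=True)
    out = grouped.agg(
        n=("chalky_score", "size"),
        chalk_area_percent_mean=("chalk_area_percent", "mean"),
        chalk_area_percent_sem=("chalk_area_percent", _sem),
        chalky_score_mean=("chalky_score", "mean"),
        chalky_score_sem=("chalky_score", _sem),
    ).reset_index()
    return out
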