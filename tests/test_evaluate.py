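"""Localization metrics, grid search, per-group aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

import chalkcam.evaluate as ev
from chalkcam.cam import Heatmap
from chalkcam.errors import ValidationError


class TestIoU:
    def test_published_pixel_counts_reproduce_ratio(self):
        # |intersection| = 5167, |union| = 6370 -> IoU = 5167/6370
        pred = np.zeros(6400, bool)
        truth = np.zeros(6400, bool)
        pred[:5167 + 603] = True          # 5167 shared + 603 pred-only
        truth[:5167] = True
        truth[5167 + 603:6370] = True     # 600 truth-only
        v = ev.iou(pred.reshape(80, 80), truth.reshape(80, 80))
        assert v == pytest.approx(5167 / 6370)
        assert round(v, 4) == 0.8111

    def test_identical_masks(self):
        m = np.random.default_rng(0).random((10, 10)) > 0.5
        m[0, 0] = True
        assert ev.iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert ev.iou(a, b) == 0.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValidationError):
            ev.iou(np.ones((3, 3), bool), np.zeros((3, 3), bool))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((8, 8)) > 0.5
        b = rng.random((8, 8)) > 0.5
        a[0, 0] = b[0, 0] = True  # both non-empty
        assert ev.iou(a, b) == ev.iou(b, a)


class TestAggregateMetrics:
    def test_average_iou_examples(self):
        assert ev.average_iou([1.0]) == 100.0
        assert ev.average_iou([0.5, 0.7]) == 60.0

    def test_average_matches_summation_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.random(166)
        total = 0.0
        for v in vals:
            total += v
        assert abs(ev.average_iou(vals) - round(100 * total / 166, 2)) <= 1e-9 + 0.005

    def test_gt_known_140_of_166(self):
        ious = [0.7] * 140 + [0.2] * 26
        pct, num, den = ev.gt_known_loc_acc(ious)
        assert (pct, num, den) == (84.34, 140, 166)

    def test_gt_known_inclusive_at_half(self):
        pct, num, den = ev.gt_known_loc_acc([0.6, 0.5, 0.49, 0.2])
        assert (pct, num, den) == (50.0, 2, 4)

    def test_all_perfect(self):
        assert ev.gt_known_loc_acc([1.0] * 7)[0] == 100.0

    def test_loc_acc_138_of_166(self):
        ious = [0.9] * 140 + [0.1] * 26
        preds = ["chalky"] * 138 + ["non-chalky"] * 2 + ["chalky"] * 26
        pct, num, den = ev.loc_acc(ious, preds, ["chalky"] * 166)
        assert (pct, num, den) == (83.13, 138, 166)

    def test_all_labels_wrong_gives_zero(self):
        pct, num, _ = ev.loc_acc([1.0, 1.0], ["non-chalky"] * 2, ["chalky"] * 2)
        assert (pct, num) == (0.0, 0)

    def test_all_labels_correct_reduces_to_gt_known(self):
        ious = [0.9, 0.4, 0.55, 0.2]
        assert ev.loc_acc(ious, ["chalky"] * 4, ["chalky"] * 4)[0] == ev.gt_known_loc_acc(ious)[0]

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=40),
        st.integers(0, 2**31 - 1),
    )
    def test_loc_acc_never_exceeds_gt_known(self, ious, seed):
        rng = np.random.default_rng(seed)
        preds = [["chalky", "non-chalky"][i] for i in rng.integers(0, 2, len(ious))]
        gt = ev.gt_known_loc_acc(ious)[0]
        loc = ev.loc_acc(ious, preds, ["chalky"] * len(ious))[0]
        assert loc <= gt


class FakeHandle:
    input_size = (64, 64)


def _fake_grain_and_truth():
    truth = np.zeros((64, 64), bool)
    truth[20:36, 24:44] = True
    pixels = np.where(truth[..., None], 255, 0).astype(np.uint8).repeat(3, axis=2)
    grain = type("G", (), {"pixels": pixels})()
    return grain, truth


def _fake_compute_heatmap(handle, x, class_index, layer, method="gradcam"):
    # recover the truth region from the preprocessed input itself
    truth = np.asarray(x)[0] > 0
    if layer == "goodlayer":
        band = ndimage.binary_dilation(truth, iterations=8) & ~truth
        final = np.where(truth, 1.0, np.where(band, 0.4, 0.0))
    else:  # mediocre layer: uniformly confident everywhere
        final = np.ones(truth.shape)
    return Heatmap(raw=final, final=final, layer_name=layer, class_index=class_index, method=method)


class TestGridSearch:
    def test_single_cell_grid_is_best(self, monkeypatch):
        monkeypatch.setattr(ev, "compute_heatmap", _fake_compute_heatmap)
        grain, truth = _fake_grain_and_truth()
        res = ev.grid_search(FakeHandle(), [(grain, truth)], ["goodlayer"], [50])
        assert res.best_layer == "goodlayer"
        assert res.best_threshold == 50.0
        assert res.matrix.shape == (1, 1)

    def test_dominant_cell_selected_and_matrix_shape(self, monkeypatch):
        monkeypatch.setattr(ev, "compute_heatmap", _fake_compute_heatmap)
        grain, truth = _fake_grain_and_truth()
        res = ev.grid_search(
            FakeHandle(), [(grain, truth)], ["goodlayer", "badlayer"], [20, 50, 80]
        )
        assert res.matrix.shape == (2, 3)
        # T bracketing the band level: at T=50 the mask is exactly the truth
        assert res.matrix.loc["goodlayer", 50] == 100.0
        assert res.best_layer == "goodlayer"
        assert res.best_threshold == 50.0  # tie with T=80 broken toward lower T
        assert res.matrix.values.max() == res.matrix.loc[res.best_layer, res.best_threshold]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            ev.grid_search(FakeHandle(), [], ["block1"], [50])


class TestAggregateByGroup:
    @staticmethod
    def _df():
        return pd.DataFrame(
            {
                "genotype": ["A", "A", "A", "B"],
                "treatment": ["HNT", "HNT", "HNT", "CNT"],
                "chalk_area_percent": [10.0, 20.0, 30.0, 5.0],
                "chalky_score": [0.1, 0.2, 0.3, 0.05],
            }
        )

    def test_mean_and_sem_hand_formula(self):
        out = ev.aggregate_by_group(self._df(), ["genotype", "treatment"])
        row = out[(out["genotype"] == "A")].iloc[0]
        assert row["chalk_area_percent_mean"] == pytest.approx(20.0)
        assert row["chalk_area_percent_sem"] == pytest.approx(10.0 / np.sqrt(3))
        assert row["n"] == 3

    def test_single_record_group_has_nan_sem(self):
        out = ev.aggregate_by_group(self._df(), ["genotype"])
        row = out[out["genotype"] == "B"].iloc[0]
        assert row["n"] == 1
        assert np.isnan(row["chalk_area_percent_sem"])

    def test_no_empty_groups_emitted(self):
        out = ev.aggregate_by_group(self._df(), ["genotype", "treatment"])
        assert (out["n"] >= 1).all()
        assert len(out) == 2

    def test_unknown_key_rejected(self):
        with pytest.raises(ValidationError):
            ev.aggregate_by_group(self._df(), ["panicle"])
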