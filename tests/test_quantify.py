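"""Heatmap binarization, ChalkyScore and chalk-area arithmetic."""

import numpy as np
import pytest

from chalkcam import classifier as clf
from chalkcam.cropper import GrainMask
from chalkcam.errors import ValidationError
from chalkcam.quantify import (
    ThresholdConfig,
    binarize_heatmap,
    chalk_area_percent,
    chalk_score,
    quantify_batch,
)
from chalkcam.synthetic import GrainSpec, generate_grain


def _grain_mask(h=10, w=10, n_fg=None):
    mask = np.zeros((h, w), bool)
    if n_fg is None:
        mask[:] = True
    else:
        mask.flat[:n_fg] = True
    return GrainMask(mask=mask, Z=int(mask.sum()))


class TestBinarize:
    def test_inclusive_threshold_selection(self):
        hm = np.array([[10.0, 6.0], [5.9, 0.0]])
        mask = binarize_heatmap(hm, ThresholdConfig(T=60))
        assert mask.tolist() == [[True, True], [False, False]]

    def test_all_zero_heatmap_gives_empty_mask(self):
        assert not binarize_heatmap(np.zeros((4, 4)), ThresholdConfig(T=20)).any()

    def test_matches_per_pixel_comparison_loop(self):
        rng = np.random.default_rng(11)
        hm = rng.random((16, 16))
        mask = binarize_heatmap(hm, ThresholdConfig(T=60))
        cut = 0.6 * hm.max()
        for i in range(16):
            for j in range(16):
                assert mask[i, j] == (hm[i, j] >= cut)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValidationError):
            binarize_heatmap(np.ones((2, 2)), ThresholdConfig(T=0))


class TestChalkScore:
    def test_zero_heatmap_scores_zero(self):
        assert chalk_score(np.zeros((10, 10)), _grain_mask()) == 0.0

    def test_saturated_heatmap_scores_one(self):
        assert chalk_score(np.full((10, 10), 7.5), _grain_mask()) == pytest.approx(1.0)

    def test_half_grain_at_half_intensity_scores_quarter(self):
        gm = _grain_mask(10, 10, n_fg=100)
        hm = np.zeros((10, 10))
        hm.flat[:50] = 0.5
        # per-image max of 1.0 sits outside the grain-foreground window
        gm.mask.flat[-1] = False
        gm2 = GrainMask(mask=gm.mask, Z=int(gm.mask.sum()))
        hm.flat[-1] = 1.0
        expected = (50 * 0.5) / gm2.Z
        assert chalk_score(hm, gm2) == pytest.approx(expected)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            chalk_score(np.zeros((4, 4)), _grain_mask(5, 5))

    def test_scaling_invariance_and_range(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            hm = rng.random((12, 12)) * rng.uniform(0.1, 50)
            mask = rng.random((12, 12)) > 0.4
            if not mask.any():
                mask[0, 0] = True
            gm = GrainMask(mask=mask, Z=int(mask.sum()))
            s = chalk_score(hm, gm)
            assert 0.0 <= s <= 1.0
            assert chalk_score(512.0 * hm, gm) == s  # power-of-two scale: exact

    def test_raising_subpeak_grain_values_never_decreases_score(self):
        rng = np.random.default_rng(13)
        hm = rng.random((12, 12))
        hm[0, 0] = 2.0  # fixed per-image maximum
        mask = rng.random((12, 12)) > 0.5
        mask[0, 0] = False
        gm = GrainMask(mask=mask, Z=int(mask.sum()))
        base = chalk_score(hm, gm)
        bumped = hm.copy()
        sel = mask & (bumped < 1.5)
        bumped[sel] += 0.3
        assert chalk_score(bumped, gm) >= base


class TestChalkArea:
    def test_mask_equal_to_grain_is_100(self):
        gm = _grain_mask()
        assert chalk_area_percent(gm.mask, gm) == 100.0

    def test_empty_mask_is_0(self):
        gm = _grain_mask()
        assert chalk_area_percent(np.zeros_like(gm.mask), gm) == 0.0

    def test_pixel_count_oracle(self):
        gm = _grain_mask(40, 25)  # Z = 1000
        mask = np.zeros((40, 25), bool)
        mask.flat[:250] = True
        assert chalk_area_percent(mask, gm) == 25.0

    def test_threshold_nesting(self):
        rng = np.random.default_rng(14)
        hm = rng.random((16, 16))
        m20 = binarize_heatmap(hm, ThresholdConfig(T=20))
        m40 = binarize_heatmap(hm, ThresholdConfig(T=40))
        m80 = binarize_heatmap(hm, ThresholdConfig(T=80))
        assert not (m80 & ~m40).any()
        assert not (m40 & ~m20).any()


class TestQuantifyBatch:
    @staticmethod
    def _always_non_chalky_handle():
        handle = clf.build_backbone("tiny", seed=0)
        fc = handle.net.layers[-1]
        fc.w[...] = 0.0
        fc.b[...] = np.array([1.0, 0.0], np.float32)
        return handle

    def test_gated_non_chalky_grain_gets_zero_record(self):
        handle = self._always_non_chalky_handle()
        img, _ = generate_grain(GrainSpec(rng_seed=1))
        records = quantify_batch(handle, [img], gate_on_prediction=True)
        r = records[0]
        assert r.label == "non-chalky"
        assert r.chalky_score == 0.0
        assert r.chalk_area_percent == 0.0
        assert not r.mask.any()

    def test_one_record_per_grain(self, trained_model):
        grains = [generate_grain(GrainSpec(rng_seed=s))[0] for s in range(4)]
        records = quantify_batch(trained_model.handle, grains)
        assert len(records) == 4
        assert len({r.grain_id for r in records}) == 4

    def test_larger_blobs_score_higher_on_average(self, trained_model):
        rng = np.random.default_rng(15)
        scores = {}
        for frac in (0.1, 0.5):
            grains = [
                generate_grain(
                    GrainSpec(chalk_present=True, chalk_fraction=frac,
                              rng_seed=int(rng.integers(0, 2**31 - 1)))
                )[0]
                for _ in range(50)
            ]
            records = quantify_batch(
                trained_model.handle, grains, gate_on_prediction=False
            )
            scores[frac] = np.mean([r.chalky_score for r in records])
        assert scores[0.5] > scores[0.1]
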