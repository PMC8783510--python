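"""CAM engine: gradient oracles, toy reductions, output contracts."""

import numpy as np
import pytest
from scipy import ndimage

from chalkcam import classifier as clf
from chalkcam.cam import (
    CAM_METHODS,
    compute_heatmap,
    finite_difference_weights,
    gradcam_heatmap,
    gradcam_weights,
    gradcampp_heatmap,
    scorecam_heatmap,
    scorecam_weights,
)
from chalkcam.errors import ConfigurationError, ValidationError
from chalkcam.imaging import bilinear_resize
from conftest import make_chalky_grain

CHALKY = 1


def _rand_image(seed=0, size=64):
    return np.random.default_rng(seed).random((3, size, size)).astype(np.float32)


def _sum_logit_handle():
    """Head surgery so that y^chalky = sum over block3 map 0: the chalky
    logit is N * GAP of channel 0, hence dy/df^0_ij = 1 everywhere and the
    other maps have no path to the logit."""
    handle = clf.build_backbone("tiny", seed=3)
    fc = handle.net.layers[-1]
    n = 8 * 8  # block3 spatial positions
    fc.w[...] = 0.0
    fc.b[...] = 0.0
    fc.w[CHALKY, 0] = n
    return handle


class TestGradcamWeights:
    def test_gradient_of_a_sum_is_one(self):
        handle = _sum_logit_handle()
        w = gradcam_weights(handle, _rand_image(1), CHALKY, "block3").w
        assert w[0] == pytest.approx(1.0, abs=1e-5)

    def test_map_without_path_to_logit_gets_zero_weight(self):
        handle = _sum_logit_handle()
        w = gradcam_weights(handle, _rand_image(1), CHALKY, "block3").w
        assert np.all(w[1:] == 0.0)

    def test_matches_finite_differences_on_small_model(self):
        handle = clf.build_backbone("tiny", input_size=(32, 32), seed=9)
        x = _rand_image(4, size=32)
        for layer in handle.layer_names:
            w = gradcam_weights(handle, x, CHALKY, layer).w
            fd = finite_difference_weights(handle, x, CHALKY, layer)
            assert np.abs(w - fd).max() <= 1e-3

    def test_unknown_layer_rejected(self, untrained_handle):
        with pytest.raises(ConfigurationError):
            gradcam_weights(untrained_handle, _rand_image(), CHALKY, "block9")


class TestGradcamHeatmap:
    def test_everywhere_negative_sum_gives_zero_heatmap(self):
        handle = _sum_logit_handle()
        handle.net.layers[-1].w[CHALKY, 0] = -64.0  # w^c_0 = -1, features >= 0
        hm = gradcam_heatmap(handle, _rand_image(2), CHALKY, "block3")
        assert np.all(hm.raw == 0.0)
        assert np.all(hm.final == 0.0)

    def test_logit_scaling_scales_raw_heatmap_exactly(self, untrained_handle):
        x = _rand_image(5)
        hm1 = gradcam_heatmap(untrained_handle, x, CHALKY, "block2")
        fc = untrained_handle.net.layers[-1]
        fc.w *= 4.0
        fc.b *= 4.0
        hm2 = gradcam_heatmap(untrained_handle, x, CHALKY, "block2")
        assert np.array_equal(hm2.raw, 4.0 * hm1.raw)

    def test_bilinear_upsample_matches_closed_form(self):
        raw = np.array([[0.0, 0.0], [0.0, 4.0]])
        up = bilinear_resize(raw, (4, 4))
        # corner-aligned sampling positions are 0, 1/3, 2/3, 1
        t = np.array([0.0, 1 / 3, 2 / 3, 1.0])
        expected = 4.0 * np.outer(t, t)
        assert up[-1, -1] == 4.0
        assert np.allclose(up, expected)


class TestGradcamPP:
    def test_single_map_uniform_gradient_reduces_to_feature_map(self):
        handle = _sum_logit_handle()
        x = _rand_image(6)
        pp = gradcampp_heatmap(handle, x, CHALKY, "block3")
        gc = gradcam_heatmap(handle, x, CHALKY, "block3")
        # both are a positive multiple of f^0: same argmax, proportional
        assert pp.raw.argmax() == gc.raw.argmax()
        scale = pp.raw.max() / gc.raw.max()
        assert np.allclose(pp.raw, scale * gc.raw, atol=1e-9)

    def test_zero_gradients_give_zero_heatmap(self, untrained_handle):
        fc = untrained_handle.net.layers[-1]
        fc.w[CHALKY, :] = 0.0
        fc.b[CHALKY] = 0.0
        hm = gradcampp_heatmap(untrained_handle, _rand_image(7), CHALKY, "block2")
        assert np.all(hm.raw == 0.0)


class TestScorecam:
    def test_input_blind_model_weights_all_valid_maps_equally(self, untrained_handle):
        fc = untrained_handle.net.layers[-1]
        fc.w[...] = 0.0
        fc.b[...] = np.array([0.3, 0.7], np.float32)
        weights, _ = scorecam_weights(untrained_handle, _rand_image(8), CHALKY, "block2")
        nz = weights[weights > 0]
        assert len(nz) >= 1
        assert np.allclose(nz, nz[0])
        assert nz.sum() == pytest.approx(1.0)

    def test_constant_activation_map_gets_zero_weight(self, untrained_handle):
        conv3 = untrained_handle.net.layers[6]
        conv3.w[0, :] = 0.0
        conv3.b[0] = 5.0  # block3 map 0 becomes constant
        weights, feats = scorecam_weights(untrained_handle, _rand_image(9), CHALKY, "block3")
        assert np.all(feats[0] == feats[0].flat[0])
        assert weights[0] == 0.0

    def test_argmax_lands_in_dilated_truth_chalk_region(self, trained_model):
        img, truth = make_chalky_grain(seed=33, chalk_fraction=0.4)
        handle = trained_model.handle
        truth64 = bilinear_resize(truth.chalk_mask.astype(float), handle.input_size) >= 0.5
        region = ndimage.binary_dilation(truth64, iterations=4)
        for method in ("scorecam", "gradcam"):
            hm = compute_heatmap(handle, img, CHALKY, "block2", method)
            i, j = np.unravel_index(hm.final.argmax(), hm.final.shape)
            assert region[i, j], f"{method} argmax outside dilated chalk truth"


class TestContracts:
    @pytest.mark.parametrize("method", sorted(CAM_METHODS))
    def test_nonnegative_and_input_resolution(self, untrained_handle, method):
        x = _rand_image(10)
        for layer in untrained_handle.layer_names:
            hm = CAM_METHODS[method](untrained_handle, x, CHALKY, layer)
            assert hm.final.shape == untrained_handle.input_size
            assert hm.raw.min() >= 0.0
            assert hm.final.min() >= 0.0

    def test_unknown_method_rejected(self, untrained_handle):
        with pytest.raises(ValidationError):
            compute_heatmap(untrained_handle, _rand_image(), CHALKY, "block1", "occlusion")
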