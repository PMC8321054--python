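"""GCAM computation and ROI placement/cropping."""

import numpy as np
import pytest

from locseg3d import (
    DensityMap,
    LabelVolume,
    NoLocalizationError,
    ROIBox,
    Volume,
    crop,
    density_to_roi,
    derive_crop_shape,
    dsc,
    gcam,
    uncrop,
)
from locseg3d.nn import Tensor


class TestGcam:
    def test_unit_gradient_reduces_to_relu_of_features(self, rng):
        x = Tensor(rng.normal(size=(1, 6, 6, 6)), requires_grad=True)
        out = gcam(x, lambda f: f.sum())
        assert np.allclose(out, np.maximum(x.data[0], 0.0), atol=1e-6)

    def test_linear_score_closed_form(self, rng):
        """S = a*sum(x1) + b*sum(x2) gives GCAM = ReLU(a*x1 + b*x2)."""
        a, b = 2.5, -1.25
        x = Tensor(rng.normal(size=(2, 5, 5, 5)), requires_grad=True)
        out = gcam(x, lambda f: a * f[0].sum() + b * f[1].sum())
        expected = np.maximum(a * x.data[0] + b * x.data[1], 0.0)
        assert np.allclose(out, expected, atol=1e-6)

    def test_constant_score_gives_zero_map(self, rng):
        x = Tensor(rng.normal(size=(3, 4, 4, 4)), requires_grad=True)
        out = gcam(x, lambda f: (f * 0.0).sum())
        assert np.allclose(out, 0.0)

    def test_gradient_free_features_rejected(self, rng):
        x = Tensor(rng.normal(size=(1, 4, 4, 4)))
        with pytest.raises(ValueError, match="gradient"):
            gcam(x, lambda f: f.sum())

    def test_nonnegativity_property_over_random_draws(self, rng):
        for _ in range(100):
            x = Tensor(rng.normal(size=(2, 3, 3, 3)), requires_grad=True)
            w = rng.normal(size=2)
            out = gcam(x, lambda f: w[0] * f[0].sum() + w[1] * f[1].sum())
            assert (out >= 0).all()


class TestDensityToRoi:
    def test_single_peak_centred_box(self):
        d = np.zeros((16, 32, 32), dtype=np.float32)
        d[4, 10, 12] = 1.0
        box = density_to_roi(DensityMap(d, (16, 32, 32)), (8, 16, 16))
        assert box.start == (0, 2, 4)

    def test_peak_near_corner_clips_to_zero(self):
        d = np.zeros((16, 32, 32), dtype=np.float32)
        d[1, 1, 1] = 1.0
        box = density_to_roi(DensityMap(d, (16, 32, 32)), (8, 16, 16))
        assert box.start == (0, 0, 0)

    def test_uniform_density_centres_box(self):
        d = np.ones((16, 32, 32), dtype=np.float32)
        box = density_to_roi(DensityMap(d, (16, 32, 32)), (8, 16, 16))
        assert box.start == (4, 8, 8)

    def test_low_resolution_map_rescaled_to_full_coordinates(self):
        # peak at low-res (2, 2, 2) in an 8^3 map over a 32^3 volume
        d = np.zeros((8, 8, 8), dtype=np.float32)
        d[2, 2, 2] = 1.0
        box = density_to_roi(DensityMap(d, (32, 32, 32)), (16, 16, 16))
        # low-res voxel centre 2.5 maps to full-res 9.5 -> start round(9.5-8)=2
        assert box.start == (2, 2, 2)

    def test_all_zero_density_raises(self):
        with pytest.raises(NoLocalizationError):
            density_to_roi(DensityMap(np.zeros((4, 4, 4)), (4, 4, 4)), (2, 2, 2))

    def test_crop_larger_than_volume_covers_axis(self):
        d = np.ones((4, 8, 8), dtype=np.float32)
        box = density_to_roi(DensityMap(d, (4, 8, 8)), (8, 4, 4))
        assert box.start[0] == 0 and box.shape[0] == 4


class TestCropUncrop:
    def test_whole_volume_box_is_identity(self, rng):
        v = Volume(rng.random((4, 6, 6)))
        box = ROIBox((0, 0, 0), (4, 6, 6))
        assert np.array_equal(crop(v, box).data, v.data)

    def test_mask_round_trip_and_voxel_conservation(self, rng):
        data = (rng.random((8, 12, 12)) < 0.2).astype(np.int16)
        lv = LabelVolume(data)
        box = ROIBox((2, 3, 1), (4, 8, 8))
        back = uncrop(crop(lv, box), box, lv.shape)
        inside = np.zeros_like(data)
        inside[box.slices()] = data[box.slices()]
        assert np.array_equal(back.data, inside)
        assert back.data.sum() == inside.sum()

    def test_structure_inside_box_survives_exactly(self):
        data = np.zeros((8, 16, 16), dtype=np.int16)
        data[3:5, 6:10, 6:10] = 1
        lv = LabelVolume(data)
        box = ROIBox((2, 4, 4), (4, 8, 8))
        back = uncrop(crop(lv, box), box, lv.shape)
        assert dsc(back.data > 0, data > 0) == 1.0

    def test_out_of_bounds_box_rejected(self, rng):
        v = Volume(rng.random((4, 4, 4)))
        with pytest.raises(ValueError):
            crop(v, ROIBox((2, 0, 0), (4, 4, 4)))

    def test_uncrop_shape_mismatch_rejected(self):
        seg = np.zeros((2, 2, 2), dtype=np.int16)
        with pytest.raises(ValueError, match="shape"):
            uncrop(seg, ROIBox((0, 0, 0), (2, 2, 3)), (4, 4, 4))

    def test_all_background_uncrop(self):
        seg = np.zeros((2, 2, 2), dtype=np.int16)
        out = uncrop(seg, ROIBox((1, 1, 1), (2, 2, 2)), (4, 4, 4))
        assert out.sum() == 0


class TestDeriveCropShape:
    def test_margin_and_divisibility(self):
        data = np.zeros((16, 64, 64), dtype=np.int16)
        data[4:10, 20:40, 22:40] = 1  # extents (6, 20, 18)
        shape = derive_crop_shape([LabelVolume(data)], margin=10, divisors=(8, 8, 8))
        assert shape == (16, 32, 32)  # (16, 30, 28) rounded up to multiples of 8

    def test_clipped_to_volume_extent(self):
        data = np.zeros((8, 16, 16), dtype=np.int16)
        data[1:7, 2:15, 2:15] = 1
        shape = derive_crop_shape([LabelVolume(data)], margin=10, divisors=(8, 8, 8))
        assert shape == (8, 16, 16)

    def test_perfect_density_box_contains_structure(self, blob_cases):
        """An oracle localizer (density = ground truth) yields a crop that
        contains every foreground voxel when the crop size fits."""
        labels = [lv for _, lv in blob_cases]
        shape = derive_crop_shape(labels, margin=10, divisors=(8, 8, 8))
        for lv in labels:
            fg = (np.asarray(lv.data) > 0).astype(np.float32)
            box = density_to_roi(DensityMap(fg, lv.shape), shape)
            inside = fg[box.slices()].sum()
            assert inside == fg.sum()
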