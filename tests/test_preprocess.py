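"""Preprocessing chain: CLAHE, normalization, resampling, pad/crop, downsampling."""

import numpy as np
import pytest
from skimage import exposure

from locseg3d import (
    LabelVolume,
    Volume,
    clahe_slicewise,
    downsample_for_localizer,
    pad_or_crop,
    resample_to_spacing,
    znormalize,
)


class TestClahe:
    def test_constant_volume_unchanged(self):
        v = Volume(np.full((4, 16, 16), 0.3, dtype=np.float32))
        out = clahe_slicewise(v)
        assert np.array_equal(out.data, v.data)

    def test_matches_per_slice_reference_loop(self, rng):
        data = rng.random((5, 64, 64)).astype(np.float32)
        v = Volume(data)
        out = clahe_slicewise(v, clip_limit=0.03, tiles=(8, 8))
        for z in range(5):
            sl = data[z]
            lo, hi = sl.min(), sl.max()
            ref = exposure.equalize_adapthist(
                (sl - lo) / (hi - lo), kernel_size=(8, 8), clip_limit=0.03
            )
            assert np.allclose(out.data[z], ref * (hi - lo) + lo, atol=1e-5)

    def test_shape_and_spacing_preserved(self, rng):
        v = Volume(rng.random((9, 64, 64)), spacing=(8.0, 1.4, 1.4))
        out = clahe_slicewise(v)
        assert out.shape == (9, 64, 64)
        assert out.spacing == v.spacing


class TestZNormalize:
    def test_zero_mean_unit_std(self, rng):
        out = znormalize(Volume(rng.normal(5.0, 3.0, (6, 8, 8))))
        assert abs(float(out.data.mean())) < 1e-5
        assert abs(float(out.data.std()) - 1.0) < 1e-5

    def test_constant_maps_to_zeros(self):
        out = znormalize(Volume(np.full((4, 4, 4), 9.0)))
        assert np.array_equal(out.data, np.zeros((4, 4, 4), dtype=np.float32))

    def test_affine_invariance(self, rng):
        data = rng.normal(size=(5, 7, 7))
        a = znormalize(Volume(data))
        b = znormalize(Volume(3.5 * data + 11.0))
        assert np.allclose(a.data, b.data, atol=1e-5)


class TestResample:
    def test_output_shape_from_spacing_ratio(self, rng):
        v = Volume(rng.random((9, 224, 224)), spacing=(10.0, 1.37, 1.37))
        out = resample_to_spacing(v, (10.0, 1.25, 1.25))
        # 224 * 1.37 / 1.25 = 245.5 -> 246
        assert out.shape == (9, 246, 246)
        assert out.spacing == (10.0, 1.25, 1.25)

    def test_identity_for_own_spacing_nearest(self, rng):
        lv = LabelVolume(
            rng.integers(0, 2, (4, 6, 6)).astype(np.int16), spacing=(2.0, 1.0, 1.0)
        )
        out = resample_to_spacing(lv, (2.0, 1.0, 1.0))
        assert np.array_equal(out.data, lv.data)

    def test_nearest_preserves_label_value_set(self, rng):
        lv = LabelVolume(
            rng.integers(0, 4, (6, 20, 20)).astype(np.int16),
            spacing=(5.0, 1.37, 1.37),
            class_names=["a", "b", "c"],
        )
        out = resample_to_spacing(lv, (5.0, 1.25, 1.25))
        assert set(np.unique(out.data)) <= set(np.unique(lv.data))

    def test_bad_target_spacing_errors(self, rng):
        v = Volume(rng.random((4, 4, 4)))
        with pytest.raises(ValueError):
            resample_to_spacing(v, (0.0, 1.0, 1.0))


class TestPadOrCrop:
    def test_pad_amounts_high_side_gets_remainder(self, rng):
        v = Volume(rng.random((9, 246, 246)))
        out, rec = pad_or_crop(v, (16, 256, 256))
        assert out.shape == (16, 256, 256)
        assert rec.pad_low == (3, 5, 5)  # (16-9)=7 -> 3 low / 4 high
        # content placed at the recorded offset
        assert np.allclose(out.data[3:12, 5:251, 5:251], v.data)

    def test_identity_when_target_equals_shape(self, rng):
        v = Volume(rng.random((4, 6, 6)))
        out, rec = pad_or_crop(v, (4, 6, 6))
        assert np.array_equal(out.data, v.data)
        assert np.array_equal(rec.restore(out.data), v.data)

    @pytest.mark.parametrize("target", [(16, 40, 40), (4, 20, 20), (8, 40, 20)])
    def test_round_trip_restores_geometry(self, rng, target):
        data = rng.random((8, 30, 30)).astype(np.float32)
        v = Volume(data)
        out, rec = pad_or_crop(v, target)
        restored = rec.restore(out.data)
        assert restored.shape == data.shape
        # padded axes restore exactly; cropped axes restore the kept window
        keep = tuple(
            slice(c, c + min(t, n))
            for c, t, n in zip(rec.crop_low, target, data.shape)
        )
        assert np.array_equal(restored[keep], data[keep])


class TestDownsample:
    def test_shapes_and_keep_z(self, rng):
        v = Volume(rng.random((16, 256, 256)))
        out = downsample_for_localizer(v, (2, 4, 4), keep_z=True)
        assert out.shape == (16, 64, 64)  # z factor forced to 1
        out2 = downsample_for_localizer(v, (2, 4, 4), keep_z=False)
        assert out2.shape == (8, 64, 64)

    def test_identity_factor(self, rng):
        v = Volume(rng.random((4, 8, 8)))
        out = downsample_for_localizer(v, (1, 1, 1))
        assert np.allclose(out.data, v.data)

    def test_label_value_subset_and_spacing(self, rng):
        lv = LabelVolume(
            rng.integers(0, 3, (6, 16, 16)).astype(np.int16),
            spacing=(8.0, 1.0, 1.0),
            class_names=["a", "b"],
        )
        out = downsample_for_localizer(lv, (1, 4, 4))
        assert out.shape == (6, 4, 4)
        assert set(np.unique(out.data)) <= set(np.unique(lv.data))
        assert out.spacing == (8.0, 4.0, 4.0)

    def test_zero_factor_errors(self, rng):
        with pytest.raises(ValueError):
            downsample_for_localizer(Volume(rng.random((4, 4, 4))), (0, 1, 1))


def test_chain_is_deterministic(rng):
    data = rng.random((6, 40, 40)).astype(np.float32)

    def run():
        v = Volume(data.copy(), spacing=(8.0, 1.4, 1.4))
        v = clahe_slicewise(v)
        v = znormalize(v)
        v = resample_to_spacing(v, (8.0, 1.25, 1.25))
        v, _ = pad_or_crop(v, (8, 48, 48))
        return v.data

    assert np.array_equal(run(), run())
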