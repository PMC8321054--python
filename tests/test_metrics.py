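"""Evaluation metrics vs brute-force oracles, and agreement analysis."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from locseg3d import (
    LabelVolume,
    asd,
    bland_altman,
    boundary_voxels,
    dsc,
    evaluate_cases,
    hausdorff,
)
from scipy import ndimage


# ---------------------------------------------------------------------------
# O(N^2) all-pairs oracles
# ---------------------------------------------------------------------------


def _boundary_coords(mask, spacing):
    b = boundary_voxels(mask)
    return np.argwhere(b) * np.asarray(spacing)


def oracle_distances(g, p, spacing):
    cg = _boundary_coords(g, spacing)
    cp = _boundary_coords(p, spacing)
    d = cdist(cg, cp)
    d_gp = d.min(axis=1)  # per G-boundary voxel
    d_pg = d.min(axis=0)
    return d_gp, d_pg


def oracle_hd(g, p, spacing, mode):
    d_gp, d_pg = oracle_distances(g, p, spacing)
    return d_gp.max() if mode == "directed" else max(d_gp.max(), d_pg.max())


def oracle_asd(g, p, spacing):
    d_gp, d_pg = oracle_distances(g, p, spacing)
    return (d_gp.sum() + d_pg.sum()) / (d_gp.size + d_pg.size)


def _random_mask(rng, shape=(12, 12, 12)):
    m = rng.random(shape) < 0.12
    if not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return m


# ---------------------------------------------------------------------------


class TestBoundary:
    def test_single_voxel_is_its_own_boundary(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        assert np.array_equal(boundary_voxels(m), m)

    def test_solid_cube_has_26_boundary_voxels(self):
        m = np.zeros((7, 7, 7), dtype=bool)
        m[2:5, 2:5, 2:5] = True
        assert boundary_voxels(m).sum() == 26  # 27 minus the centre

    def test_full_grid_boundary_is_the_border_shell(self):
        m = np.ones((4, 5, 6), dtype=bool)
        b = boundary_voxels(m)
        interior = np.zeros_like(m)
        interior[1:-1, 1:-1, 1:-1] = True
        assert np.array_equal(b, m & ~interior)

    def test_empty_mask(self):
        assert boundary_voxels(np.zeros((3, 3, 3), dtype=bool)).sum() == 0


class TestDsc:
    def test_identical_masks(self, rng):
        m = _random_mask(rng)
        assert dsc(m, m) == 1.0

    def test_half_overlap_counts(self):
        g = np.zeros((4, 4, 4), dtype=bool)
        p = np.zeros((4, 4, 4), dtype=bool)
        g[0, 0, :2] = g[0, 1, :2] = g[1, 0, :2] = g[1, 1, :2] = True  # 8 voxels
        p[0, 0, :2] = p[0, 1, :2] = p[2, 2, :2] = p[2, 3, :2] = True  # 8, overlap 4
        assert dsc(g, p) == pytest.approx(0.5)

    def test_confusion_count_form(self):
        # TP=4, FP=2, FN=2 -> 2*4 / (2 + 8 + 2)
        g = np.zeros((3, 3, 3), dtype=bool)
        p = np.zeros((3, 3, 3), dtype=bool)
        g.ravel()[:6] = True  # |G| = 6 = TP + FN
        p.ravel()[2:8] = True  # |P| = 6 = TP + FP, overlap 4
        assert dsc(g, p) == pytest.approx(2 * 4 / (2 + 8 + 2))

    def test_both_empty_is_one_and_symmetry(self, rng):
        z = np.zeros((3, 3, 3), dtype=bool)
        assert dsc(z, z) == 1.0
        g, p = _random_mask(rng), _random_mask(rng)
        assert dsc(g, p) == dsc(p, g)


class TestSurfaceDistances:
    def test_identical_masks_are_zero(self, rng):
        m = _random_mask(rng)
        assert hausdorff(m, m) == 0.0
        assert asd(m, m) == 0.0

    def test_two_voxels_isotropic(self):
        g = np.zeros((8, 8, 8), dtype=bool)
        p = np.zeros((8, 8, 8), dtype=bool)
        g[1, 4, 4] = True
        p[4, 4, 4] = True
        for mode in ("directed", "symmetric"):
            assert hausdorff(g, p, (1, 1, 1), mode=mode) == pytest.approx(3.0)

    def test_in_plane_offset_uses_spacing(self):
        g = np.zeros((4, 12, 12), dtype=bool)
        p = np.zeros((4, 12, 12), dtype=bool)
        g[2, 6, 2] = True
        p[2, 6, 6] = True  # 4 voxels apart along x at 1.25 mm
        assert hausdorff(g, p, (10.0, 1.25, 1.25)) == pytest.approx(5.0)

    def test_parallel_plates_asd(self):
        g = np.zeros((8, 6, 6), dtype=bool)
        p = np.zeros((8, 6, 6), dtype=bool)
        g[2] = True
        p[4] = True  # plates 2 slices apart at 1 mm spacing
        assert asd(g, p, (1.0, 1.0, 1.0)) == pytest.approx(2.0)

    def test_empty_mask_rejected(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        n = m.copy()
        n[1, 1, 1] = True
        with pytest.raises(ValueError):
            hausdorff(m, n)
        with pytest.raises(ValueError):
            asd(n, m)

    def test_directed_mode_is_asymmetric(self):
        g = np.zeros((6, 6, 6), dtype=bool)
        p = np.zeros((6, 6, 6), dtype=bool)
        g[2, 2, 2] = True  # single voxel inside p's plate
        p[2] = True
        assert hausdorff(g, p, mode="directed") == 0.0
        assert hausdorff(p, g, mode="directed") > 0.0

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_all_pairs_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        g, p = _random_mask(rng), _random_mask(rng)
        spacing = (float(rng.uniform(1, 10)), 1.25, 1.4)
        assert hausdorff(g, p, spacing, "directed") == pytest.approx(
            oracle_hd(g, p, spacing, "directed"), abs=1e-9
        )
        assert hausdorff(g, p, spacing, "symmetric") == pytest.approx(
            oracle_hd(g, p, spacing, "symmetric"), abs=1e-9
        )
        assert asd(g, p, spacing) == pytest.approx(oracle_asd(g, p, spacing), abs=1e-9)

    def test_translation_invariance(self, rng):
        g = np.zeros((10, 10, 10), dtype=bool)
        p = np.zeros((10, 10, 10), dtype=bool)
        g[3:5, 3:5, 3:5] = True
        p[4:6, 3:5, 3:5] = True
        spacing = (2.0, 1.0, 1.0)
        h0, a0 = hausdorff(g, p, spacing), asd(g, p, spacing)
        gs, ps = np.roll(g, 2, axis=2), np.roll(p, 2, axis=2)
        assert hausdorff(gs, ps, spacing) == pytest.approx(h0)
        assert asd(gs, ps, spacing) == pytest.approx(a0)


class TestBlandAltman:
    def test_worked_example(self):
        res = bland_altman([10, 12, 8], [9, 13, 8])
        assert res.bias == pytest.approx(0.0)
        assert res.loa_low == pytest.approx(-1.96)
        assert res.loa_high == pytest.approx(1.96)

    def test_identical_inputs_zero_width(self):
        res = bland_altman([5.0, 7.0, 9.0], [5.0, 7.0, 9.0])
        assert res.bias == 0.0 and res.loa_low == 0.0 and res.loa_high == 0.0

    def test_constant_offset(self):
        res = bland_altman([15.0, 17.0], [10.0, 12.0])
        assert res.bias == pytest.approx(5.0)
        assert res.loa_low == pytest.approx(5.0)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestEvaluateCases:
    def _cases(self, rng, n=4):
        gts = {}
        for i in range(n):
            data = np.zeros((6, 16, 16), dtype=np.int16)
            c = rng.integers(5, 11, 2)
            data[2:5, c[0] - 3 : c[0] + 3, c[1] - 3 : c[1] + 3] = 1
            gts[f"case{i}"] = LabelVolume(
                data, spacing=(2.0, 1.0, 1.0), class_names=["s"]
            )
        return gts

    def test_perfect_predictions(self, rng):
        gts = self._cases(rng)
        report, ba = evaluate_cases(dict(gts), gts)
        assert (report.per_case["dsc"] == 1.0).all()
        assert (report.per_case["hd_mm"] == 0.0).all()
        assert (report.per_case["asd_mm"] == 0.0).all()
        assert ba["s"].bias == pytest.approx(0.0)

    def test_dilated_predictions_give_negative_bias(self, rng):
        """Over-segmentation means the automated volume exceeds the manual
        one, so the (manual - automated) bias is negative."""
        gts = self._cases(rng)
        preds = {
            k: lv.with_data(
                ndimage.binary_dilation(lv.data > 0).astype(np.int16)
            )
            for k, lv in gts.items()
        }
        report, ba = evaluate_cases(preds, gts)
        assert (report.per_case["vol_pred_mm3"] > report.per_case["vol_gt_mm3"]).all()
        assert ba["s"].bias < 0

    def test_three_structure_report(self, shortaxis_cases):
        gts = {f"c{i}": lv for i, (_, lv) in enumerate(shortaxis_cases[:3])}
        report, ba = evaluate_cases(dict(gts), gts)
        assert set(report.per_case["structure"]) == {"cavity", "ring", "crescent"}
        assert len(report.aggregates) == 3

    def test_missing_predictions_listed(self, rng):
        gts = self._cases(rng)
        preds = dict(list(gts.items())[:-1])
        report, _ = evaluate_cases(preds, gts)
        assert report.missing == ["case3"]
        assert set(report.per_case["case_id"]) == set(list(gts)[:-1])
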