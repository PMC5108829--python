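"""Comparison statistics: masks, profiles, ROIs, ICC(2,1), GMR, diff tables."""

import numpy as np
import pandas as pd
import pytest

from petscatter.evalstats import (
    RoiSpec,
    abs_diff_table,
    gmr_fit,
    icc_2_1,
    roi_stats,
    slice_diff_profile,
    tissue_masks,
)

VOX_MM = (2.0, 2.0, 2.6)


class TestTissueMasks:
    def test_strict_threshold(self):
        gm_p = np.full((4, 4, 2), 0.5)
        wm_p = np.zeros((4, 4, 2))
        gm, wm = tissue_masks(gm_p, wm_p)
        assert not gm.any()  # exactly 0.5 is excluded
        gm, _ = tissue_masks(gm_p + 0.01, wm_p)
        assert gm.all()

    def test_empty_probability(self):
        gm, wm = tissue_masks(np.zeros((3, 3, 3)), np.zeros((3, 3, 3)))
        assert not gm.any() and not wm.any()

    def test_label_volume_identity(self, small_geom):
        """Masks built from the generating labels equal the labels."""
        from petscatter import brain_phantom
        from petscatter.simdata import LABELS

        _, _, labels = brain_phantom(small_geom, scale=0.65)
        gm_p = (labels == LABELS["gm"]).astype(float)
        wm_p = (labels == LABELS["wm"]).astype(float)
        gm, wm = tissue_masks(gm_p, wm_p)
        assert np.array_equal(gm, labels == LABELS["gm"])
        assert np.array_equal(wm, labels == LABELS["wm"])

    def test_overlap_warns(self):
        p = np.full((2, 2, 2), 0.9)
        with pytest.warns(UserWarning, match="overlap"):
            tissue_masks(p, p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tissue_masks(np.full((2, 2, 2), 1.5), np.zeros((2, 2, 2)))


class TestSliceDiffProfile:
    def test_identical_images(self, rng):
        img = rng.random((8, 8, 5))
        mask = np.ones_like(img, dtype=bool)
        assert np.allclose(slice_diff_profile(img, img, mask), 0.0)

    def test_five_percent_scaling(self, rng):
        img = rng.random((8, 8, 5)) + 1.0
        mask = np.ones_like(img, dtype=bool)
        prof = slice_diff_profile(1.05 * img, img, mask)
        assert np.allclose(prof, 5.0)

    def test_empty_slice_is_nan(self, rng):
        img = rng.random((8, 8, 5)) + 1.0
        mask = np.ones_like(img, dtype=bool)
        mask[:, :, 2] = False
        prof = slice_diff_profile(img, img, mask)
        assert np.isnan(prof[2]) and not np.isnan(prof[1])

    def test_zero_reference_is_nan_not_error(self):
        a = np.ones((4, 4, 2))
        b = np.zeros((4, 4, 2))
        mask = np.ones_like(a, dtype=bool)
        prof = slice_diff_profile(a, b, mask)
        assert np.isnan(prof).all()


class TestRoiStats:
    def _rois(self):
        return [
            RoiSpec("cortex", (20.0, 32.0), 2, shape="ellipse", axes_mm=(16, 32)),
            RoiSpec("mid", (32.0, 32.0), 2, shape="circle", axes_mm=(16, 16), bilateral=False),
        ]

    def test_constant_image(self):
        vol = np.full((64, 64, 8), 7.0)
        df = roi_stats(vol, self._rois(), VOX_MM)
        assert np.allclose(df["mean"], 7.0)
        assert df.loc["cortex", "lr_ratio"] == pytest.approx(1.0)

    def test_scaled_hemisphere_ratio(self):
        vol = np.full((64, 64, 8), 10.0)
        vol[32:, :, :] *= 0.8  # left half (mirrored side) scaled
        df = roi_stats(vol, self._rois()[:1], VOX_MM)
        assert df.loc["cortex", "lr_ratio"] == pytest.approx(0.8)

    def test_unilateral_has_no_ratio(self):
        vol = np.ones((64, 64, 8))
        df = roi_stats(vol, self._rois(), VOX_MM)
        assert np.isnan(df.loc["mid", "lr_ratio"])

    def test_roi_outside_image_rejected(self):
        vol = np.ones((64, 64, 4))
        roi = RoiSpec("edge", (32.0, 32.0), 3, n_slices_averaged=3)
        with pytest.raises(ValueError, match="slices"):
            roi_stats(vol, [roi], VOX_MM)

    def test_three_slice_average(self):
        vol = np.ones((64, 64, 8))
        vol[:, :, 3] = 4.0  # middle slice of the 2..4 window
        df = roi_stats(vol, self._rois()[:1], VOX_MM)
        assert df.loc["cortex", "mean"] == pytest.approx(2.0)  # (1+4+1)/3


class TestIcc:
    def test_identical_columns(self):
        x = np.arange(10.0)
        assert icc_2_1(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_matches_pingouin_oracle(self, rng):
        """Independent two-way random-effects ANOVA implementation
        (pingouin ICC2) agrees to 1e-10."""
        import pingouin as pg

        m = rng.random((10, 2)) * 5 + np.arange(10)[:, None]
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 2),
                "rater": np.tile(["a", "b"], 10),
                "score": m.ravel(),
            }
        )
        res = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        # ICC(A,1) in McGraw-Wong naming = ICC(2,1) in Shrout-Fleiss
        expected = float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_2_1(m) == pytest.approx(expected, abs=1e-10)

    def test_null_distribution_near_zero(self, rng):
        """Independent equal-variance columns, n = 200: ICC within 0.15 of 0."""
        m = rng.standard_normal((200, 2))
        assert abs(icc_2_1(m)) < 0.15

    def test_shift_invariance_and_scale_equivariance(self, rng):
        m = rng.random((12, 3))
        base = icc_2_1(m)
        assert icc_2_1(m + 100.0) == pytest.approx(base, abs=1e-12)
        assert icc_2_1(m * 3.5) == pytest.approx(base, abs=1e-12)

    def test_degenerate_input(self):
        assert np.isnan(icc_2_1(np.ones((5, 2))))
        with pytest.raises(ValueError):
            icc_2_1(np.ones((1, 2)))


class TestGmr:
    def test_exact_line(self):
        x = np.linspace(0, 10, 20)
        slope, intercept = gmr_fit(x, 2 * x + 1)
        assert slope == pytest.approx(2.0, abs=1e-12)
        assert intercept == pytest.approx(1.0, abs=1e-12)

    def test_swap_symmetry(self, rng):
        x = rng.random(30)
        y = 1.5 * x + 0.3 * rng.random(30)
        s_xy, _ = gmr_fit(x, y)
        s_yx, _ = gmr_fit(y, x)
        assert s_xy * s_yx == pytest.approx(1.0, abs=1e-12)
        assert np.sign(s_xy) == np.sign(s_yx)

    def test_rescaling_y_scales_slope(self, rng):
        x = rng.random(25)
        y = rng.random(25)
        s1, _ = gmr_fit(x, y)
        s2, _ = gmr_fit(x, 4.0 * y)
        assert s2 == pytest.approx(4.0 * s1, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            gmr_fit(np.ones(5), np.arange(5.0))


class TestAbsDiffTable:
    def _tables(self, a_vals, b_vals):
        cols = ["roi1", "roi2"]
        a = pd.DataFrame(a_vals, columns=cols)
        b = pd.DataFrame(b_vals, columns=cols)
        return a, b

    def test_identical_all_zero(self):
        a, b = self._tables([[1.0, 2.0], [3.0, 4.0]], [[1.0, 2.0], [3.0, 4.0]])
        out = abs_diff_table(a, b)
        assert np.allclose(out["abs_diff_pct"], 0.0)

    def test_ten_percent(self):
        b = [[1.0, 2.0], [3.0, 4.0]]
        a = [[1.1, 2.2], [3.3, 4.4]]
        out = abs_diff_table(*self._tables(a, b))
        assert np.allclose(out["abs_diff_pct"], 10.0)

    def test_patient_mean(self):
        """Per-subject diffs 4% and 8% average to 6%."""
        b = [[100.0, 100.0], [100.0, 100.0]]
        a = [[104.0, 104.0], [92.0, 92.0]]
        out = abs_diff_table(*self._tables(a, b))
        assert np.allclose(out.loc[["roi1", "roi2"], "abs_diff_pct"], 6.0)
        assert out.loc["Total", "abs_diff_pct"] == pytest.approx(6.0)

    def test_zero_reference_is_nan(self):
        a, b = self._tables([[1.0, 1.0]], [[0.0, 2.0]])
        out = abs_diff_table(a, b)
        assert np.isnan(out.loc["roi1", "abs_diff_pct"])
        assert np.isfinite(out.loc["Total", "abs_diff_pct"])

    def test_mismatched_layout_rejected(self):
        a = pd.DataFrame([[1.0]], columns=["x"])
        b = pd.DataFrame([[1.0]], columns=["y"])
        with pytest.raises(ValueError):
            abs_diff_table(a, b)


def test_profile_and_table_agree_on_single_roi_slice(rng):
    """A one-ROI, one-slice comparison gives the same percent difference
    through both reporting paths (internal consistency)."""
    img_b = rng.random((32, 32, 3)) + 1.0
    img_a = 1.07 * img_b
    mask = np.zeros_like(img_b, dtype=bool)
    roi = RoiSpec("one", (16.0, 16.0), 1, shape="circle", axes_mm=(16, 16),
                  bilateral=False, n_slices_averaged=1)
    m2d = roi._mask2d(32, 32, (2.0, 2.0), mirror=False)
    mask[:, :, 1] = m2d
    prof = slice_diff_profile(img_a, img_b, mask)
    stats_a = roi_stats(img_a, [roi], VOX_MM)
    stats_b = roi_stats(img_b, [roi], VOX_MM)
    table = abs_diff_table(
        pd.DataFrame({"one": [stats_a.loc["one", "mean"]]}),
        pd.DataFrame({"one": [stats_b.loc["one", "mean"]]}),
    )
    assert prof[1] == pytest.approx(table.loc["one", "abs_diff_pct"], rel=1e-9)
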