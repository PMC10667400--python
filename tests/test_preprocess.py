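import numpy as np
import pytest

from radrepro.preprocess import (
    PreprocessSetting,
    apply_setting,
    discretize_fbn,
    discretize_fbs,
    enumerate_settings,
    filter_outliers,
    normalize_dual_reference,
)


@pytest.fixture()
def settings():
    return enumerate_settings()


class TestEnumerateSettings:
    def test_grid_has_48_settings(self, settings):
        assert len(settings) == 48

    def test_indices_run_1_to_48(self, settings):
        assert [s.setting_index for s in settings] == list(range(1, 49))

    def test_every_combination_appears_exactly_once(self, settings):
        combos = {
            (s.discretization, s.binning, s.normalization, s.outlier_mode)
            for s in settings
        }
        assert len(combos) == 48

    def test_unique_filter_fbn64_nar_out(self, settings):
        hits = [
            s
            for s in settings
            if (s.discretization, s.binning, s.normalization, s.outlier_mode)
            == ("FBN", 64, "NAR", "OUT")
        ]
        assert len(hits) == 1
        # anchor indices used in the analysis
        assert hits[0].setting_index == 18

    def test_setting_37_is_fbs20_ar_nof(self, settings):
        s = settings[36]
        assert (s.discretization, s.binning, s.normalization, s.outlier_mode) == (
            "FBS",
            20,
            "AR",
            "NoF",
        )

    def test_stable_across_runs(self, settings):
        assert settings == enumerate_settings()

    def test_illegal_binning_rejected(self):
        with pytest.raises(ValueError, match="not legal"):
            PreprocessSetting(1, "FBN", 5, "AR", "NoF")


class TestNormalizeDualReference:
    def _refs(self):
        fat = np.zeros((4, 4, 4), dtype=bool)
        muscle = np.zeros((4, 4, 4), dtype=bool)
        fat[0, 0, :2] = True
        muscle[3, 3, 2:] = True
        return fat, muscle

    def test_two_point_map_by_hand(self):
        # muscle mean 200, fat mean 800, anchors (0, 1000): 500 -> 500
        fat, muscle = self._refs()
        vol = np.full((4, 4, 4), 500.0)
        vol[fat] = 800.0
        vol[muscle] = 200.0
        out = normalize_dual_reference(vol, fat, muscle, anchors=(0.0, 1000.0))
        assert out[1, 1, 1] == pytest.approx(500.0)
        assert out[fat].mean() == pytest.approx(1000.0)
        assert out[muscle].mean() == pytest.approx(0.0)

    def test_identity_when_anchors_already_met(self):
        fat, muscle = self._refs()
        vol = np.full((4, 4, 4), 321.0)
        vol[fat] = 1000.0
        vol[muscle] = 0.0
        out = normalize_dual_reference(vol, fat, muscle, anchors=(0.0, 1000.0))
        np.testing.assert_allclose(out, vol)

    def test_affine_invariance(self):
        fat, muscle = self._refs()
        rng = np.random.default_rng(3)
        vol = rng.normal(400, 100, size=(4, 4, 4))
        vol[fat] += 500.0  # keep fat brighter than muscle
        a = normalize_dual_reference(vol, fat, muscle)
        b = normalize_dual_reference(2.0 * vol + 10.0, fat, muscle)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_degenerate_references_error(self):
        fat, muscle = self._refs()
        vol = np.full((4, 4, 4), 7.0)
        with pytest.raises(ValueError, match="degenerate"):
            normalize_dual_reference(vol, fat, muscle)

    def test_empty_reference_error(self):
        fat, muscle = self._refs()
        vol = np.zeros((4, 4, 4))
        with pytest.raises(ValueError, match="empty"):
            normalize_dual_reference(vol, np.zeros_like(fat), muscle)


class TestFilterOutliers:
    def test_nof_is_identity(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.5
        res = filter_outliers(vol, mask, "NoF")
        assert res.n_affected == 0
        np.testing.assert_array_equal(res.volume, vol)
        np.testing.assert_array_equal(res.mask, mask)

    def test_hand_computed_bounds(self):
        # 99 voxels of 0 and one of 1000: mu=10, sample sigma=100,
        # bounds 10 +/- 300
        vol = np.zeros((10, 10, 1))
        vol[0, 0, 0] = 1000.0
        mask = np.ones((10, 10, 1), dtype=bool)
        out = filter_outliers(vol, mask, "OUT")
        assert out.mu == pytest.approx(10.0)
        assert out.sigma == pytest.approx(100.0, rel=1e-3)
        assert out.n_affected == 1
        assert out.mask.sum() == 99
        assert not out.mask[0, 0, 0]

        inn = filter_outliers(vol, mask, "IN")
        assert inn.mask.sum() == 100
        assert inn.volume[0, 0, 0] == pytest.approx(inn.mu + 3 * inn.sigma)

    def test_all_within_range_unchanged(self):
        rng = np.random.default_rng(1)
        vol = rng.uniform(0, 1, size=(6, 6, 6))
        mask = np.ones((6, 6, 6), dtype=bool)
        for mode in ("IN", "OUT"):
            res = filter_outliers(vol, mask, mode)
            assert res.n_affected == 0
            np.testing.assert_array_equal(res.mask, mask)
            np.testing.assert_array_equal(res.volume, vol)

    def test_in_mode_clips_into_range(self):
        rng = np.random.default_rng(2)
        vol = rng.standard_t(df=2, size=(8, 8, 8)) * 50
        mask = np.ones(vol.shape, dtype=bool)
        res = filter_outliers(vol, mask, "IN")
        lo, hi = res.mu - 3 * res.sigma, res.mu + 3 * res.sigma
        assert res.volume[res.mask].min() >= lo - 1e-9
        assert res.volume[res.mask].max() <= hi + 1e-9
        np.testing.assert_array_equal(res.mask, mask)

    def test_out_mask_is_subset(self):
        rng = np.random.default_rng(5)
        vol = rng.standard_cauchy(size=(8, 8, 8))
        mask = rng.random(vol.shape) < 0.8
        res = filter_outliers(vol, mask, "OUT")
        assert not (res.mask & ~mask).any()
        removed = mask & ~res.mask
        lo, hi = res.mu - 3 * res.sigma, res.mu + 3 * res.sigma
        assert ((vol[removed] < lo) | (vol[removed] > hi)).all()

    def test_zero_sigma_warns_and_noops(self):
        vol = np.full((3, 3, 3), 4.0)
        mask = np.ones((3, 3, 3), dtype=bool)
        with pytest.warns(UserWarning, match="no-op"):
            res = filter_outliers(vol, mask, "OUT")
        assert res.mask.sum() == 27


class TestDiscretization:
    def test_fbn_hand_example(self):
        vol = np.array([[[1.0, 2.0, 3.0, 4.0]]])
        mask = np.ones_like(vol, dtype=bool)
        disc = discretize_fbn(vol, mask, 2)
        np.testing.assert_array_equal(disc.levels[mask], [1, 1, 2, 2])
        assert disc.n_levels == 2

    def test_fbn_affine_invariance(self):
        rng = np.random.default_rng(7)
        vol = rng.normal(500, 80, size=(6, 6, 6))
        mask = rng.random(vol.shape) < 0.6
        a = discretize_fbn(vol, mask, 32)
        b = discretize_fbn(3.7 * vol + 12.0, mask, 32)
        np.testing.assert_array_equal(a.levels, b.levels)

    def test_fbn_constant_roi(self):
        vol = np.full((3, 3, 3), 9.0)
        mask = np.ones_like(vol, dtype=bool)
        disc = discretize_fbn(vol, mask, 16)
        assert disc.n_levels == 1
        assert (disc.levels[mask] == 1).all()

    def test_fbn_ng_equals_bin_count(self):
        rng = np.random.default_rng(8)
        vol = rng.normal(size=(5, 5, 5))
        mask = np.ones(vol.shape, dtype=bool)
        for nb in (16, 32, 64, 128):
            disc = discretize_fbn(vol, mask, nb)
            assert disc.n_levels == nb
            assert disc.levels[mask].min() >= 1
            assert disc.levels[mask].max() == nb

    def test_fbs_hand_example(self):
        # values {10,17,25}, W=5, lowest edge 10 -> levels 1,2,4 and Ng=4
        vol = np.array([[[10.0, 17.0, 25.0]]])
        mask = np.ones_like(vol, dtype=bool)
        disc = discretize_fbs(vol, mask, 5.0)
        np.testing.assert_array_equal(disc.levels[mask], [1, 2, 4])
        assert disc.n_levels == 4

    def test_fbs_shift_by_whole_bin_invariant(self):
        rng = np.random.default_rng(9)
        vol = rng.uniform(100, 300, size=(5, 5, 5))
        mask = np.ones(vol.shape, dtype=bool)
        a = discretize_fbs(vol, mask, 10.0)
        b = discretize_fbs(vol + 10.0, mask, 10.0)
        np.testing.assert_array_equal(a.levels, b.levels)

    def test_fbs_scale_sensitive(self):
        rng = np.random.default_rng(10)
        vol = rng.uniform(100, 300, size=(6, 6, 6))
        mask = np.ones(vol.shape, dtype=bool)
        a = discretize_fbs(vol, mask, 10.0)
        b = discretize_fbs(2.0 * vol, mask, 10.0)
        assert b.n_levels == pytest.approx(2 * a.n_levels, abs=2)
        assert b.n_levels > a.n_levels

    def test_empty_mask_errors(self):
        vol = np.zeros((3, 3, 3))
        empty = np.zeros_like(vol, dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            discretize_fbn(vol, empty, 16)
        with pytest.raises(ValueError, match="empty"):
            discretize_fbs(vol, empty, 5.0)


class TestApplySetting:
    def test_nar_nof_fbn_reduces_to_plain_fbn(self, small_cohort, settings):
        cases, _ = small_cohort
        case = cases[0]
        setting = next(
            s
            for s in settings
            if (s.discretization, s.binning, s.normalization, s.outlier_mode)
            == ("FBN", 16, "NAR", "NoF")
        )
        _, mask, disc = apply_setting(case, 1, setting)
        direct = discretize_fbn(case.scan1_volume, case.scan1_mask, 16)
        np.testing.assert_array_equal(disc.levels, direct.levels)

    def test_out_mode_shrinks_by_exact_outlier_set(self, small_cohort, settings):
        cases, _ = small_cohort
        case = cases[1]
        setting = settings[17]  # FBN64/NAR/OUT
        _, mask, _ = apply_setting(case, 1, setting)
        vals = case.scan1_volume[case.scan1_mask]
        mu, sigma = vals.mean(), vals.std(ddof=1)
        expected_removed = case.scan1_mask & (
            (case.scan1_volume < mu - 3 * sigma) | (case.scan1_volume > mu + 3 * sigma)
        )
        np.testing.assert_array_equal(case.scan1_mask & ~mask, expected_removed)

    def test_ar_vs_nar_identical_fbn_levels(self, small_cohort, settings):
        cases, _ = small_cohort
        case = cases[2]
        ar = next(s for s in settings if s.label == "FBN32/AR/NoF")
        nar = next(s for s in settings if s.label == "FBN32/NAR/NoF")
        _, _, disc_ar = apply_setting(case, 1, ar)
        _, _, disc_nar = apply_setting(case, 1, nar)
        np.testing.assert_array_equal(disc_ar.levels, disc_nar.levels)

    def test_missing_reference_masks_fail_for_ar(self, settings):
        class Case:
            lesion_id = "L999"
            spacing = (0.5, 0.5, 3.0)
            scan1_volume = np.random.default_rng(0).normal(size=(6, 6, 6))
            scan1_mask = np.zeros((6, 6, 6), dtype=bool)
            fat_mask = np.zeros((6, 6, 6), dtype=bool)
            muscle_mask = np.zeros((6, 6, 6), dtype=bool)

        Case.scan1_mask[0, 0, :4] = True
        ar_setting = settings[2]  # FBN16/AR/OUT
        assert ar_setting.normalization == "AR"
        with pytest.raises(ValueError, match="reference mask is empty"):
            apply_setting(Case, 1, ar_setting)

    def test_invalid_scan_number_rejected(self, small_cohort, settings):
        cases, _ = small_cohort
        with pytest.raises(ValueError, match="scan"):
            apply_setting(cases[0], 3, settings[0])
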