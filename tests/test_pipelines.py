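import numpy as np
import pytest

from ciliaquant import pipelines
from ciliaquant.errors import (
    BoundsError,
    InvalidParameterError,
    UndefinedStatisticError,
)
from ciliaquant.imagecore import Calibration, ImageStack, PolyROI
from ciliaquant.pipelines import (
    IntensityProfile,
    actin_clearing,
    basal_body_enrichment,
    clearing_ratio_from_profile,
    detect_basal_bodies,
    enrichment_from_mask,
    lysotracker_size,
    manders_from_masks,
    percent_ciliation,
)


class TestLysoTracker:
    def test_degenerate_roi_skipped(self, flat_stack):
        results = lysotracker_size(flat_stack)
        assert len(results) == 1
        assert results[0].skipped and results[0].mean_area_um2 is None

    def test_counts_and_area_on_clean_disks(self):
        # three clean disks well inside the field, radius 3 px each
        cal = Calibration(0.21, 0.21)
        img = np.zeros((100, 100), dtype=np.float32)
        yy, xx = np.mgrid[0:100, 0:100]
        for cy, cx in ((25, 25), (50, 70), (75, 30)):
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 9] = 150.0
        stack = ImageStack(img[None, None], ["vesicles"], cal)
        (res,) = lysotracker_size(stack)
        assert not res.skipped
        assert res.n_particles == 3
        # smoothing before thresholding dilates small disks by up to ~1.5 px,
        # so the recovered area lies between the drawn disk and its dilation
        drawn_px = 29
        dilated_px = int(np.pi * 4.5**2) + 10
        assert drawn_px * 0.21**2 <= res.mean_area_um2 <= dilated_px * 0.21**2

    def test_circularity_filter_removes_lines(self):
        cal = Calibration(0.21, 0.21)
        img = np.zeros((100, 100), dtype=np.float32)
        img[50, 20:80] = 150.0  # a long line: circularity far below 0.5
        stack = ImageStack(img[None, None], ["vesicles"], cal)
        (res,) = lysotracker_size(stack)
        assert res.n_particles == 0


class TestClearing:
    def _profile(self, values, psz=0.28):
        n = len(values)
        d = (np.arange(n) - n // 2) * psz
        v = np.asarray(values, dtype=float)
        return IntensityProfile(distance_um=d, value=v / v.mean())

    def test_uniform_ratio_exactly_one(self):
        prof = self._profile(np.full(29, 7.0))
        assert clearing_ratio_from_profile(prof) == 1.0

    def test_zero_center_ratio_zero(self):
        vals = np.ones(29)
        d = (np.arange(29) - 14) * 0.28
        vals[np.abs(d) <= 0.3] = 0.0
        assert clearing_ratio_from_profile(self._profile(vals)) == 0.0

    def test_analytic_dip(self):
        # rectangular multiplicative dip of depth d within radius R: the
        # ratio is exactly (1 - d) because the dip covers the whole center
        # window and leaves the flanks untouched
        psz = 0.28
        for depth in (0.3, 0.6, 0.9):
            cols = 29
            d_um = (np.arange(cols) - cols // 2) * psz
            profile_vals = np.where(np.abs(d_um) <= 1.0, 1.0 - depth, 1.0)
            sideview = np.zeros((20, cols))
            sideview[8:12, :] = 100.0 * profile_vals  # cortex rows
            res = actin_clearing(
                sideview, bb_center=(cols // 2, 10), calibration=Calibration(psz, psz)
            )
            assert res.ratio == pytest.approx(1.0 - depth, rel=1e-9)

    def test_out_of_bounds_roi(self):
        with pytest.raises(BoundsError):
            actin_clearing(
                np.ones((10, 10)), bb_center=(1, 1), calibration=Calibration(0.28, 0.28)
            )

    def test_gtub_profile_attached_but_ignored(self):
        psz = 0.28
        sideview = np.ones((30, 40)) * 50
        gtub = np.ones((30, 40))
        res = actin_clearing(sideview, (20, 15), Calibration(psz, psz), gtub_sideview=gtub)
        assert res.ratio == 1.0
        assert res.profile_gtub is not None


class TestCiliation:
    def test_invalid_variant(self, flat_stack):
        with pytest.raises(InvalidParameterError):
            percent_ciliation(flat_stack, variant="hela")

    def test_variant_parameters(self):
        assert pipelines._CILIA_PARAMS["mdck"] == {
            "method": "shanbhag",
            "min_size_px": 2,
        }
        assert pipelines._CILIA_PARAMS["rpe1"] == {"method": "yen", "min_size_px": 5}

    def test_manual_override(self, small_monolayer):
        stack, _ = small_monolayer
        res = percent_ciliation(stack, variant="rpe1", manual_nuclei_override=10)
        assert res.n_nuclei == 10
        assert res.percent_ciliated == pytest.approx(100.0 * res.n_cilia / 10)

    def test_zero_nuclei_undefined(self, small_monolayer):
        stack, _ = small_monolayer
        with pytest.raises(UndefinedStatisticError):
            percent_ciliation(stack, variant="rpe1", manual_nuclei_override=0)

    def test_degenerate_cilia_channel_counts_zero(self, small_monolayer):
        stack, _ = small_monolayer
        flat = np.full_like(stack.voxels[:1], 5.0)
        st = ImageStack(
            np.concatenate([flat, stack.voxels[:1]]),
            ["cilia", "nuclei"],
            stack.calibration,
        )
        res = percent_ciliation(st, variant="rpe1")
        assert res.n_cilia == 0

    def test_recovers_truth_small_monolayer(self, small_monolayer):
        stack, truth = small_monolayer
        res = percent_ciliation(stack, variant="rpe1")
        true_pct = truth.realized_ciliation_fraction * 100
        assert abs(res.percent_ciliated - true_pct) <= 10.0


class TestEnrichment:
    CAL = Calibration(0.12, 0.12)
    POLY = PolyROI([(30, 30), (220, 30), (220, 220), (30, 220)])

    def test_uniform_fold_near_one(self, rng):
        mask = rng.random((300, 300)) < 0.3
        res = enrichment_from_mask(mask, (150, 100), self.POLY, self.CAL)
        assert not res.excluded
        assert res.fold_enrichment == pytest.approx(1.0, abs=0.35)

    def test_full_concentration_identity(self):
        mask = np.zeros((300, 300), dtype=bool)
        w, h = round(3.0 / 0.12), round(2.0 / 0.12)
        x0 = 150 - w // 2
        mask[100 : 100 + h, x0 : x0 + w] = True
        res = enrichment_from_mask(mask, (150, 100), self.POLY, self.CAL)
        a_c = self.POLY.mask((300, 300)).sum()
        assert res.fold_enrichment == pytest.approx(a_c / (w * h))

    def test_near_uniform_exclusions(self):
        res_hi = enrichment_from_mask(
            np.ones((300, 300), dtype=bool), (150, 100), self.POLY, self.CAL
        )
        assert res_hi.excluded
        sparse = np.zeros((300, 300), dtype=bool)
        sparse[40, 40] = True
        res_lo = enrichment_from_mask(sparse, (150, 100), self.POLY, self.CAL)
        assert res_lo.excluded

    def test_bb_roi_bounds(self):
        with pytest.raises(BoundsError):
            enrichment_from_mask(
                np.zeros((40, 40), dtype=bool),
                (2, 38),
                PolyROI([(1, 1), (10, 1), (10, 10)]),
                self.CAL,
            )

    def test_degenerate_slice_excluded(self):
        res = basal_body_enrichment(
            np.full((300, 300), 9.0), (150, 100), self.POLY, self.CAL
        )
        assert res.excluded and "degenerate" in res.exclusion_reason


class TestManders:
    def test_identical_masks(self, rng):
        a = rng.random((60, 60)) < 0.2
        res = manders_from_masks(a, a)
        assert (res.m1, res.m2) == (1.0, 1.0)

    def test_disjoint_masks(self, rng):
        a = rng.random((60, 60)) < 0.3
        res = manders_from_masks(a, ~a)
        assert (res.m1, res.m2) == (0.0, 0.0)

    def test_fixture_100_50_25(self):
        a = np.zeros((40, 40), dtype=bool)
        b = np.zeros((40, 40), dtype=bool)
        a[:10, :10] = True  # |A| = 100
        b[:5, :5] = True  # 25 px overlapping A
        b[20:25, 20:25] = True  # 25 px disjoint
        res = manders_from_masks(a, b)
        assert res.m1 == pytest.approx(0.25)
        assert res.m2 == pytest.approx(0.50)

    def test_empty_channel_flags(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.ones((10, 10), dtype=bool)
        res = manders_from_masks(a, b)
        assert res.m1 is None and res.m2 == 0.0
        assert any("M1" in f for f in res.flags)

    def test_shape_mismatch(self):
        with pytest.raises(InvalidParameterError):
            manders_from_masks(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestDetectBasalBodies:
    def test_finds_bright_puncta(self):
        img = np.zeros((50, 80))
        img[10, 30] = 100.0
        img[40, 60] = 90.0
        peaks = detect_basal_bodies(img, n_peaks=2, min_separation_px=5)
        assert (30, 10) in peaks and (60, 40) in peaks
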