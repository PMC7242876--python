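"""PET ROI interpolation, %ID/g arithmetic and PET-vs-gamma agreement."""

import numpy as np
import pytest
from scipy import stats

from adipophen import synthetic
from adipophen.errors import InvalidContourError, UndefinedFractionError
from adipophen.pet import (
    ContourSet,
    GammaCountRecord,
    compute_pet_uptake,
    correlate_pet_gamma,
    gamma_uptake,
    interpolate_roi,
)
from adipophen.volume import BinaryMask, MaskRole, Modality, VoxelVolume

SP = (1.0, 1.0, 1.0)
SQUARE = np.array([[10.0, 10.0], [10.0, 30.0], [30.0, 30.0], [30.0, 10.0]])


def _circle(r, c=32.0, n=64):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([c + r * np.cos(th), c + r * np.sin(th)])


class TestContourSet:
    def test_single_contour_cannot_interpolate(self):
        cs = ContourSet([(0, SQUARE), (4, SQUARE)], SP)
        cs.contours = cs.contours[:1]
        with pytest.raises(InvalidContourError):
            interpolate_roi(cs, (5, 40, 40))

    def test_self_intersecting_polygon_rejected(self):
        bowtie = np.array([[0.0, 0.0], [10.0, 10.0], [0.0, 10.0], [10.0, 0.0]])
        with pytest.raises(InvalidContourError):
            ContourSet([(0, bowtie), (4, SQUARE)], SP)

    def test_duplicate_slices_rejected(self):
        with pytest.raises(InvalidContourError):
            ContourSet([(0, SQUARE), (0, SQUARE)], SP)


class TestInterpolateRoi:
    def test_identical_contours_fill_identically(self):
        roi = interpolate_roi(ContourSet([(0, SQUARE), (4, SQUARE)], SP), (5, 40, 40))
        for j in range(1, 5):
            np.testing.assert_array_equal(roi.data[j], roi.data[0])

    def test_input_slices_reproduced_exactly(self, pet_phantom):
        roi = interpolate_roi(pet_phantom.contours, pet_phantom.volume.shape)
        from adipophen.pet import _rasterize

        dy, dx = pet_phantom.contours.spacing[1:]
        ny, nx = pet_phantom.volume.shape[1:]
        for idx, verts in pet_phantom.contours.contours:
            np.testing.assert_array_equal(
                roi.data[idx], _rasterize(verts, (dy, dx), (ny, nx))
            )

    def test_cone_mid_slice_radius(self):
        cs = ContourSet([(0, _circle(10.0)), (10, _circle(20.0))], SP)
        roi = interpolate_roi(cs, (11, 64, 64))
        r_eff = np.sqrt(roi.data[5].sum() / np.pi)
        assert r_eff == pytest.approx(15.0, abs=1.0)

    def test_traced_ellipsoid_jaccard(self, pet_phantom):
        roi = interpolate_roi(pet_phantom.contours, pet_phantom.volume.shape)
        truth = pet_phantom.true_mask.data
        jac = (roi.data & truth).sum() / (roi.data | truth).sum()
        assert jac >= 0.95


class TestPetUptake:
    def test_uniform_volume_closed_form(self):
        vol = VoxelVolume(np.full((8, 8, 8), 3.0), SP, Modality.PET_ACTIVITY)
        roi = BinaryMask(np.ones((8, 8, 8), bool), MaskRole.ROI, SP)
        res = compute_pet_uptake(vol, roi, injected_dose=60.0)
        assert res.percent_id_per_g == pytest.approx(100 * 3.0 / 60.0, rel=1e-12)

    def test_dose_doubling_halves_uptake(self, pet_phantom):
        roi = pet_phantom.true_mask
        a = compute_pet_uptake(pet_phantom.volume, roi, 100.0).percent_id_per_g
        b = compute_pet_uptake(pet_phantom.volume, roi, 200.0).percent_id_per_g
        assert b == pytest.approx(a / 2.0, rel=1e-12)

    def test_matches_bruteforce_voxel_sum(self, pet_phantom):
        roi = pet_phantom.true_mask
        res = compute_pet_uptake(pet_phantom.volume, roi, 100.0)
        total, n = 0.0, 0  # exhaustive voxel loop over a subgrid for speed
        data, m = pet_phantom.volume.data, roi.data
        for z in range(data.shape[0]):
            sl, msk = data[z], m[z]
            total += float(sl[msk].sum())
            n += int(msk.sum())
        oracle = 100.0 * (total / n) / 100.0
        assert res.percent_id_per_g == pytest.approx(oracle, abs=1e-6)

    def test_linear_in_concentration(self):
        ph1 = synthetic.make_pet_phantom(hot_concentration=4.0, noise_sd=0, seed=0)
        ph2 = synthetic.make_pet_phantom(hot_concentration=8.0, noise_sd=0, seed=0)
        u1 = compute_pet_uptake(ph1.volume, ph1.true_mask, 100.0).percent_id_per_g
        u2 = compute_pet_uptake(ph2.volume, ph2.true_mask, 100.0).percent_id_per_g
        assert u2 == pytest.approx(2 * u1, rel=1e-9)

    def test_mask_growth_into_background_decreases_mean(self):
        from scipy import ndimage as ndi

        ph = synthetic.make_pet_phantom(noise_sd=0, seed=0)
        grown = ph.true_mask.data
        prev = compute_pet_uptake(ph.volume, ph.true_mask, 100.0).percent_id_per_g
        for _ in range(3):
            grown = ndi.binary_dilation(grown)
            cur = compute_pet_uptake(
                ph.volume, BinaryMask(grown, MaskRole.ROI, SP), 100.0
            ).percent_id_per_g
            assert cur <= prev
            prev = cur

    def test_empty_roi_and_zero_dose_rejected(self):
        vol = VoxelVolume(np.ones((4, 4, 4)), SP, Modality.PET_ACTIVITY)
        empty = BinaryMask(np.zeros((4, 4, 4), bool), MaskRole.ROI, SP)
        full = BinaryMask(np.ones((4, 4, 4), bool), MaskRole.ROI, SP)
        with pytest.raises(UndefinedFractionError):
            compute_pet_uptake(vol, empty, 1.0)
        with pytest.raises(ValueError):
            compute_pet_uptake(vol, full, 0.0)


class TestGammaUptake:
    def test_unit_case(self):
        assert gamma_uptake(GammaCountRecord("BAT", 1e6, 1.0, 1e6)) == 100.0

    def test_zero_counts(self):
        assert gamma_uptake(GammaCountRecord("BAT", 0.0, 0.5, 1e6)) == 0.0

    def test_randomized_records_match_hand_formula(self, rng):
        for _ in range(50):
            counts = rng.uniform(0, 1e5)
            w = rng.uniform(0.05, 0.5)
            inj = rng.uniform(1e5, 1e7)
            got = gamma_uptake(GammaCountRecord("eFat", counts, w, inj))
            assert got == pytest.approx(100.0 * counts / inj / w, rel=1e-12)

    def test_invalid_records_rejected(self):
        with pytest.raises(ValueError):
            gamma_uptake(GammaCountRecord("BAT", 1.0, 0.0, 1e6))
        with pytest.raises(ValueError):
            gamma_uptake(GammaCountRecord("BAT", 1.0, 1.0, 0.0))


class TestCorrelatePetGamma:
    def test_identity_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        reg = correlate_pet_gamma(x, x)
        assert reg.slope == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.r == pytest.approx(1.0)

    def test_affine_line(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        reg = correlate_pet_gamma(x, 2 * x + 1)
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(1.0)
        assert reg.r2 == pytest.approx(1.0)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ZeroDivisionError):
            correlate_pet_gamma(np.ones(5), np.arange(5.0))

    def test_slope_ci_coverage(self):
        """Over replicated noisy cohorts generated with slope 0.9, the OLS
        slope's own 95% CI covers 0.9 in at least 93% of replicates."""
        rng = np.random.default_rng(7)
        n, true_slope, hits, reps = 9, 0.9, 0, 500
        for _ in range(reps):
            x = rng.uniform(2.0, 12.0, n)
            y = true_slope * x + rng.normal(0, 0.4, n)
            fit = stats.linregress(x, y)
            tcrit = stats.t.ppf(0.975, n - 2)
            lo, hi = fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr
            hits += lo <= true_slope <= hi
        assert hits / reps >= 0.93


def test_pet_and_gamma_agree_on_paired_subjects():
    """One ground-truth uptake per subject measured both ways: OLS slope
    within 1 +/- 0.05 and r >= 0.99."""
    pet_vals, gamma_vals = [], []
    for i, u in enumerate(np.linspace(2.0, 12.0, 9)):
        ph = synthetic.make_pet_phantom(
            hot_concentration=u, injected_dose=100.0, noise_sd=0.05,
            seed=100 + i, geometry_seed=200 + i,
        )
        roi = interpolate_roi(ph.contours, ph.volume.shape)
        pet_vals.append(
            compute_pet_uptake(ph.volume, roi, ph.injected_dose).percent_id_per_g
        )
        recs, _ = synthetic.make_gamma_records(
            {"BAT": ph.true_percent_id_per_g}, measurement_cv=0.02, seed=300 + i
        )
        gamma_vals.append(gamma_uptake(recs[0]))
    reg = correlate_pet_gamma(np.array(pet_vals), np.array(gamma_vals))
    assert abs(reg.slope - 1.0) <= 0.05
    assert reg.r >= 0.99
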