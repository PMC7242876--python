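"""Whole-body CT fat segmentation: unit behaviour and recovery properties."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from adipophen import synthetic
from adipophen.ct import (
    FatSegmentationParams,
    analyze_ct,
    compute_fat_fraction,
    normalize_to_hounsfield,
    segment_body,
    segment_fat,
)
from adipophen.errors import (
    InvalidCalibrationError,
    NoBodyFoundError,
    UndefinedFractionError,
)
from adipophen.volume import BinaryMask, MaskRole, Modality, VoxelVolume

SP = (0.2, 0.2, 0.2)


def _mask(data, role=MaskRole.BODY):
    return BinaryMask(data, role, SP)


class TestNormalizeToHounsfield:
    def test_constant_input_maps_affinely(self):
        vol = normalize_to_hounsfield(np.zeros((4, 4, 4)), 1.0, -1000.0, SP)
        assert vol.modality is Modality.CT_HU
        assert np.all(vol.data == -1000.0)

    def test_identity_calibration(self, rng):
        raw = rng.normal(size=(5, 6, 7))
        vol = normalize_to_hounsfield(raw, 1.0, 0.0, SP)
        np.testing.assert_array_equal(vol.data, raw)

    def test_matches_elementwise_oracle(self, rng):
        raw = rng.integers(0, 4096, size=(6, 5, 4)).astype(float)
        vol = normalize_to_hounsfield(raw, 0.5, -1024.0, SP)
        # independent elementwise computation
        oracle = np.array(
            [0.5 * v - 1024.0 for v in raw.ravel()]
        ).reshape(raw.shape)
        np.testing.assert_allclose(vol.data, oracle, rtol=0, atol=1e-12)

    def test_zero_slope_rejected(self):
        with pytest.raises(InvalidCalibrationError):
            normalize_to_hounsfield(np.zeros((2, 2, 2)), 0.0, 0.0, SP)


class TestSegmentBody:
    def test_all_air_raises(self):
        vol = VoxelVolume(np.full((8, 8, 8), -1000.0), SP)
        with pytest.raises(NoBodyFoundError):
            segment_body(vol)

    def test_ellipsoid_recovered_within_surface_band(self):
        shape = (40, 40, 40)
        grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
        truth = sum(((g - 19.5) / 14.0) ** 2 for g in grids) <= 1.0
        vol = VoxelVolume(np.where(truth, 0.0, -1000.0), SP)
        body = segment_body(vol).data
        surface = truth & ~ndi.binary_erosion(truth)
        n_mismatch = int((body ^ truth).sum())
        assert n_mismatch <= int(surface.sum())

    def test_largest_component_only(self):
        data = np.full((40, 40, 40), -1000.0)
        grids = np.ogrid[:40, :40, :40]
        ellipsoid = sum(((g - 19.5) / 12.0) ** 2 for g in grids) <= 1.0
        data[ellipsoid] = 0.0
        data[2:6, 2:6, 2:6] = 0.0  # separate small cube
        body = segment_body(VoxelVolume(data, SP)).data
        assert not body[2:6, 2:6, 2:6].any()
        assert body[20, 20, 20]


class TestSegmentFat:
    def test_uniform_soft_tissue_is_fat_away_from_air(self):
        # 0 HU lies inside the fat window; with no internal air the only
        # exclusion is the partial-volume band where exterior air grows
        # 3 voxels into the body surface
        data = np.full((20, 20, 20), -1000.0)
        data[5:15, 5:15, 5:15] = 0.0
        vol = VoxelVolume(data, SP)
        body = _mask(data > -700.0)
        seg = segment_fat(vol, body, FatSegmentationParams(min_object_voxels=1))
        halo = ndi.binary_dilation(
            data < -250.0, ndi.generate_binary_structure(3, 1), iterations=3
        )
        np.testing.assert_array_equal(seg.fat.data, body.data & ~halo)

    def test_dense_tissue_yields_empty_fat(self):
        data = np.full((20, 20, 20), -1000.0)
        data[5:15, 5:15, 5:15] = 200.0
        vol = VoxelVolume(data, SP)
        seg = segment_fat(vol, _mask(data > -700.0))
        assert seg.fat.is_empty()

    def test_empty_body_rejected(self):
        vol = VoxelVolume(np.zeros((4, 4, 4)), SP)
        with pytest.raises(NoBodyFoundError):
            segment_fat(vol, _mask(np.zeros((4, 4, 4), bool)))

    def test_phantom_fat_mask_overlap(self):
        ph = synthetic.make_ct_phantom(
            fat_fraction=0.30, noise_sigma_hu=0.0, seed=0, geometry_seed=3
        )
        _, body, seg = analyze_ct(ph.volume)
        inter = (seg.fat.data & ph.fat.data).sum()
        union = (seg.fat.data | ph.fat.data).sum()
        assert inter / union >= 0.95

    def test_fat_respects_containment_and_air_exclusion(self, ct_phantom):
        _, body, seg = analyze_ct(ct_phantom.volume)
        assert not (seg.fat.data & ~body.data).any()
        assert not (seg.fat.data & seg.excluded).any()
        assert not (seg.fat.data & seg.air.data).any()

    def test_lung_is_largest_interior_air_region(self, ct_phantom):
        _, _, seg = analyze_ct(ct_phantom.volume)
        # recovered lung overlaps the true lung and stays inside the body
        overlap = (seg.lung.data & ct_phantom.lung.data).sum()
        assert overlap / ct_phantom.lung.count() > 0.9

    def test_widening_fat_window_is_monotone(self, ct_phantom):
        vol = ct_phantom.volume
        body = segment_body(vol)
        pcts = []
        for hi in (0.0, 50.0, 120.0):
            seg = segment_fat(vol, body, FatSegmentationParams(fat_range_hu=(-250.0, hi)))
            res = compute_fat_fraction(seg.fat, body, seg.air, vol.spacing)
            pcts.append(res.percent_fat)
        assert pcts[0] <= pcts[1] <= pcts[2]


class TestComputeFatFraction:
    def test_full_coverage_is_100(self):
        ones = np.ones((4, 4, 4), bool)
        res = compute_fat_fraction(
            _mask(ones, MaskRole.FAT_FINAL),
            _mask(ones),
            _mask(np.zeros_like(ones), MaskRole.AIR),
            SP,
        )
        assert res.percent_fat == 100.0
        assert res.voxel_volume_mm3 == pytest.approx(0.008)

    def test_empty_fat_is_0(self):
        ones = np.ones((4, 4, 4), bool)
        res = compute_fat_fraction(
            _mask(np.zeros_like(ones), MaskRole.FAT_FINAL),
            _mask(ones),
            _mask(np.zeros_like(ones), MaskRole.AIR),
            SP,
        )
        assert res.percent_fat == 0.0

    def test_empty_denominator_raises(self):
        zeros = np.zeros((4, 4, 4), bool)
        with pytest.raises(UndefinedFractionError):
            compute_fat_fraction(
                _mask(zeros, MaskRole.FAT_FINAL), _mask(zeros),
                _mask(zeros, MaskRole.AIR), SP,
            )

    def test_phantom_recovery_within_2_points_low_noise(self):
        ph = synthetic.make_ct_phantom(
            fat_fraction=0.30, noise_sigma_hu=5.0, seed=9, geometry_seed=2
        )
        res, _, _ = analyze_ct(ph.volume)
        assert abs(res.percent_fat - ph.true_percent_fat) <= 2.0


class TestGeometricInvariance:
    def test_percent_fat_invariant_under_rotations_and_flips(self):
        ph = synthetic.make_ct_phantom(
            fat_fraction=0.25, noise_sigma_hu=5.0, shape=(64, 64, 64), seed=3,
            geometry_seed=4,
        )
        base, _, _ = analyze_ct(ph.volume)
        for transform in (
            lambda d: np.rot90(d, k=1, axes=(1, 2)),
            lambda d: np.rot90(d, k=1, axes=(0, 2)),
            lambda d: d[::-1],
            lambda d: d[:, ::-1, ::-1],
        ):
            vol = VoxelVolume(transform(ph.volume.data).copy(), ph.volume.spacing)
            res, _, _ = analyze_ct(vol)
            assert res.percent_fat == pytest.approx(base.percent_fat, abs=1e-9)


def test_partial_volume_correction_reduces_error():
    """On interface-blurred phantoms with lung cavities, masking dilated air
    must bring the estimate closer to truth than leaving it uncorrected."""
    for seed in (1, 2):
        ph = synthetic.make_ct_phantom(
            fat_fraction=0.2, noise_sigma_hu=5.0, interface_blur_vox=1.0,
            seed=seed, geometry_seed=seed,
        )
        corrected, _, _ = analyze_ct(ph.volume)
        uncorrected, _, _ = analyze_ct(
            ph.volume, params=FatSegmentationParams(pv_correction=False)
        )
        err_c = abs(corrected.percent_fat - ph.true_percent_fat)
        err_u = abs(uncorrected.percent_fat - ph.true_percent_fat)
        assert err_c < err_u
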