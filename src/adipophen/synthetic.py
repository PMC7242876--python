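"""Ground-truth-known synthetic inputs for every pipeline stage.

Each generator is a pure function of its parameters and seed, and returns
the rendered data *together with* the ground truth it was built from
(masks, per-cell areas, stained fractions, phase means, fold changes), so
recovery can be scored without ever re-reading truth off the rendered data.

Geometry of the imaging phantoms is controlled by a ``geometry_seed``
separate from the noise ``seed``: two phantoms with the same geometry but
different noise share identical true masks.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .calorimetry import CalorimetryTrace
from .errors import PhantomError
from .expression import CONTROL, TEST, CtTable, DensitometryTable
from .histology import FieldImage, Stain
from .pet import ContourSet, GammaCountRecord
from .volume import BinaryMask, MaskRole, Modality, VoxelVolume

# ---------------------------------------------------------------------------
# whole-body CT phantom
# ---------------------------------------------------------------------------


@dataclass
class CtPhantom:
    """A rodent whole-body CT phantom with exact truth masks.

    The body is a soft-tissue ellipsoid (60 HU) in an air background
    (-1000 HU) with two lung cavities (-900 HU) and fat depots (-100 HU)
    grown from compact anatomical sites until the requested fraction of the
    air-excluded body volume is reached.  True percent fat is computed from
    the generated masks, before any blurring or noise.
    """

    volume: VoxelVolume
    body: BinaryMask
    fat: BinaryMask
    lung: BinaryMask
    true_percent_fat: float
    requested_fat_fraction: float
    noise_sigma_hu: float
    seed: int


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    m = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return m <= 1.0


def make_ct_phantom(
    fat_fraction: float = 0.30,
    shape: tuple[int, int, int] = (128, 96, 96),
    spacing: tuple[float, float, float] = (0.2, 0.2, 0.2),
    noise_sigma_hu: float = 20.0,
    interface_blur_vox: float = 0.0,
    with_lungs: bool = True,
    with_bed: bool = False,
    seed: int = 0,
    geometry_seed: int = 0,
    hu_tissue: float = 60.0,
    hu_fat: float = -100.0,
    hu_lung: float = -900.0,
    hu_background: float = -1000.0,
    rind_vox: float = 5.0,
    lung_margin_vox: float = 8.0,
) -> CtPhantom:
    """Build a CT phantom whose true fat fraction matches the request exactly
    (to within tie-breaking on one voxel).

    ``rind_vox`` keeps a skin-like soft-tissue layer between the body surface
    and any fat, and ``lung_margin_vox`` keeps fat clear of the lung
    cavities, so the partial-volume exclusion dilations never remove true
    fat.  ``interface_blur_vox`` optionally smooths the rendered phantom to
    emulate scanner partial-volume blur at air/tissue interfaces.
    """
    if not (0.0 <= fat_fraction < 0.6):
        raise PhantomError(f"fat fraction {fat_fraction} outside [0, 0.6)")
    nz, ny, nx = shape
    center = tuple((s - 1) / 2.0 for s in shape)
    semi = (0.41 * nz, 0.40 * ny, 0.40 * nx)
    body = _ellipsoid(shape, center, semi)

    lung = np.zeros(shape, dtype=bool)
    if with_lungs:
        lsemi = (0.07 * nz, 0.0625 * ny, 0.0625 * nx)
        for dy in (+0.35, -0.35):
            lc = (center[0] + 0.35 * semi[0], center[1] + dy * semi[1], center[2])
            lung |= _ellipsoid(shape, lc, lsemi)
        # airway bridge joining the two lobes into one air region
        bc = (center[0] + 0.35 * semi[0], center[1], center[2])
        lung |= _ellipsoid(shape, bc, (0.02 * nz, 0.30 * semi[1], 0.03 * nx))

    depth = ndi.distance_transform_edt(body)
    lung_dist = ndi.distance_transform_edt(~lung) if lung.any() else np.full(shape, np.inf)
    eligible = (depth > rind_vox) & (lung_dist > lung_margin_vox)

    denom = int(body.sum()) - int(lung.sum())
    target = int(round(fat_fraction * denom))
    if target > int(eligible.sum()):
        raise PhantomError(
            f"fat fraction {fat_fraction} unattainable: needs {target} voxels, "
            f"only {int(eligible.sum())} eligible"
        )

    fat = np.zeros(shape, dtype=bool)
    if target > 0:
        rng_geo = np.random.default_rng(geometry_seed)
        # compact depot sites in normalised body coordinates (z, y, x)
        sites = np.array(
            [
                (-0.50, 0.00, 0.00),
                (-0.15, 0.45, 0.00),
                (-0.15, -0.45, 0.00),
                (0.25, 0.00, 0.45),
                (0.25, 0.00, -0.45),
            ]
        )
        sites = sites + rng_geo.uniform(-0.06, 0.06, sites.shape)
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        metric = np.full(shape, np.inf)
        for k, u in enumerate(sites):
            depot_center = [c + ui * a for c, ui, a in zip(center, u, semi)]
            aspect = np.array([1.4, 1.0, 1.0]) * rng_geo.uniform(0.85, 1.2, 3)
            m = sum(
                ((g - c) / b) ** 2 for g, c, b in zip(grids, depot_center, aspect)
            )
            np.minimum(metric, m, out=metric)
        vals = np.sort(metric[eligible])
        cut = vals[target - 1]
        fat = eligible & (metric <= cut)

    true_pct = 100.0 * int(fat.sum()) / denom

    vol = np.full(shape, hu_background, dtype=np.float64)
    vol[body] = hu_tissue
    vol[fat] = hu_fat
    vol[lung] = hu_lung
    if with_bed:
        # a foam bed slab below the animal, detached from the body
        y0 = int(center[1] + semi[1]) + 4
        if y0 + 4 < ny:
            vol[:, y0 : y0 + 4, nx // 4 : 3 * nx // 4] = -150.0
    if interface_blur_vox > 0:
        vol = ndi.gaussian_filter(vol, interface_blur_vox)
    if noise_sigma_hu > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sigma_hu, shape)

    return CtPhantom(
        volume=VoxelVolume(vol.astype(np.float32), spacing, Modality.CT_HU),
        body=BinaryMask(body, MaskRole.BODY, spacing),
        fat=BinaryMask(fat, MaskRole.FAT_FINAL, spacing),
        lung=BinaryMask(lung, MaskRole.LUNG, spacing),
        true_percent_fat=true_pct,
        requested_fat_fraction=fat_fraction,
        noise_sigma_hu=noise_sigma_hu,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# adipocyte mosaic
# ---------------------------------------------------------------------------


@dataclass
class MosaicPhantom:
    """A space-filling adipocyte mosaic with exact per-cell lumen areas.

    Cells tile the field periodically (a torus), so no cell is clipped by
    the frame and the lumen areas partition the field together with the
    membrane pixels.  ``interior_ids`` lists cells that do not touch the
    frame, for comparisons against border-excluding segmentation.
    """

    field: FieldImage
    labels: np.ndarray
    membrane: np.ndarray
    true_areas_um2: np.ndarray  # indexed by cell id - 1
    interior_ids: np.ndarray
    mean_area_requested_um2: float

    def interior_truth_areas(self, min_area_um2: float = 0.0) -> np.ndarray:
        """True lumen areas of cells that never touch the frame, optionally
        floored the same way a segmenter's minimum-area filter would."""
        areas = self.true_areas_um2[self.interior_ids - 1]
        return areas[areas >= min_area_um2]

    def interior_estimated_areas(
        self, seg_labels: np.ndarray, pixel_size_um: float
    ) -> np.ndarray:
        """Areas of segmented components belonging to interior cells.

        A segmented lumen component inherits the phantom cell id under it;
        components over frame-touching cells are dropped so estimates and
        truth cover the same cell population.
        """
        comp_ids, first = np.unique(seg_labels, return_index=True)
        keep_cells = np.zeros(self.labels.max() + 1, dtype=bool)
        keep_cells[self.interior_ids] = True
        counts = np.bincount(seg_labels.ravel())
        areas = []
        for comp, idx in zip(comp_ids, first):
            if comp == 0:
                continue
            cell = self.labels.ravel()[idx]
            if keep_cells[cell]:
                areas.append(counts[comp] * pixel_size_um**2)
        return np.asarray(areas, dtype=np.float64)


def _periodic_power_labels(
    side: int, points: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Power-diagram labels on a periodic square via the 3-D lifting trick."""
    offsets = np.array([(dy, dx) for dy in (-side, 0, side) for dx in (-side, 0, side)])
    sites = (points[None, :, :] + offsets[:, None, :]).reshape(-1, 2)
    w_rep = np.tile(weights, len(offsets))
    lift = np.sqrt(w_rep.max() - w_rep + 1.0)
    tree = cKDTree(np.column_stack([sites, lift]))
    yy, xx = np.mgrid[0:side, 0:side]
    q = np.column_stack([yy.ravel(), xx.ravel(), np.zeros(side * side)])
    _, idx = tree.query(q, workers=-1)
    return (idx % len(points)).reshape(side, side).astype(np.int32) + 1


def make_adipocyte_mosaic(
    n_cells: int = 300,
    mean_area_um2: float = 3000.0,
    sigma_log: float = 0.5,
    pixel_size_um: float = 1.0,
    membrane_width_px: int = 2,
    lumen_intensity: float = 230.0,
    membrane_intensity: float = 60.0,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> MosaicPhantom:
    """Tessellate a field into ``n_cells`` polygonal adipocytes whose lumen
    areas follow a lognormal law with the requested mean (µm²)."""
    if n_cells < 1:
        raise PhantomError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    mean_px = mean_area_um2 / pixel_size_um**2
    mu = np.log(mean_px) - sigma_log**2 / 2.0
    lumen_targets = rng.lognormal(mu, sigma_log, n_cells)
    # inflate polygon targets so the lumen (polygon minus half-membrane ring)
    # hits the requested area; 4*sqrt(A) approximates an irregular perimeter
    poly_targets = lumen_targets + 4.0 * np.sqrt(lumen_targets) * membrane_width_px / 2.0
    if np.sqrt(poly_targets.min()) < 2.5 * membrane_width_px:
        raise PhantomError("cells too small for the membrane width")
    side = int(round(np.sqrt(poly_targets.sum())))

    # dart-throwing seed placement with periodic distances
    radii = np.sqrt(poly_targets / np.pi)
    order = np.argsort(-radii)
    points = np.zeros((n_cells, 2))
    placed: list[int] = []
    for k in order:
        best, best_score = None, -np.inf
        for _ in range(60):
            cand = rng.uniform(0, side, 2)
            if not placed:
                best = cand
                break
            d = np.abs(points[placed] - cand)
            d = np.minimum(d, side - d)
            gap = np.hypot(d[:, 0], d[:, 1]) - 0.7 * (radii[placed] + radii[k])
            score = gap.min()
            if score > best_score:
                best, best_score = cand, score
            if score > 0:
                break
        points[k] = best
        placed.append(k)

    def tessellate(side_px: int, pts: np.ndarray, targets: np.ndarray):
        weights = targets / np.pi
        labels = _periodic_power_labels(side_px, pts, weights)
        for _ in range(2):  # capacity correction toward the target areas
            areas = np.bincount(labels.ravel(), minlength=n_cells + 1)[1:]
            weights = weights + 0.9 * (targets - areas) / np.pi
            labels = _periodic_power_labels(side_px, pts, weights)
        band = ndi.maximum_filter(labels, size=3) != ndi.minimum_filter(labels, size=3)
        extra = max(0, (membrane_width_px - 2) // 2)
        if extra:
            band = ndi.binary_dilation(band, np.ones((3, 3), bool), iterations=extra)
        lumen = np.bincount(labels[~band].ravel(), minlength=n_cells + 1)[1:]
        return labels, band, lumen.astype(np.float64)

    labels, membrane, lumen_counts = tessellate(side, points, poly_targets)
    # the analytic perimeter estimate under-corrects for irregular cells, so
    # recalibrate the polygon targets from the measured membrane loss and
    # tessellate once more on a rescaled field
    deficit = lumen_targets - lumen_counts
    poly_targets = np.maximum(poly_targets + deficit, (2.5 * membrane_width_px) ** 2)
    side2 = int(round(np.sqrt(poly_targets.sum())))
    points = points * (side2 / side)
    side = side2
    labels, membrane, lumen_counts = tessellate(side, points, poly_targets)

    true_areas = lumen_counts * pixel_size_um**2

    border = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    interior = np.setdiff1d(np.arange(1, n_cells + 1), border)

    gray = np.where(membrane, membrane_intensity, lumen_intensity).astype(np.float64)
    if noise_sd > 0:
        gray = gray + rng.normal(0.0, noise_sd, gray.shape)
    gray = np.clip(gray, 0, 255)
    rgb = np.stack([gray, gray * 0.88, gray * 0.94], axis=-1)  # eosin-like tint
    pixels = np.clip(rgb, 0, 255).astype(np.uint8)

    return MosaicPhantom(
        field=FieldImage(pixels, pixel_size_um, Stain.HE, magnification="20X"),
        labels=labels,
        membrane=membrane,
        true_areas_um2=true_areas,
        interior_ids=interior,
        mean_area_requested_um2=mean_area_um2,
    )


# ---------------------------------------------------------------------------
# stained fields (PSR / DAB)
# ---------------------------------------------------------------------------


@dataclass
class StainFieldPhantom:
    field: FieldImage
    stained_mask: np.ndarray
    true_percent_stained: float


_STAIN_COLORS = {
    Stain.PSR: ((190, 30, 35), (232, 196, 110)),  # sirius red on picric yellow
    Stain.DAB: ((125, 78, 38), (226, 226, 240)),  # DAB brown on hematoxylin
}


def make_stain_field(
    stain: Stain | str = Stain.PSR,
    stained_fraction: float = 0.175,
    shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 1.0,
    blob_scale_px: float = 8.0,
    color_jitter: float = 6.0,
    seed: int = 0,
) -> StainFieldPhantom:
    """A sparsely stained field whose stained-pixel count is exact.

    A smoothed random field is thresholded at the order statistic that
    yields exactly ``round(fraction * n_pixels)`` stained pixels, giving
    organic blob shapes with an exactly known stained fraction.
    """
    stain = Stain(stain)
    if stain not in _STAIN_COLORS:
        raise PhantomError(f"no colour scheme for stain {stain}")
    if not (0.0 <= stained_fraction <= 1.0):
        raise PhantomError("stained fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_px = shape[0] * shape[1]
    n_stained = int(round(stained_fraction * n_px))
    if n_stained == 0:
        mask = np.zeros(shape, dtype=bool)
    elif n_stained == n_px:
        mask = np.ones(shape, dtype=bool)
    else:
        fld = ndi.gaussian_filter(rng.standard_normal(shape), blob_scale_px)
        cut = np.partition(fld.ravel(), n_px - n_stained)[n_px - n_stained]
        mask = fld >= cut
        # float ties are vanishingly rare; trim deterministically if any
        excess = int(mask.sum()) - n_stained
        if excess > 0:
            idx = np.flatnonzero(fld.ravel() == cut)[:excess]
            mask.ravel()[idx] = False

    fg, bg = _STAIN_COLORS[stain]
    img = np.empty((*shape, 3), dtype=np.float64)
    img[...] = bg
    img[mask] = fg
    if color_jitter > 0:
        img = img + rng.uniform(-color_jitter, color_jitter, img.shape)
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return StainFieldPhantom(
        field=FieldImage(pixels, pixel_size_um, stain),
        stained_mask=mask,
        true_percent_stained=100.0 * int(mask.sum()) / n_px,
    )


# ---------------------------------------------------------------------------
# PET hot-region phantom
# ---------------------------------------------------------------------------


@dataclass
class PetPhantom:
    """A PET volume with a hot interscapular-fat-like ellipsoid.

    Contours trace the true ellipsoid every ``contour_step`` slices, as a
    hand contourer would; the true %ID/g comes from the noiseless
    concentrations over the true mask.
    """

    volume: VoxelVolume
    contours: ContourSet
    true_mask: BinaryMask
    injected_dose: float
    true_percent_id_per_g: float


def make_pet_phantom(
    hot_concentration: float = 5.0,
    background_concentration: float = 0.5,
    injected_dose: float = 100.0,
    shape: tuple[int, int, int] = (40, 64, 64),
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4),
    semi_axes_vox: tuple[float, float, float] = (12.0, 14.0, 11.0),
    contour_step: int = 3,
    noise_sd: float = 0.05,
    noise_model: str = "gaussian",
    seed: int = 0,
    geometry_seed: int = 0,
) -> PetPhantom:
    """Hot ellipsoid of known activity concentration in a warm background."""
    nz, ny, nx = shape
    rng_geo = np.random.default_rng(geometry_seed)
    center = np.array([(s - 1) / 2.0 for s in shape]) + rng_geo.uniform(-1.0, 1.0, 3)
    semi = np.asarray(semi_axes_vox, dtype=np.float64)
    if np.any(center - semi < 1) or np.any(center + semi > np.array(shape) - 2):
        raise PhantomError("hot ellipsoid does not fit inside the grid")
    mask = _ellipsoid(shape, center, semi)

    vol = np.full(shape, background_concentration, dtype=np.float64)
    vol[mask] = hot_concentration
    true_pid = 100.0 * float(vol[mask].mean()) / injected_dose

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        if noise_model == "gaussian":
            vol = vol + rng.normal(0.0, noise_sd, shape)
        elif noise_model == "poisson":
            scale = 1.0 / noise_sd**2  # counts per concentration unit
            vol = rng.poisson(np.maximum(vol, 0) * scale) / scale
        else:
            raise PhantomError(f"unknown noise model {noise_model!r}")

    cz, cy, cx = center
    az, ay, ax = semi
    z_lo = int(np.ceil(cz - az))
    z_hi = int(np.floor(cz + az))
    theta = np.linspace(0.0, 2.0 * np.pi, 48, endpoint=False)
    contour_list = []
    slice_ids = sorted(set(range(z_lo, z_hi + 1, contour_step)) | {z_hi})
    for z in slice_ids:
        u = 1.0 - ((z - cz) / az) ** 2
        if u <= 0:
            continue
        ry, rx = ay * np.sqrt(u), ax * np.sqrt(u)
        if min(ry, rx) < 1.0:
            continue
        verts = np.column_stack(
            [
                (cy + ry * np.cos(theta)) * spacing[1],
                (cx + rx * np.sin(theta)) * spacing[2],
            ]
        )
        contour_list.append((z, verts))
    if len(contour_list) < 2:
        raise PhantomError("ellipsoid too small to trace two contours")

    return PetPhantom(
        volume=VoxelVolume(vol.astype(np.float32), spacing, Modality.PET_ACTIVITY),
        contours=ContourSet(contour_list, spacing),
        true_mask=BinaryMask(mask, MaskRole.ROI, spacing),
        injected_dose=injected_dose,
        true_percent_id_per_g=true_pid,
    )


def make_gamma_records(
    true_percent_id_per_g: dict[str, float],
    injected_counts: float = 1.0e6,
    tissue_weight_g: dict[str, float] | None = None,
    measurement_cv: float = 0.02,
    seed: int = 0,
) -> tuple[list[GammaCountRecord], dict[str, float]]:
    """Scintillation-count records consistent with known per-tissue %ID/g."""
    rng = np.random.default_rng(seed)
    weights = tissue_weight_g or {t: 0.2 for t in true_percent_id_per_g}
    records = []
    for tissue, pid in true_percent_id_per_g.items():
        w = weights[tissue]
        counts = pid / 100.0 * injected_counts * w
        counts *= max(0.0, 1.0 + rng.normal(0.0, measurement_cv))
        records.append(
            GammaCountRecord(
                tissue=tissue,
                counts=counts,
                tissue_weight_g=w,
                injected_counts=injected_counts,
            )
        )
    return records, dict(true_percent_id_per_g)


# ---------------------------------------------------------------------------
# indirect-calorimetry trace
# ---------------------------------------------------------------------------


@dataclass
class ClamsPhantom:
    trace: CalorimetryTrace
    true_means: dict[str, dict[str, float]]  # phase -> {vo2, vco2, rer}


def make_clams_trace(
    hours: float = 48.0,
    cadence_min: float = 10.0,
    lights_on: dt.time = dt.time(6, 0),
    lights_off: dt.time = dt.time(18, 0),
    vo2_diurnal: float = 2800.0,
    vo2_nocturnal: float = 3400.0,
    rer_diurnal: float = 0.78,
    rer_nocturnal: float = 0.88,
    modulation_amplitude: float = 150.0,
    noise_sd: float = 0.0,
    activity_rate_diurnal: float = 5.0,
    activity_rate_nocturnal: float = 25.0,
    food_rate_g_h_nocturnal: float = 0.25,
    body_mass_g: float = 32.0,
    start: dt.datetime = dt.datetime(2020, 1, 1, 0, 0),
    seed: int = 0,
) -> ClamsPhantom:
    """Two-phase respirometry trace whose per-phase means are exact.

    VO2 is a phase-specific constant plus a sinusoidal modulation completing
    whole cycles within each 12 h phase, so the phase mean equals the
    constant exactly when noise is zero.  VCO2 is the phase RER times VO2
    pointwise.
    """
    rng = np.random.default_rng(seed)
    n = int(round(hours * 60.0 / cadence_min))
    ts = pd.date_range(start, periods=n, freq=pd.Timedelta(minutes=cadence_min))
    sec = (
        ts.hour.to_numpy() * 3600 + ts.minute.to_numpy() * 60 + ts.second.to_numpy()
    ).astype(np.float64)
    s_on = lights_on.hour * 3600 + lights_on.minute * 60
    s_off = lights_off.hour * 3600 + lights_off.minute * 60
    if s_on < s_off:
        diurnal = (sec >= s_on) & (sec < s_off)
    else:
        diurnal = (sec >= s_on) | (sec < s_off)

    phase_len_h = 12.0
    t_in_phase = np.where(
        diurnal, (sec - s_on) % 86400, (sec - s_off) % 86400
    ) / 3600.0
    mod = modulation_amplitude * np.sin(2.0 * np.pi * 2.0 * t_in_phase / phase_len_h)
    vo2 = np.where(diurnal, vo2_diurnal, vo2_nocturnal) + mod
    rer = np.where(diurnal, rer_diurnal, rer_nocturnal)
    vco2 = rer * vo2
    if noise_sd > 0:
        vo2 = vo2 + rng.normal(0.0, noise_sd, n)
        vco2 = vco2 + rng.normal(0.0, noise_sd, n)
    vo2 = np.maximum(vo2, 1.0)
    vco2 = np.maximum(vco2, 1.0)

    activity = rng.poisson(np.where(diurnal, activity_rate_diurnal, activity_rate_nocturnal))
    food_increment = np.where(diurnal, 0.02, food_rate_g_h_nocturnal) * cadence_min / 60.0
    food = np.cumsum(food_increment)

    trace = CalorimetryTrace(
        samples=pd.DataFrame(
            {
                "timestamp": ts,
                "vo2": vo2,
                "vco2": vco2,
                "activity_counts": activity,
                "food_g": food,
            }
        ),
        light_schedule=(lights_on, lights_off),
        body_mass_g=body_mass_g,
    )
    true_means = {
        "diurnal": {"vo2": vo2_diurnal, "vco2": rer_diurnal * vo2_diurnal, "rer": rer_diurnal},
        "nocturnal": {
            "vo2": vo2_nocturnal,
            "vco2": rer_nocturnal * vo2_nocturnal,
            "rer": rer_nocturnal,
        },
    }
    return ClamsPhantom(trace=trace, true_means=true_means)


# ---------------------------------------------------------------------------
# qPCR and densitometry tables
# ---------------------------------------------------------------------------


@dataclass
class QpcrPhantom:
    table: CtTable
    true_fold_changes: dict[str, float]


def make_ct_qpcr_table(
    fold_changes: dict[str, float] | None = None,
    n_control: int = 6,
    n_test: int = 6,
    reference_gene: str = "18s",
    ct_reference: float = 12.0,
    delta_ct_base: float = 10.0,
    sample_jitter_sd: float = 0.5,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
) -> QpcrPhantom:
    """Ct table in which each target gene has a specified true fold change.

    Control samples carry dCt = delta_ct_base; test samples carry
    dCt = delta_ct_base - log2(fold).  A per-sample jitter shifts the
    reference and target Ct together (it cancels in dCt); ``ct_noise_sd``
    adds independent technical noise per measurement.
    """
    folds = fold_changes if fold_changes is not None else {"ucp1": 10.0}
    rng = np.random.default_rng(seed)
    rows = []
    samples = [(f"C{i+1}", CONTROL) for i in range(n_control)] + [
        (f"T{i+1}", TEST) for i in range(n_test)
    ]
    for sample_id, group in samples:
        jitter = rng.normal(0.0, sample_jitter_sd)
        ct_ref = ct_reference + jitter
        if ct_noise_sd > 0:
            ct_ref += rng.normal(0.0, ct_noise_sd)
        rows.append((sample_id, group, reference_gene, ct_ref))
        for gene, fold in folds.items():
            dct = delta_ct_base if group == CONTROL else delta_ct_base - np.log2(fold)
            ct = ct_reference + jitter + dct
            if ct_noise_sd > 0:
                ct += rng.normal(0.0, ct_noise_sd)
            rows.append((sample_id, group, gene, ct))
    table = CtTable(
        pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"]),
        reference_gene=reference_gene,
    )
    return QpcrPhantom(table=table, true_fold_changes=dict(folds))


@dataclass
class DensitometryPhantom:
    table: DensitometryTable
    true_idv: dict[str, dict[str, float]]  # protein -> group -> normalised IDV


def make_densitometry_table(
    proteins: dict[str, tuple[float, float]] | None = None,
    n_per_group: int = 6,
    loading_control: str = "beta-actin",
    actin_intensity: float = 1000.0,
    lane_jitter_cv: float = 0.1,
    measurement_cv: float = 0.0,
    seed: int = 0,
) -> DensitometryPhantom:
    """Blot table with known loading-normalised IDV per protein and group.

    ``proteins`` maps protein -> (control IDV, test IDV).  Lane-to-lane
    loading varies by ``lane_jitter_cv`` but cancels in the normalised
    ratio; ``measurement_cv`` adds band-level noise that does not.
    """
    prots = proteins if proteins is not None else {"ddr1": (1.0, 2.5)}
    rng = np.random.default_rng(seed)
    rows = []
    for g_idx, group in enumerate((CONTROL, TEST)):
        for i in range(n_per_group):
            lane = f"{group[0].upper()}{i+1}"
            actin = actin_intensity * (1.0 + rng.normal(0.0, lane_jitter_cv))
            rows.append((lane, group, loading_control, actin))
            for protein, (idv_c, idv_t) in prots.items():
                idv = (idv_c, idv_t)[g_idx]
                band = idv * actin
                if measurement_cv > 0:
                    band *= max(0.0, 1.0 + rng.normal(0.0, measurement_cv))
                rows.append((lane, group, protein, band))
    table = DensitometryTable(
        pd.DataFrame(rows, columns=["lane_id", "group", "protein", "intensity"]),
        loading_control=loading_control,
    )
    true_idv = {
        p: {CONTROL: c, TEST: t} for p, (c, t) in prots.items()
    }
    return DensitometryPhantom(table=table, true_idv=true_idv)
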