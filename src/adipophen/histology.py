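"""Adipocyte morphometry and stain %-area quantification on 2-D fields.

H&E fields are converted to grayscale and contrast-stretched so that cell
lumina (bright) separate from membranes (dark); thresholding the white
channel yields one connected component per adipocyte whose pixel area,
scaled by the pixel size, gives the cell cross-section in µm².  Collagen
(picrosirius red) and UCP-1 (DAB, brown) staining are quantified as the
percentage of ROI pixels matching an explicit, overridable HSV colour rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.segmentation import clear_border

from .errors import UndefinedFractionError


class Stain(str, Enum):
    HE = "HE"
    PSR = "PSR"
    DAB = "DAB"


@dataclass
class FieldImage:
    """A 2-D RGB histology field with physical pixel size in µm."""

    pixels: np.ndarray
    pixel_size_um: float
    stain: Stain = Stain.HE
    magnification: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("FieldImage requires an (H, W, 3) RGB array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.stain = Stain(self.stain)


@dataclass(frozen=True)
class SizeDistribution:
    """Binned adipocyte cross-section areas."""

    cell_areas_um2: np.ndarray
    bin_edges_um2: np.ndarray
    counts: np.ndarray
    proportions: np.ndarray
    mean_area_um2: float
    overflow_count: int = 0

    @property
    def n_cells(self) -> int:
        return int(len(self.cell_areas_um2))


@dataclass(frozen=True)
class StainAreaResult:
    roi_area_px: int
    stained_area_px: int
    percent_stained: float


@dataclass(frozen=True)
class StainRule:
    """HSV colour predicate: hue window in degrees (wrapping past 360 allowed),
    minimum saturation and value in [0, 1]."""

    hue_low_deg: float
    hue_high_deg: float
    s_min: float
    v_min: float

    def __call__(self, rgb: np.ndarray) -> np.ndarray:
        hsv = rgb2hsv(np.asarray(rgb, dtype=np.float64) / 255.0)
        hue = hsv[..., 0] * 360.0
        lo, hi = self.hue_low_deg % 360.0, self.hue_high_deg % 360.0
        if lo <= hi:
            in_hue = (hue >= lo) & (hue <= hi)
        else:  # wrapped window, e.g. 340..20
            in_hue = (hue >= lo) | (hue <= hi)
        return in_hue & (hsv[..., 1] >= self.s_min) & (hsv[..., 2] >= self.v_min)


#: red rule for picrosirius-red collagen staining
PSR_RED_RULE = StainRule(hue_low_deg=-20.0, hue_high_deg=20.0, s_min=0.3, v_min=0.2)
#: brown rule for DAB (UCP-1) immunostaining
DAB_BROWN_RULE = StainRule(hue_low_deg=10.0, hue_high_deg=45.0, s_min=0.25, v_min=0.15)

DEFAULT_STAIN_RULES: dict[Stain, StainRule] = {
    Stain.PSR: PSR_RED_RULE,
    Stain.DAB: DAB_BROWN_RULE,
}


def preprocess_he(
    field: FieldImage,
    p_low: float = 1.0,
    p_high: float = 99.0,
) -> np.ndarray:
    """Luminance conversion followed by linear contrast stretching.

    The (p_low, p_high) intensity percentiles map to 0 and 255; values
    outside are clipped.  A constant image is returned unchanged with a
    warning, since the stretch is undefined.
    """
    if field.stain is not Stain.HE:
        raise ValueError("preprocess_he expects an H&E field")
    rgb = field.pixels.astype(np.float64)
    gray = 0.2125 * rgb[..., 0] + 0.7154 * rgb[..., 1] + 0.0721 * rgb[..., 2]
    lo, hi = np.percentile(gray, [p_low, p_high])
    if hi <= lo:
        warnings.warn("constant image: contrast stretch skipped", stacklevel=2)
        return gray
    return np.clip((gray - lo) / (hi - lo), 0.0, 1.0) * 255.0


@dataclass
class AdipocyteSegmentation:
    labels: np.ndarray
    areas_um2: np.ndarray
    white_threshold: float


def segment_adipocytes(
    gray: np.ndarray,
    pixel_size_um: float,
    white_threshold: float | None = None,
    min_area_um2: float = 200.0,
    exclude_border: bool = True,
) -> AdipocyteSegmentation:
    """Detect adipocyte lumina by thresholding the white channel.

    Pixels at or above ``white_threshold`` (Otsu's value if None) form
    candidate lumina; 8-connected components smaller than ``min_area_um2``
    are discarded, as are components touching the field border when
    ``exclude_border``.  Areas are pixel counts scaled by the pixel size
    squared.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if white_threshold is None:
        white_threshold = float(threshold_otsu(gray))
    white = gray >= white_threshold
    labels = sk_label(white, connectivity=2)
    if exclude_border:
        labels = clear_border(labels)
    min_px = max(1, int(np.ceil(min_area_um2 / pixel_size_um**2)))
    counts = np.bincount(labels.ravel())
    if len(counts) > 1:
        keep = counts >= min_px
        keep[0] = False
        labels = np.where(keep[labels], labels, 0)
    # compact the label ids after removals
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1)
    labels = remap[labels]
    areas_px = np.bincount(labels.ravel())[1:]
    areas = areas_px.astype(np.float64) * pixel_size_um**2
    if len(areas) == 0:
        warnings.warn("no adipocytes detected", stacklevel=2)
    return AdipocyteSegmentation(labels=labels, areas_um2=areas, white_threshold=white_threshold)


def size_distribution(
    areas_um2: np.ndarray,
    bin_edges_um2: np.ndarray,
) -> SizeDistribution:
    """Bin per-cell areas into half-open ranges ``[e_i, e_{i+1})``.

    The final bin is closed at its upper edge.  Areas falling outside every
    bin land in an overflow count that is reported alongside the bins.
    Proportions are relative to the total cell count, overflow included.
    """
    areas = np.asarray(areas_um2, dtype=np.float64)
    edges = np.asarray(bin_edges_um2, dtype=np.float64)
    if len(areas) == 0:
        raise ValueError("size_distribution requires at least one cell")
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly ascending with >= 2 entries")
    counts, _ = np.histogram(areas, bins=edges)
    overflow = int(((areas < edges[0]) | (areas > edges[-1])).sum())
    if overflow:
        warnings.warn(f"{overflow} cell(s) outside the binning range", stacklevel=2)
    n = len(areas)
    return SizeDistribution(
        cell_areas_um2=areas,
        bin_edges_um2=edges,
        counts=counts,
        proportions=counts / n,
        mean_area_um2=float(areas.mean()),
        overflow_count=overflow,
    )


def quantify_stain_area(
    field: FieldImage,
    roi: np.ndarray | None = None,
    stain_rule: StainRule | None = None,
) -> StainAreaResult:
    """Percent of ROI pixels matching the stain's colour rule."""
    if field.stain not in (Stain.PSR, Stain.DAB):
        raise ValueError("quantify_stain_area expects a PSR or DAB field")
    if roi is None:
        roi = np.ones(field.pixels.shape[:2], dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != field.pixels.shape[:2]:
        raise ValueError("ROI shape must match the field")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise UndefinedFractionError("empty ROI")
    rule = stain_rule or DEFAULT_STAIN_RULES[field.stain]
    stained = rule(field.pixels) & roi
    n_stained = int(stained.sum())
    return StainAreaResult(
        roi_area_px=n_roi,
        stained_area_px=n_stained,
        percent_stained=100.0 * n_stained / n_roi,
    )


def polygon_roi(shape: tuple[int, int], vertices_px: np.ndarray) -> np.ndarray:
    """Rasterize a polygon ROI given ``(row, col)`` vertices in pixels."""
    from skimage.draw import polygon as draw_polygon

    vertices_px = np.asarray(vertices_px, dtype=np.float64)
    rr, cc = draw_polygon(vertices_px[:, 0], vertices_px[:, 1], shape=shape)
    roi = np.zeros(shape, dtype=bool)
    roi[rr, cc] = True
    return roi
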