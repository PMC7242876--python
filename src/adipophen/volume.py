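"""3-D scalar volumes and boolean masks with physical voxel spacing.

Volumes are stored as ``(z, y, x)`` arrays with per-axis spacing in mm.
CT volumes are expressed on the Hounsfield scale (air ~ -1000 HU, water 0 HU);
PET volumes carry an activity concentration (activity per mL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np


class Modality(str, Enum):
    CT_HU = "CT_HU"
    PET_ACTIVITY = "PET_ACTIVITY"


class MaskRole(str, Enum):
    BODY = "BODY"
    AIR = "AIR"
    LUNG = "LUNG"
    FAT_CANDIDATE = "FAT_CANDIDATE"
    FAT_FINAL = "FAT_FINAL"
    ROI = "ROI"


@dataclass
class VoxelVolume:
    """A 3-D scalar grid with voxel spacing ``(dz, dy, dx)`` in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: Modality = Modality.CT_HU

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass
class BinaryMask:
    """A boolean grid aligned voxel-for-voxel with a parent volume."""

    data: np.ndarray
    role: MaskRole
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.role = MaskRole(self.role)
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not bool(self.data.any())


def load_volume(path: str | Path, modality: Modality = Modality.CT_HU) -> VoxelVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    The array is returned in ``(z, y, x)`` order with spacing from the header.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        # NIfTI stores (x, y, z); flip to (z, y, x)
        arr = np.transpose(arr, (2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    elif suffixes.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)  # already (z, y, x)
        sp = img.GetSpacing()  # (x, y, z)
        spacing = (float(sp[2]), float(sp[1]), float(sp[0]))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    return VoxelVolume(arr, spacing, modality)


def save_volume(vol: VoxelVolume | BinaryMask, path: str | Path) -> None:
    """Write a volume or mask to NIfTI or MetaImage, preserving spacing."""
    path = Path(path)
    arr = vol.data
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    suffixes = "".join(path.suffixes).lower()
    dz, dy, dx = vol.spacing
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([dx, dy, dz, 1.0])
        img = nib.Nifti1Image(np.transpose(arr, (2, 1, 0)), affine)
        img.header.set_zooms((dx, dy, dz))
        nib.save(img, str(path))
    elif suffixes.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(arr)
        img.SetSpacing((dx, dy, dz))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
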