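"""NIfTI volume and mask I/O, grid checks, NAWM normalization, Dice agreement.

All downstream stages assume that every map and mask for a subject lives on a
single voxel grid (the co-registration that puts them there is outside the
scope of this package).  The functions here are the gatekeepers: they read
NIfTI-1/2 files with :mod:`nibabel`, carry voxel dimensions and the world
affine along with the data, and refuse mixed grids rather than resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import nibabel as nib
import numpy as np

__all__ = [
    "ParametricVolume",
    "ROIMask",
    "NormalizedMap",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "check_grid_compatibility",
    "normalize_by_nawm",
    "dice",
]

#: Modality tags understood by the pipeline.
MODALITIES = ("ADC", "rCBV", "p", "q", "other")

#: ROI label tags (anatomical inputs plus derived habitat compartments).
ROI_LABELS = (
    "CE",
    "FLAIR",
    "NAWM",
    "rCBV_L",
    "ADC_L",
    "ADC_H",
    "ADC_L-rCBV_L",
    "ADC_H-rCBV_L",
    "CEC",
    "other",
)


@dataclass
class ParametricVolume:
    """A 3D scalar map on a voxel grid.

    Parameters
    ----------
    data : ndarray
        3D floating-point array.  ADC in mm^2/s (or dimensionless after NAWM
        normalization), rCBV dimensionless.
    voxel_dims : tuple of float
        Physical voxel edge lengths in mm, all strictly positive.
    affine : ndarray
        4x4 voxel-to-world transform (preserved on write).
    modality : str
        One of ``ADC, rCBV, p, q, other``.
    """

    data: np.ndarray
    voxel_dims: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    modality: str = "other"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.voxel_dims = tuple(float(d) for d in self.voxel_dims)
        if len(self.voxel_dims) != 3 or any(d <= 0 for d in self.voxel_dims):
            raise ValueError(f"voxel_dims must be three positive lengths, got {self.voxel_dims}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims))


@dataclass
class ROIMask:
    """A binary region-of-interest mask on the same grid as its companion maps."""

    data: np.ndarray
    voxel_dims: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    label: str = "other"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={arr.ndim}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("mask values must be exactly 0 or 1")
            arr = arr.astype(bool)
        self.data = arr
        self.voxel_dims = tuple(float(d) for d in self.voxel_dims)
        if len(self.voxel_dims) != 3 or any(d <= 0 for d in self.voxel_dims):
            raise ValueError(f"voxel_dims must be three positive lengths, got {self.voxel_dims}")
        if self.label not in ROI_LABELS:
            raise ValueError(f"unknown ROI label {self.label!r}")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not self.data.any()


@dataclass
class NormalizedMap:
    """A parametric map divided by its subject's mean value in NAWM.

    The data are dimensionless; by construction the mean over the NAWM mask
    used for normalization is 1.
    """

    data: np.ndarray
    voxel_dims: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    source_modality: str = "other"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.voxel_dims = tuple(float(d) for d in self.voxel_dims)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


GridItem = Union[ParametricVolume, ROIMask, NormalizedMap]


def read_volume(path: str | Path, modality: str = "other") -> ParametricVolume:
    """Read a 3D NIfTI-1/2 scalar map.

    Voxel dimensions come from the header ``pixdim``; data are cast to
    float64.  Raises ``FileNotFoundError`` for a missing file and
    ``ValueError`` for a non-3D image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ParametricVolume(
        data=data.astype(np.float64),
        voxel_dims=zooms,
        affine=np.asarray(img.affine),
        modality=modality,
    )


def write_volume(vol: ParametricVolume | NormalizedMap, path: str | Path) -> None:
    """Write a scalar map as NIfTI, preserving voxel dimensions and affine."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    img.header.set_zooms(vol.voxel_dims)
    nib.save(img, str(path))


def read_mask(path: str | Path, label: str = "other") -> ROIMask:
    """Read a binary mask stored as NIfTI (any nonzero-free 0/1 coding)."""
    vol = read_volume(path)
    return ROIMask(data=vol.data, voxel_dims=vol.voxel_dims, affine=vol.affine, label=label)


def write_mask(mask: ROIMask, path: str | Path) -> None:
    """Write a mask as unsigned 8-bit NIfTI (booleans in memory, uint8 on disk)."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.voxel_dims)
    nib.save(img, str(path))


def check_grid_compatibility(items: Sequence[GridItem], tol_mm: float = 1e-6) -> bool:
    """True iff all volumes/masks share one shape and voxel size (within ``tol_mm``).

    The pipeline treats ``False`` as fatal: inputs are assumed pre-registered
    onto one grid, and mixed grids are refused rather than resampled.
    """
    if len(items) == 0:
        raise ValueError("need at least one volume or mask")
    ref = items[0]
    for item in items[1:]:
        if item.shape != ref.shape:
            return False
        if any(abs(a - b) > tol_mm for a, b in zip(item.voxel_dims, ref.voxel_dims)):
            return False
    return True


def require_compatible(items: Sequence[GridItem], what: str = "inputs") -> None:
    """Raise ``ValueError`` unless all items share one grid."""
    if not check_grid_compatibility(items):
        shapes = [i.shape for i in items]
        dims = [i.voxel_dims for i in items]
        raise ValueError(f"{what} are not on one grid: shapes={shapes}, voxel_dims={dims}")


def normalize_by_nawm(volume: ParametricVolume, nawm: ROIMask) -> NormalizedMap:
    """Divide a parametric map by its mean value in normal-appearing white matter.

    The arithmetic mean over the NAWM mask is used.  The result is
    dimensionless with NAWM mean exactly 1; normalization is invariant to
    rescaling the input by any positive constant.
    """
    require_compatible([volume, nawm], "map and NAWM mask")
    if nawm.is_empty():
        raise ValueError("NAWM mask is empty; cannot normalize")
    vals = volume.data[nawm.data]
    if not np.isfinite(vals).all():
        raise ValueError("non-finite values inside the NAWM mask")
    mean = float(vals.mean())
    if mean <= 0:
        raise ValueError(f"NAWM mean must be positive, got {mean}")
    return NormalizedMap(
        data=volume.data / mean,
        voxel_dims=volume.voxel_dims,
        affine=volume.affine,
        source_modality=volume.modality,
    )


def dice(a: ROIMask, b: ROIMask, empty_value: float = 1.0) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A|+|B|)`` between two masks.

    Used for interrater agreement of delineations.  When both masks are empty
    the coefficient is undefined; ``empty_value`` (default 1.0, agreement on
    absence) is returned.
    """
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    na, nb = a.count(), b.count()
    if na == 0 and nb == 0:
        return float(empty_value)
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)
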