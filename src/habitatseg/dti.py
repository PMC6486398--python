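"""Diffusion-tensor p/q decomposition and invasive-phenotype classification.

The diffusion tensor at each voxel, with eigenvalues λ1 ≥ λ2 ≥ λ3 (mm²/s),
splits into an isotropic and an anisotropic part:

    MD = (λ1 + λ2 + λ3) / 3
    p  = √3 · MD
    q  = √((λ1 − MD)² + (λ2 − MD)² + (λ3 − MD)²)

p measures the magnitude of isotropic diffusion, q the deviation from
isotropy; q = 0 exactly when the tensor is isotropic, and for a
cylindrically symmetric tensor (a, b, b), q = √(2/3)·|a − b|.

Invasive phenotypes compare how far p- and q-defined abnormality extends
beyond the contrast-enhancing (CE) boundary.  Isotropic (p) abnormality
reaching well beyond anisotropic (q) abnormality suggests diffuse
infiltration; both margins small suggests minimal invasion.  The decision
thresholds here (t_min, t_diff, both default 10 mm) are provisional,
configurable defaults — the originating criteria live in prior work — and
externally supplied labels can override the rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import ParametricVolume, ROIMask, require_compatible

__all__ = [
    "TensorEigenvalues",
    "PQMaps",
    "InvasivePhenotype",
    "compute_pq",
    "abnormality_margins",
    "classify_phenotype",
    "zscore_abnormality",
]

PHENOTYPES = ("diffuse", "localized", "minimal")

DEFAULT_T_MIN_MM = 10.0
DEFAULT_T_DIFF_MM = 10.0


@dataclass
class TensorEigenvalues:
    """Voxelwise principal diffusivities, sorted non-increasing on ingestion.

    Negative eigenvalues (noise) are clamped to zero with a warning; the
    clamp count is recorded.
    """

    l1: np.ndarray
    l2: np.ndarray
    l3: np.ndarray
    n_clamped: int = 0

    @classmethod
    def from_arrays(cls, l1: np.ndarray, l2: np.ndarray, l3: np.ndarray) -> "TensorEigenvalues":
        stack = np.stack([np.asarray(a, dtype=np.float64) for a in (l1, l2, l3)])
        if stack.ndim != 4:
            raise ValueError("eigenvalue maps must be 3D arrays")
        n_neg = int((stack < 0).sum())
        if n_neg:
            warnings.warn(f"clamped {n_neg} negative eigenvalues to 0", stacklevel=2)
            stack = np.clip(stack, 0.0, None)
        stack = np.sort(stack, axis=0)[::-1]  # non-increasing
        return cls(l1=stack[0], l2=stack[1], l3=stack[2], n_clamped=n_neg)


@dataclass
class PQMaps:
    """Isotropic (p) and anisotropic (q) component maps, mm²/s."""

    p: np.ndarray
    q: np.ndarray


def compute_pq(eig: TensorEigenvalues) -> PQMaps:
    """Voxelwise p/q decomposition of the diffusion tensor.

    Non-finite eigenvalues are masked out (p and q set to NaN there) and the
    affected voxel count reported via a warning.
    """
    l1, l2, l3 = eig.l1, eig.l2, eig.l3
    finite = np.isfinite(l1) & np.isfinite(l2) & np.isfinite(l3)
    n_bad = int(finite.size - finite.sum())
    if n_bad:
        warnings.warn(f"masked {n_bad} voxels with non-finite eigenvalues", stacklevel=2)
    md = (l1 + l2 + l3) / 3.0
    p = np.sqrt(3.0) * md
    q = np.sqrt((l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2)
    p = np.where(finite, p, np.nan)
    q = np.where(finite, q, np.nan)
    return PQMaps(p=p, q=q)


def zscore_abnormality(
    volume: ParametricVolume,
    nawm: ROIMask,
    z: float = 2.0,
    direction: str = "above",
) -> ROIMask:
    """Abnormality mask: voxels deviating > z NAWM standard deviations.

    ``direction`` selects deviation above, below, or either side of the NAWM
    mean.  This is a configurable stand-in definition; externally derived
    abnormality masks can be supplied instead.
    """
    require_compatible([volume, nawm], "map and NAWM")
    if nawm.is_empty():
        raise ValueError("NAWM mask is empty")
    vals = volume.data[nawm.data]
    mu, sd = float(vals.mean()), float(vals.std())
    if sd == 0:
        raise ValueError("NAWM values are constant; z-score undefined")
    if direction == "above":
        data = volume.data > mu + z * sd
    elif direction == "below":
        data = volume.data < mu - z * sd
    elif direction == "both":
        data = np.abs(volume.data - mu) > z * sd
    else:
        raise ValueError(f"unknown direction {direction!r}")
    data = data & np.isfinite(volume.data)
    return ROIMask(data=data, voxel_dims=volume.voxel_dims, affine=volume.affine, label="other")


def abnormality_margins(
    p_abnormal: ROIMask,
    q_abnormal: ROIMask,
    ce: ROIMask,
    voxel_dims: tuple[float, float, float] | None = None,
) -> tuple[float, float]:
    """Maximal extent (mm) of p- and q-abnormality beyond the CE boundary.

    Each margin is the maximum Euclidean distance-transform value, computed
    with physical voxel spacing, over abnormality voxels outside CE; 0 when
    the abnormality is contained in CE.
    """
    require_compatible([p_abnormal, q_abnormal, ce], "abnormality and CE masks")
    if ce.is_empty():
        raise ValueError("CE mask is empty; margins undefined")
    dims = voxel_dims if voxel_dims is not None else ce.voxel_dims
    dist = ndimage.distance_transform_edt(~ce.data, sampling=dims)

    def margin(abn: ROIMask) -> float:
        outside = abn.data & ~ce.data
        return float(dist[outside].max()) if outside.any() else 0.0

    return margin(p_abnormal), margin(q_abnormal)


@dataclass(frozen=True)
class InvasivePhenotype:
    """Invasive phenotype label with the margins that produced it."""

    label: str
    p_margin: float
    q_margin: float

    def __post_init__(self) -> None:
        if self.label not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.label!r}")
        if self.p_margin < 0 or self.q_margin < 0:
            raise ValueError("margins must be non-negative")


def classify_phenotype(
    p_margin: float,
    q_margin: float,
    t_min_mm: float = DEFAULT_T_MIN_MM,
    t_diff_mm: float = DEFAULT_T_DIFF_MM,
    override_label: str | None = None,
) -> InvasivePhenotype:
    """Margin-threshold phenotype rule.

    - **minimal**: both margins below ``t_min_mm``;
    - **diffuse**: p-margin exceeds q-margin by more than ``t_diff_mm``
      (isotropic abnormality spreading well beyond anisotropic);
    - **localized**: otherwise.

    ``override_label`` bypasses the rule for cohorts with externally
    adjudicated phenotypes.
    """
    if p_margin < 0 or q_margin < 0:
        raise ValueError("margins must be non-negative")
    if override_label is not None:
        return InvasivePhenotype(label=override_label, p_margin=p_margin, q_margin=q_margin)
    if p_margin < t_min_mm and q_margin < t_min_mm:
        label = "minimal"
    elif p_margin - q_margin > t_diff_mm:
        label = "diffuse"
    else:
        label = "localized"
    return InvasivePhenotype(label=label, p_margin=p_margin, q_margin=q_margin)
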