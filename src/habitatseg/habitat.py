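"""Low-perfusion habitat compartments from pooled-quartile ADC/rCBV thresholds.

The method: within the contrast-enhancing (CE) ROI of a rim-enhancing lesion,
pool the voxelwise NAWM-normalized rCBV and ADC values.  The lowest rCBV
quartile (rCBV_L) marks low perfusion; the lowest and highest ADC quartiles
(ADC_L, ADC_H) mark restricted and elevated diffusivity.  Intersecting them
yields two compartments — ADC_L-rCBV_L (high cellularity under low perfusion)
and ADC_H-rCBV_L (diminished microstructure under low perfusion) — with the
remaining CE voxels as the contrast-enhancing control (CEC).  Compartment
volumes are reported absolutely (cm^3) and as a percentage of CE volume.

Thresholds are per-subject: each lesion's own ADC/rCBV distribution defines
its quartiles, treating every tumor as an independent ecological system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume_io import NormalizedMap, ParametricVolume, ROIMask, normalize_by_nawm, require_compatible

__all__ = [
    "QuartileThresholds",
    "HabitatResult",
    "HabitatModel",
    "pooled_quartiles",
    "lowest_quartile_mask",
    "highest_quartile_mask",
    "intersect_compartments",
    "mask_volume",
    "proportional_volume",
]

#: integer labels used when compartments are written as one labelled volume
COMPARTMENT_LABELS = {"ADC_L-rCBV_L": 1, "ADC_H-rCBV_L": 2, "CEC": 3}

#: CE masks smaller than this (voxels) are flagged as unreliable for quartiles
MIN_CE_VOXELS = 64


@dataclass(frozen=True)
class QuartileThresholds:
    """25th/75th percentile thresholds of a map pooled over a ROI."""

    q1: float
    q3: float
    source: str  # "rCBV" or "ADC"

    def __post_init__(self) -> None:
        if self.q1 > self.q3:
            raise ValueError(f"q1={self.q1} exceeds q3={self.q3}")


def pooled_quartiles(
    volume: NormalizedMap | ParametricVolume,
    roi: ROIMask,
    method: str = "linear",
) -> QuartileThresholds:
    """25th and 75th percentiles of the voxel values pooled inside ``roi``.

    ``method`` is the quantile interpolation rule (numpy naming); the default
    is linear interpolation between order statistics.
    """
    if roi.is_empty():
        raise ValueError("ROI is empty; quartiles undefined")
    vals = volume.data[roi.data]
    if not np.isfinite(vals).all():
        raise ValueError("non-finite map values inside the ROI")
    q1, q3 = np.percentile(vals, [25.0, 75.0], method=method)
    source = "rCBV" if getattr(volume, "source_modality", getattr(volume, "modality", "")) == "rCBV" else "ADC"
    return QuartileThresholds(q1=float(q1), q3=float(q3), source=source)


def _tie_fraction(vals: np.ndarray, threshold: float) -> float:
    return float(np.mean(vals == threshold)) if vals.size else 0.0


def lowest_quartile_mask(
    volume: NormalizedMap | ParametricVolume,
    roi: ROIMask,
    thresholds: QuartileThresholds,
) -> ROIMask:
    """Voxels of ``roi`` with value <= q1 (the lowest pooled quartile).

    With continuous values this selects ~25% of the ROI; ties at the
    threshold inflate the selection and are reported via a warning.
    """
    vals = volume.data[roi.data]
    ties = _tie_fraction(vals, thresholds.q1)
    if ties > 0.01:
        warnings.warn(
            f"{ties:.1%} of ROI voxels tie the q1 threshold; lowest-quartile mask over-selects",
            stacklevel=2,
        )
    data = roi.data & (volume.data <= thresholds.q1)
    label = "rCBV_L" if thresholds.source == "rCBV" else "ADC_L"
    return ROIMask(data=data, voxel_dims=roi.voxel_dims, affine=roi.affine, label=label)


def highest_quartile_mask(
    volume: NormalizedMap | ParametricVolume,
    roi: ROIMask,
    thresholds: QuartileThresholds,
) -> ROIMask:
    """Voxels of ``roi`` with value >= q3 (the highest pooled quartile)."""
    vals = volume.data[roi.data]
    ties = _tie_fraction(vals, thresholds.q3)
    if ties > 0.01:
        warnings.warn(
            f"{ties:.1%} of ROI voxels tie the q3 threshold; highest-quartile mask over-selects",
            stacklevel=2,
        )
    data = roi.data & (volume.data >= thresholds.q3)
    return ROIMask(data=data, voxel_dims=roi.voxel_dims, affine=roi.affine, label="ADC_H")


def intersect_compartments(
    rcbv_l: ROIMask,
    adc_l: ROIMask,
    adc_h: ROIMask,
    ce: ROIMask,
) -> dict[str, ROIMask]:
    """Intersect the quartile masks into the two compartments plus control.

    Returns the six derived masks.  By construction the compartments and CEC
    partition CE exactly:

    - ``ADC_L-rCBV_L`` = ADC_L ∩ rCBV_L
    - ``ADC_H-rCBV_L`` = ADC_H ∩ rCBV_L
    - ``CEC``          = CE minus both compartments
    """
    require_compatible([rcbv_l, adc_l, adc_h, ce], "quartile masks")
    for m, name in ((rcbv_l, "rCBV_L"), (adc_l, "ADC_L"), (adc_h, "ADC_H")):
        if (m.data & ~ce.data).any():
            raise ValueError(f"{name} mask extends outside CE")
    low = adc_l.data & rcbv_l.data
    high = adc_h.data & rcbv_l.data
    cec = ce.data & ~(low | high)
    mk = lambda data, label: ROIMask(data=data, voxel_dims=ce.voxel_dims, affine=ce.affine, label=label)
    return {
        "rCBV_L": mk(rcbv_l.data.copy(), "rCBV_L"),
        "ADC_L": mk(adc_l.data.copy(), "ADC_L"),
        "ADC_H": mk(adc_h.data.copy(), "ADC_H"),
        "ADC_L-rCBV_L": mk(low, "ADC_L-rCBV_L"),
        "ADC_H-rCBV_L": mk(high, "ADC_H-rCBV_L"),
        "CEC": mk(cec, "CEC"),
    }


def mask_volume(mask: ROIMask, voxel_dims: tuple[float, float, float] | None = None) -> float:
    """Absolute mask volume in cm^3 (voxel count x voxel volume / 1000)."""
    dims = voxel_dims if voxel_dims is not None else mask.voxel_dims
    return mask.count() * float(np.prod(dims)) / 1000.0


def proportional_volume(compartment: ROIMask, ce: ROIMask) -> float:
    """Compartment volume as a percentage of CE volume."""
    if ce.is_empty():
        raise ValueError("CE mask is empty")
    if (compartment.data & ~ce.data).any():
        raise ValueError("compartment extends outside CE")
    return 100.0 * compartment.count() / ce.count()


@dataclass
class HabitatResult:
    """Derived compartment masks with thresholds and volumes.

    ``abs_volumes`` are in cm^3 for all six masks; ``prop_volumes`` give the
    two compartments and CEC as percentages of CE volume.
    """

    masks: dict[str, ROIMask]
    thresholds: dict[str, QuartileThresholds]
    abs_volumes: dict[str, float]
    prop_volumes: dict[str, float]
    ce_voxels: int
    tie_counts: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def labelled_volume(self) -> np.ndarray:
        """One integer-labelled array: 1 = ADC_L-rCBV_L, 2 = ADC_H-rCBV_L, 3 = CEC."""
        ref = self.masks["CEC"]
        out = np.zeros(ref.shape, dtype=np.uint8)
        for name, lab in COMPARTMENT_LABELS.items():
            out[self.masks[name].data] = lab
        return out

    def summary(self) -> str:
        lines = ["Habitat compartments (pooled-quartile ADC/rCBV thresholding)"]
        lines.append(f"  CE voxels: {self.ce_voxels}")
        for src, thr in self.thresholds.items():
            lines.append(f"  {src} quartiles: q1={thr.q1:.4g}, q3={thr.q3:.4g}")
        lines.append(f"  {'mask':>14} {'volume cm^3':>12} {'% of CE':>8}")
        for name in ("CE", "rCBV_L", "ADC_L", "ADC_H", "ADC_L-rCBV_L", "ADC_H-rCBV_L", "CEC"):
            if name in self.abs_volumes:
                prop = self.prop_volumes.get(name)
                prop_s = f"{prop:8.2f}" if prop is not None else " " * 8
                lines.append(f"  {name:>14} {self.abs_volumes[name]:12.3f} {prop_s}")
        if self.flags:
            lines.append("  flags: " + "; ".join(self.flags))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "thresholds": {k: {"q1": v.q1, "q3": v.q3} for k, v in self.thresholds.items()},
            "abs_volumes_cm3": dict(self.abs_volumes),
            "prop_volumes_pct": dict(self.prop_volumes),
            "ce_voxels": self.ce_voxels,
            "tie_counts": dict(self.tie_counts),
            "flags": list(self.flags),
        }


class HabitatModel:
    """Habitat segmentation of one subject, statsmodels-style.

    Built from NAWM-normalized ADC and rCBV maps plus the CE mask;
    :meth:`fit` derives the quartile masks, intersections and volumes and
    returns a :class:`HabitatResult`.

    Use :meth:`from_raw` to start from unnormalized maps and a NAWM mask.
    """

    def __init__(
        self,
        adc: NormalizedMap,
        rcbv: NormalizedMap,
        ce: ROIMask,
        quantile_method: str = "linear",
        min_ce_voxels: int = MIN_CE_VOXELS,
    ) -> None:
        require_compatible([adc, rcbv, ce], "ADC, rCBV and CE")
        if ce.is_empty():
            raise ValueError("CE mask is empty")
        self.adc = adc
        self.rcbv = rcbv
        self.ce = ce
        self.quantile_method = quantile_method
        self.min_ce_voxels = min_ce_voxels

    @classmethod
    def from_raw(
        cls,
        adc: ParametricVolume,
        rcbv: ParametricVolume,
        ce: ROIMask,
        nawm: ROIMask,
        **kwargs,
    ) -> "HabitatModel":
        """Normalize raw ADC/rCBV maps by the subject's NAWM mean, then build."""
        return cls(normalize_by_nawm(adc, nawm), normalize_by_nawm(rcbv, nawm), ce, **kwargs)

    def fit(self) -> HabitatResult:
        ce = self.ce
        flags: list[str] = []
        if ce.count() < self.min_ce_voxels:
            flags.append(f"CE has {ce.count()} voxels (< {self.min_ce_voxels}); quartiles unreliable")

        thr_rcbv = pooled_quartiles(self.rcbv, ce, method=self.quantile_method)
        thr_adc = pooled_quartiles(self.adc, ce, method=self.quantile_method)
        thr_rcbv = QuartileThresholds(thr_rcbv.q1, thr_rcbv.q3, "rCBV")
        thr_adc = QuartileThresholds(thr_adc.q1, thr_adc.q3, "ADC")

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rcbv_l = lowest_quartile_mask(self.rcbv, ce, thr_rcbv)
            adc_l = lowest_quartile_mask(self.adc, ce, thr_adc)
            adc_h = highest_quartile_mask(self.adc, ce, thr_adc)
        masks = intersect_compartments(rcbv_l, adc_l, adc_h, ce)
        masks["CE"] = ce

        rcbv_vals = self.rcbv.data[ce.data]
        adc_vals = self.adc.data[ce.data]
        tie_counts = {
            "rCBV_q1": int((rcbv_vals == thr_rcbv.q1).sum()),
            "ADC_q1": int((adc_vals == thr_adc.q1).sum()),
            "ADC_q3": int((adc_vals == thr_adc.q3).sum()),
        }

        abs_volumes = {name: mask_volume(m) for name, m in masks.items()}
        prop_volumes = {
            name: proportional_volume(masks[name], ce)
            for name in ("ADC_L-rCBV_L", "ADC_H-rCBV_L", "CEC")
        }
        return HabitatResult(
            masks=masks,
            thresholds={"rCBV": thr_rcbv, "ADC": thr_adc},
            abs_volumes=abs_volumes,
            prop_volumes=prop_volumes,
            ce_voxels=ce.count(),
            tie_counts=tie_counts,
            flags=flags,
        )
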