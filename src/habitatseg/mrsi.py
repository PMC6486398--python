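"""Cross-resolution MRSI aggregation for habitat compartments.

Spectroscopic imaging voxels are roughly an order of magnitude coarser
in-plane than the T2-space image grid on which the compartments are drawn.
Each spectroscopic voxel is modelled as an axis-aligned block of image-grid
voxels.  To attach a metabolite level (Lac/Cr or ML9/Cr, ratios to creatine)
to a compartment:

1. keep only spectroscopic voxels lying *completely* inside the delineated
   tumor and passing spectral quality control;
2. for each kept voxel, count the fraction of its block covered by the
   compartment mask (the coverage fraction);
3. use the coverage fractions, renormalized to sum to one, as weights, and
   report the weighted mean of the per-voxel metabolite ratios.

The weighted mean (rather than a raw weighted sum) keeps the result on the
concentration-ratio scale regardless of compartment size; it always lies in
the convex hull of the contributing ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_io import ROIMask

__all__ = [
    "MRSIGrid",
    "WeightedMetabolite",
    "coverage_fractions",
    "tumor_containment_filter",
    "weighted_metabolite",
]

METABOLITES = ("lac_cr", "ml9_cr")

#: default spectral quality cut: relative Cramér–Rao-style SD (%) at or below
DEFAULT_QUALITY_MAX_SD = 20.0

_GEOM_COLS = ["row", "col", "i0", "j0", "k0", "ni", "nj", "nk"]


@dataclass
class MRSIGrid:
    """A coarse spectroscopic lattice mapped onto the image grid.

    ``table`` has one row per spectroscopic voxel with columns:

    - ``row, col`` — lattice indices;
    - ``i0, j0, k0, ni, nj, nk`` — origin and extent of the axis-aligned
      image-voxel block it covers;
    - ``lac_cr, ml9_cr`` — metabolite ratios to creatine (dimensionless);
    - quality: either a boolean ``qc_pass`` column, or a ``crlb_pct``
      relative-SD column filtered at ``quality_max_sd``.

    Blocks must be non-overlapping and lie inside ``image_shape``.
    """

    table: pd.DataFrame
    image_shape: tuple[int, int, int]
    quality_max_sd: float = DEFAULT_QUALITY_MAX_SD

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _GEOM_COLS if c not in t.columns]
        if missing:
            raise ValueError(f"MRSI table missing columns {missing}")
        if not any(m in t.columns for m in METABOLITES):
            raise ValueError(f"MRSI table has none of the metabolite columns {METABOLITES}")
        self.image_shape = tuple(int(s) for s in self.image_shape)
        self._validate_geometry()

    def _validate_geometry(self) -> None:
        t = self.table
        occupancy = np.zeros(self.image_shape, dtype=np.uint8)
        for blk in t.itertuples():
            i0, j0, k0 = int(blk.i0), int(blk.j0), int(blk.k0)
            ni, nj, nk = int(blk.ni), int(blk.nj), int(blk.nk)
            if min(ni, nj, nk) <= 0:
                raise ValueError("spectroscopic voxel block with non-positive extent")
            if i0 < 0 or j0 < 0 or k0 < 0 or i0 + ni > self.image_shape[0] \
                    or j0 + nj > self.image_shape[1] or k0 + nk > self.image_shape[2]:
                raise ValueError("spectroscopic voxel block outside the image grid")
            occupancy[i0:i0 + ni, j0:j0 + nj, k0:k0 + nk] += 1
        if (occupancy > 1).any():
            raise ValueError("spectroscopic voxel blocks overlap")

    def __len__(self) -> int:
        return len(self.table)

    def quality_pass(self) -> np.ndarray:
        """Boolean per-voxel quality flag (explicit ``qc_pass`` or SD cut)."""
        t = self.table
        if "qc_pass" in t.columns:
            return t["qc_pass"].to_numpy(dtype=bool)
        if "crlb_pct" in t.columns:
            return t["crlb_pct"].to_numpy(dtype=float) <= self.quality_max_sd
        return np.ones(len(t), dtype=bool)

    def block_slices(self, idx: int) -> tuple[slice, slice, slice]:
        r = self.table.iloc[idx]
        return (
            slice(int(r.i0), int(r.i0) + int(r.ni)),
            slice(int(r.j0), int(r.j0) + int(r.nj)),
            slice(int(r.k0), int(r.k0) + int(r.nk)),
        )

    def block_sizes(self) -> np.ndarray:
        t = self.table
        return (t["ni"] * t["nj"] * t["nk"]).to_numpy(dtype=np.int64)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        image_shape: tuple[int, int, int],
        quality_max_sd: float = DEFAULT_QUALITY_MAX_SD,
    ) -> "MRSIGrid":
        return cls(pd.read_csv(path), image_shape, quality_max_sd)


@dataclass
class WeightedMetabolite:
    """Coverage-weighted metabolite value for one compartment.

    ``value`` is NaN and ``n_voxels`` 0 when no spectroscopic voxel is
    eligible; such subjects are excluded from metabolite analyses.
    """

    compartment: str
    metabolite: str
    value: float
    weights: np.ndarray
    voxel_indices: np.ndarray
    n_voxels: int

    @property
    def missing(self) -> bool:
        return self.n_voxels == 0


def coverage_fractions(mask: ROIMask, grid: MRSIGrid) -> np.ndarray:
    """Fraction of each spectroscopic voxel's block covered by ``mask``."""
    if mask.shape != grid.image_shape:
        raise ValueError(f"mask grid {mask.shape} does not match MRSI image grid {grid.image_shape}")
    fracs = np.empty(len(grid), dtype=np.float64)
    for i in range(len(grid)):
        sl = grid.block_slices(i)
        block = mask.data[sl]
        fracs[i] = block.mean()
    return fracs


def tumor_containment_filter(tumor: ROIMask, grid: MRSIGrid) -> np.ndarray:
    """Boolean inclusion flags: block completely inside tumor AND quality pass."""
    if tumor.shape != grid.image_shape:
        raise ValueError(f"tumor grid {tumor.shape} does not match MRSI image grid {grid.image_shape}")
    inside = np.empty(len(grid), dtype=bool)
    for i in range(len(grid)):
        sl = grid.block_slices(i)
        inside[i] = bool(tumor.data[sl].all())
    return inside & grid.quality_pass()


def weighted_metabolite(
    mask: ROIMask,
    grid: MRSIGrid,
    tumor: ROIMask,
    metabolite: str,
) -> WeightedMetabolite:
    """Coverage-weighted metabolite value of a compartment.

    Weights are the compartment coverage fractions of the included
    (tumor-contained, quality-passing) spectroscopic voxels, renormalized to
    sum to one; voxels with zero coverage are dropped.  Returns an explicit
    missing-value record when no voxel is eligible.
    """
    if metabolite not in METABOLITES:
        raise ValueError(f"unknown metabolite {metabolite!r}; expected one of {METABOLITES}")
    if metabolite not in grid.table.columns:
        raise ValueError(f"MRSI table has no column {metabolite!r}")
    included = tumor_containment_filter(tumor, grid)
    fracs = coverage_fractions(mask, grid)
    eligible = included & (fracs > 0)
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return WeightedMetabolite(
            compartment=mask.label,
            metabolite=metabolite,
            value=float("nan"),
            weights=np.empty(0),
            voxel_indices=idx,
            n_voxels=0,
        )
    w = fracs[idx]
    w = w / w.sum()
    ratios = grid.table[metabolite].to_numpy(dtype=float)[idx]
    if not np.isfinite(ratios).all():
        raise ValueError(f"non-finite {metabolite} ratios in included spectroscopic voxels")
    value = float(np.dot(w, ratios))
    return WeightedMetabolite(
        compartment=mask.label,
        metabolite=metabolite,
        value=value,
        weights=w,
        voxel_indices=idx,
        n_voxels=int(idx.size),
    )


def compartment_metabolite_table(
    masks: dict[str, ROIMask],
    grid: MRSIGrid,
    tumor: ROIMask,
    metabolites: tuple[str, ...] = METABOLITES,
) -> pd.DataFrame:
    """Tidy per-compartment metabolite table (one row per compartment x metabolite)."""
    rows = []
    for name, mask in masks.items():
        for met in metabolites:
            if met not in grid.table.columns:
                continue
            wm = weighted_metabolite(mask, grid, tumor, met)
            rows.append(
                {
                    "compartment": name,
                    "metabolite": met,
                    "value": wm.value,
                    "n_mrsi_voxels": wm.n_voxels,
                }
            )
    return pd.DataFrame(rows)
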