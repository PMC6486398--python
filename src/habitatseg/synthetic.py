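"""Synthetic phantoms and cohorts with known ground truth.

No imaging data ship with this package; every pipeline stage is exercised on
generated inputs instead.

:func:`make_phantom` builds one subject: a rim-enhancing ellipsoidal lesion
whose interior core has rCBV drawn from a distribution whose support lies
strictly below the rim's, so that when ``core_fraction = 0.25`` the planted
core is exactly the lowest pooled rCBV quartile.  The core is split into a
restricted-diffusivity (low-ADC) and an elevated-diffusivity (high-ADC)
subregion, again with disjoint intensity supports straddling the rim's ADC
range, so the ADC quartile masks recover the planted split.  A contralateral
NAWM sphere anchors normalization, DTI eigenvalue maps are derived from the
ADC map with region-dependent anisotropy, and a single mid-lesion slice
carries a coarse MRSI slab with metabolite ratios elevated over the planted
compartments.

:func:`make_cohort` draws clinical covariates and exponential survival times
with planted log-hazard effects and independent censoring, for parameter-
recovery tests of the survival machinery.

All randomness flows from the single ``seed`` in each spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .mrsi import MRSIGrid, weighted_metabolite
from .volume_io import ParametricVolume, ROIMask

__all__ = [
    "PhantomSpec",
    "PhantomBundle",
    "CohortSpec",
    "make_phantom",
    "make_cohort",
    "random_phantom_spec",
]


def _default_rcbv() -> dict:
    # raw (pre-normalization) rCBV; NAWM mean ~1 so normalization barely rescales
    return {
        "rim": (2.5, 0.4),
        "core": (0.5, 0.1),
        "background": (1.0, 0.05),
    }


def _default_adc() -> dict:
    # ADC in 1e-3 mm^2/s; restricted < rim < elevated with disjoint 2-SD supports
    return {
        "rim": (1.10, 0.05),
        "core_restricted": (0.70, 0.03),
        "core_elevated": (1.50, 0.05),
        "nawm": (0.80, 0.02),
        "background": (0.80, 0.05),
    }


def _default_lac() -> dict:
    return {"ADC_L-rCBV_L": 2.0, "ADC_H-rCBV_L": 1.4, "CEC": 0.9, "background": 0.3}


def _default_ml9() -> dict:
    return {"ADC_L-rCBV_L": 1.8, "ADC_H-rCBV_L": 1.1, "CEC": 0.7, "background": 0.25}


@dataclass
class PhantomSpec:
    """Geometry, intensity and noise parameters of one synthetic subject.

    Defaults give a ~11 cm^3 contrast-enhancing lesion (~1.1e4 voxels at
    1 mm isotropic) on a 64x64x32 grid, a low-perfusion core occupying a
    quarter of CE split evenly into restricted and elevated diffusivity, an
    8x coarser in-plane MRSI slab on the mid-lesion slice, and disjoint
    per-region intensity supports (truncated Gaussians at +/-2 SD).
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center: tuple[float, float, float] = (38.0, 32.0, 16.0)
    radii_mm: tuple[float, float, float] = (17.0, 14.0, 11.0)
    rim_thickness_mm: float = 3.0
    core_fraction: float = 0.25
    split_fraction: float = 0.5
    rcbv_params: dict = field(default_factory=_default_rcbv)
    adc_params: dict = field(default_factory=_default_adc)
    disjoint_supports: bool = True
    nawm_center: tuple[float, float, float] = (12.0, 16.0, 16.0)
    nawm_radius_mm: float = 5.0
    flair_scale: float = 1.5
    mrsi_block: tuple[int, int, int] = (8, 8, 1)
    mrsi_slice: int | None = None
    lac_cr_means: dict = field(default_factory=_default_lac)
    ml9_cr_means: dict = field(default_factory=_default_ml9)
    mrsi_noise_sd: float = 0.05
    mrsi_fail_fraction: float = 0.0
    p_invasion_mm: float = 15.0
    q_invasion_mm: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.core_fraction < 1) or not (0 < self.split_fraction < 1):
            raise ValueError("core_fraction and split_fraction must lie in (0, 1)")
        for name, params in (("rcbv", self.rcbv_params), ("adc", self.adc_params)):
            for region, (mu, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"{name} SD for {region!r} is negative")
        bx, by, bz = self.mrsi_block
        if self.shape[0] % bx or self.shape[1] % by:
            raise ValueError("MRSI block size must divide the in-plane extent")
        # lesion inside the grid
        for c, r_mm, dim, n in zip(self.center, self.radii_mm, self.voxel_dims, self.shape):
            r_vox = r_mm / dim
            if c - r_vox < 0 or c + r_vox > n - 1:
                raise ValueError("lesion extends outside the grid")
        # core must stay inside the enhancing rim
        r_core = self.core_fraction ** (1.0 / 3.0)
        if (1.0 - r_core) * min(self.radii_mm) < self.rim_thickness_mm * 0.5:
            raise ValueError("core_fraction leaves no room for the enhancing rim")


@dataclass
class PhantomBundle:
    """One synthetic subject with ground truth."""

    adc: ParametricVolume
    rcbv: ParametricVolume
    eigenvalues: tuple[ParametricVolume, ParametricVolume, ParametricVolume]
    ce: ROIMask
    flair: ROIMask
    nawm: ROIMask
    p_abnormal: ROIMask
    q_abnormal: ROIMask
    mrsi: MRSIGrid
    truth: dict

    def volumes_and_masks(self) -> list:
        return [self.adc, self.rcbv, *self.eigenvalues, self.ce, self.flair,
                self.nawm, self.p_abnormal, self.q_abnormal]


def _draw(rng: np.random.Generator, mu: float, sd: float, size: int, truncate: bool) -> np.ndarray:
    if sd == 0 or size == 0:
        return np.full(size, mu)
    if truncate:
        return sps.truncnorm.rvs(-2.0, 2.0, loc=mu, scale=sd, size=size, random_state=rng)
    return rng.normal(mu, sd, size)


def make_phantom(spec: PhantomSpec | None = None) -> PhantomBundle:
    """Generate one subject bundle from a :class:`PhantomSpec`.

    The same seed yields bit-identical outputs.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    dims = spec.voxel_dims
    ii, jj, kk = np.indices(spec.shape, dtype=np.float64)

    # normalized ellipsoid radius (1.0 at the lesion surface)
    radii_vox = tuple(r / d for r, d in zip(spec.radii_mm, dims))
    re = np.sqrt(
        ((ii - spec.center[0]) / radii_vox[0]) ** 2
        + ((jj - spec.center[1]) / radii_vox[1]) ** 2
        + ((kk - spec.center[2]) / radii_vox[2]) ** 2
    )
    ce_arr = re <= 1.0
    n_ce = int(ce_arr.sum())
    if n_ce == 0:
        raise ValueError("lesion contains no voxels")

    # the planted low-perfusion core: innermost core_fraction of CE voxels
    r_core = np.quantile(re[ce_arr], spec.core_fraction)
    core = ce_arr & (re <= r_core)
    r_split = np.quantile(re[core], spec.split_fraction)
    restricted = core & (re <= r_split)      # low ADC, high cellularity
    elevated = core & ~restricted            # high ADC, diminished microstructure
    rim = ce_arr & ~core

    # FLAIR abnormality: enlarged ellipsoid (clipped by the grid)
    flair_arr = re <= spec.flair_scale

    # contralateral NAWM sphere (physical mm radius)
    dist_nawm = np.sqrt(
        ((ii - spec.nawm_center[0]) * dims[0]) ** 2
        + ((jj - spec.nawm_center[1]) * dims[1]) ** 2
        + ((kk - spec.nawm_center[2]) * dims[2]) ** 2
    )
    nawm_arr = dist_nawm <= spec.nawm_radius_mm
    if (nawm_arr & flair_arr).any():
        raise ValueError("NAWM sphere overlaps the lesion; spec geometrically impossible")

    trunc = spec.disjoint_supports

    rcbv_arr = np.empty(spec.shape)
    rp = spec.rcbv_params
    bg = ~ce_arr
    rcbv_arr[bg] = _draw(rng, *rp["background"], int(bg.sum()), trunc)
    rcbv_arr[rim] = _draw(rng, *rp["rim"], int(rim.sum()), trunc)
    rcbv_arr[core] = _draw(rng, *rp["core"], int(core.sum()), trunc)

    adc_arr = np.empty(spec.shape)
    ap = spec.adc_params
    adc_bg = ~ce_arr & ~nawm_arr
    adc_arr[adc_bg] = _draw(rng, *ap["background"], int(adc_bg.sum()), trunc)
    adc_arr[nawm_arr] = _draw(rng, *ap["nawm"], int(nawm_arr.sum()), trunc)
    adc_arr[rim] = _draw(rng, *ap["rim"], int(rim.sum()), trunc)
    adc_arr[restricted] = _draw(rng, *ap["core_restricted"], int(restricted.sum()), trunc)
    adc_arr[elevated] = _draw(rng, *ap["core_elevated"], int(elevated.sum()), trunc)
    adc_arr *= 1e-3  # to mm^2/s

    # DTI eigenvalues: mean diffusivity equals ADC; anisotropy collapses in tumor
    aniso = np.where(ce_arr, 0.1, 0.6)
    l1 = adc_arr * (1.0 + aniso)
    l2 = adc_arr * (1.0 - aniso / 2.0)
    l3 = l2.copy()

    # invasion: p/q abnormality extends a fixed physical margin beyond CE
    dist_out = ndimage.distance_transform_edt(~ce_arr, sampling=dims)
    p_abn = dist_out <= spec.p_invasion_mm
    q_abn = dist_out <= spec.q_invasion_mm

    affine = np.diag([*dims, 1.0])
    mk_vol = lambda arr, mod: ParametricVolume(arr, dims, affine, mod)
    mk_mask = lambda arr, lab: ROIMask(arr, dims, affine, lab)

    # ---- MRSI slab on the mid-lesion slice -------------------------------
    k_s = spec.mrsi_slice if spec.mrsi_slice is not None else int(round(spec.center[2]))
    bx, by, bz = spec.mrsi_block

    def metabolite_map(means: dict) -> np.ndarray:
        m = np.full(spec.shape, means["background"])
        m[rim] = means["CEC"]
        m[restricted] = means["ADC_L-rCBV_L"]
        m[elevated] = means["ADC_H-rCBV_L"]
        return m

    lac_map = metabolite_map(spec.lac_cr_means)
    ml9_map = metabolite_map(spec.ml9_cr_means)

    rows = []
    for r, i0 in enumerate(range(0, nx, bx)):
        for c, j0 in enumerate(range(0, ny, by)):
            blk = (slice(i0, i0 + bx), slice(j0, j0 + by), slice(k_s, k_s + bz))
            lac_true = float(lac_map[blk].mean())
            ml9_true = float(ml9_map[blk].mean())
            fail = rng.random() < spec.mrsi_fail_fraction
            rows.append(
                {
                    "row": r, "col": c,
                    "i0": i0, "j0": j0, "k0": k_s, "ni": bx, "nj": by, "nk": bz,
                    "lac_cr": lac_true + rng.normal(0.0, spec.mrsi_noise_sd),
                    "ml9_cr": ml9_true + rng.normal(0.0, spec.mrsi_noise_sd),
                    "lac_cr_true": lac_true,
                    "ml9_cr_true": ml9_true,
                    "crlb_pct": float(rng.uniform(25, 40) if fail else rng.uniform(5, 15)),
                }
            )
    table = pd.DataFrame(rows)
    grid = MRSIGrid(table, spec.shape)

    # geometry-implied noise-free expected weighted values per compartment
    noisefree = MRSIGrid(
        table.assign(lac_cr=table["lac_cr_true"], ml9_cr=table["ml9_cr_true"]),
        spec.shape,
    )
    ce_mask = mk_mask(ce_arr, "CE")
    truth_masks = {
        "rCBV_L": mk_mask(core, "rCBV_L"),
        "ADC_L-rCBV_L": mk_mask(restricted, "ADC_L-rCBV_L"),
        "ADC_H-rCBV_L": mk_mask(elevated, "ADC_H-rCBV_L"),
        "CEC": mk_mask(rim, "CEC"),
    }
    expected_weighted: dict[str, dict[str, float]] = {}
    for name in ("ADC_L-rCBV_L", "ADC_H-rCBV_L", "CEC"):
        expected_weighted[name] = {}
        for met in ("lac_cr", "ml9_cr"):
            wm = weighted_metabolite(truth_masks[name], noisefree, ce_mask, met)
            expected_weighted[name][met] = wm.value

    truth = {
        "masks": truth_masks,
        "core_fraction": int(core.sum()) / n_ce,
        "split_fraction": int(restricted.sum()) / int(core.sum()),
        "n_ce": n_ce,
        "expected_weighted": expected_weighted,
        "planted_means": {"lac_cr": dict(spec.lac_cr_means), "ml9_cr": dict(spec.ml9_cr_means)},
        "p_invasion_mm": spec.p_invasion_mm,
        "q_invasion_mm": spec.q_invasion_mm,
        "seed": spec.seed,
    }

    return PhantomBundle(
        adc=mk_vol(adc_arr, "ADC"),
        rcbv=mk_vol(rcbv_arr, "rCBV"),
        eigenvalues=(mk_vol(l1, "other"), mk_vol(l2, "other"), mk_vol(l3, "other")),
        ce=ce_mask,
        flair=mk_mask(flair_arr, "FLAIR"),
        nawm=mk_mask(nawm_arr, "NAWM"),
        p_abnormal=mk_mask(p_abn, "other"),
        q_abnormal=mk_mask(q_abn, "other"),
        mrsi=grid,
        truth=truth,
    )


def random_phantom_spec(seed: int) -> PhantomSpec:
    """A small randomized phantom for property sweeps.

    Jitters lesion geometry, core/split fractions and noise around a compact
    48x48x24 grid so repeated invariant checks see varied inputs while each
    phantom stays cheap to generate.
    """
    rng = np.random.default_rng(seed)
    center = (
        28.0 + rng.uniform(-2, 2),
        24.0 + rng.uniform(-2, 2),
        12.0 + rng.uniform(-1, 1),
    )
    return PhantomSpec(
        shape=(48, 48, 24),
        center=center,
        radii_mm=(rng.uniform(9, 12), rng.uniform(8, 11), rng.uniform(6, 8)),
        rim_thickness_mm=3.0,
        core_fraction=rng.uniform(0.2, 0.3),
        split_fraction=rng.uniform(0.4, 0.6),
        nawm_center=(7.0, 8.0, 12.0),
        nawm_radius_mm=3.0,
        flair_scale=1.3,
        mrsi_noise_sd=rng.uniform(0.0, 0.1),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _default_covariates() -> dict:
    """Clinical covariate generators mirroring a rim-enhancing glioma cohort.

    Ages cluster around 59 years, three quarters male, lognormal volumes with
    CE ~ 53 +/- 33 cm^3 and compartments ~ 5.7 / 2.3 cm^3.
    """
    return {
        "age": ("normal_clipped", 59.4, 10.9, 22.0, 76.0),
        "sex_male": ("binary", 0.75),
        "eor_partial": ("binary", 0.33),
        "mgmt_methylated": ("binary", 0.44),
        "idh1_mutant": ("binary", 0.0625),
        "ce_vol": ("lognormal", 3.805, 0.574),
        "flair_vol": ("lognormal", 4.58, 0.52),
        "adch_rcbvl_vol": ("lognormal", 1.49, 0.708),
        "adcl_rcbvl_vol": ("lognormal", 0.508, 0.806),
        "lac_cr_adcl": ("lognormal", 0.60, 0.35),
        "lac_cr_adch": ("lognormal", 0.30, 0.35),
        "lac_cr_cec": ("lognormal", -0.15, 0.35),
    }


def _default_betas() -> dict:
    """Planted log hazard ratios (PFS scale), directions as reported clinically:
    partial resection and larger CE volume raise hazard, MGMT methylation
    lowers it, lactate in the restricted compartment raises it."""
    return {
        "eor_partial": math.log(2.8),
        "mgmt_methylated": math.log(0.62),
        "ce_vol": 0.008,
        "lac_cr_adcl": math.log(2.0),
    }


@dataclass
class CohortSpec:
    """Cohort size, covariate generators, planted effects and censoring."""

    n: int = 112
    baseline_hazard: float = math.log(2.0) / 265.0   # per day; median PFS 265 d
    baseline_hazard_os: float = math.log(2.0) / 455.0
    betas: dict = field(default_factory=_default_betas)
    censoring_rate: float = 0.3
    covariates: dict = field(default_factory=_default_covariates)
    mgmt_missing_fraction: float = 4.0 / 112.0
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0 or self.baseline_hazard_os <= 0:
            raise ValueError("baseline hazards must be positive")
        unknown = set(self.betas) - set(self.covariates)
        if unknown:
            raise ValueError(f"betas reference unknown covariates: {sorted(unknown)}")


def _draw_covariate(rng: np.random.Generator, spec: tuple, n: int) -> np.ndarray:
    kind = spec[0]
    if kind == "binary":
        return (rng.random(n) < spec[1]).astype(float)
    if kind == "normal":
        return rng.normal(spec[1], spec[2], n)
    if kind == "normal_clipped":
        return np.clip(rng.normal(spec[1], spec[2], n), spec[3], spec[4])
    if kind == "lognormal":
        return rng.lognormal(spec[1], spec[2], n)
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], n)
    raise ValueError(f"unknown covariate distribution {kind!r}")


def _survival_outcome(
    rng: np.random.Generator, eta: np.ndarray, h0: float, censoring_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    rate = h0 * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)
    if censoring_rate > 0:
        # per-subject censoring rate chosen so P(censored) = censoring_rate
        c_rate = rate * censoring_rate / (1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate)
    else:
        t_cens = np.full_like(t_event, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def make_cohort(spec: CohortSpec | None = None) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table plus its ground-truth parameters.

    Survival times for PFS and OS are exponential with hazard
    ``h0 * exp(sum beta_j x_j)`` sharing the planted linear predictor;
    censoring is independent, calibrated so each subject is censored with
    probability ``censoring_rate``.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    cols = {name: _draw_covariate(rng, dist, n) for name, dist in spec.covariates.items()}
    df = pd.DataFrame(cols)

    eta = np.zeros(n)
    for name, beta in spec.betas.items():
        eta += beta * df[name].to_numpy()

    pfs_days, pfs_event = _survival_outcome(rng, eta, spec.baseline_hazard, spec.censoring_rate)
    os_days, os_event = _survival_outcome(rng, eta, spec.baseline_hazard_os, spec.censoring_rate)
    df["pfs_days"] = pfs_days
    df["pfs_event"] = pfs_event
    df["os_days"] = os_days
    df["os_event"] = os_event

    if "mgmt_methylated" in df.columns and spec.mgmt_missing_fraction > 0:
        miss = rng.random(n) < spec.mgmt_missing_fraction
        df.loc[miss, "mgmt_methylated"] = np.nan

    truth = {
        "betas": dict(spec.betas),
        "baseline_hazard": spec.baseline_hazard,
        "baseline_hazard_os": spec.baseline_hazard_os,
        "censoring_rate": spec.censoring_rate,
        "seed": spec.seed,
    }
    return df, truth
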