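"""Per-subject and cohort orchestration with reproducible JSON reports.

``run_subject`` chains I/O -> NAWM normalization -> habitat segmentation ->
MRSI aggregation -> DTI phenotype for one subject described by a
:class:`RunConfig`; every stage failure is re-raised with a stage label.
``run_cohort`` runs the cohort-level statistics (descriptive comparisons,
correlations, cutpoint/Kaplan-Meier dichotomizations, multivariate and
stepwise Cox) on a cohort table.

Outputs are deterministic for fixed inputs and config: reports carry the
package version and a config hash but no timestamps, so reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dti import TensorEigenvalues, abnormality_margins, classify_phenotype, compute_pq
from .habitat import HabitatModel
from .mrsi import MRSIGrid, compartment_metabolite_table
from .stats import (
    bh_adjust,
    cox_fit,
    group_compare,
    km_logrank,
    spearman,
    stepwise_cox,
    surv_cutpoint,
)
from .volume_io import (
    check_grid_compatibility,
    read_mask,
    read_volume,
    write_mask,
    write_volume,
)

__all__ = ["RunConfig", "ConfigError", "StageError", "run_subject", "run_cohort"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


@dataclass
class RunConfig:
    """Paths and options for one subject run.

    Optional inputs (MRSI table, eigenvalue maps, abnormality masks) degrade
    gracefully: the corresponding report fields are marked missing.
    """

    subject_id: str
    adc: str
    rcbv: str
    ce: str
    nawm: str
    flair: str | None = None
    mrsi: str | None = None
    eigenvalues: tuple[str, str, str] | None = None
    p_abnormal: str | None = None
    q_abnormal: str | None = None
    quantile_method: str = "linear"
    min_ce_voxels: int = 64
    mrsi_quality_max_sd: float = 20.0
    dti_t_min_mm: float = 10.0
    dti_t_diff_mm: float = 10.0
    phenotype_override: str | None = None
    outdir: str | None = None

    def validate(self) -> None:
        for name in ("adc", "rcbv", "ce", "nawm"):
            if not getattr(self, name):
                raise ConfigError(f"missing required path {name!r}")
        if self.min_ce_voxels < 1:
            raise ConfigError("min_ce_voxels must be >= 1")
        if self.mrsi_quality_max_sd <= 0:
            raise ConfigError("mrsi_quality_max_sd must be positive")
        if self.dti_t_min_mm < 0 or self.dti_t_diff_mm < 0:
            raise ConfigError("DTI thresholds must be non-negative")
        if self.eigenvalues is not None and len(self.eigenvalues) != 3:
            raise ConfigError("eigenvalues needs exactly three paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "eigenvalues" in raw and raw["eigenvalues"] is not None:
            raw["eigenvalues"] = tuple(raw["eigenvalues"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        """Hash of the analysis-relevant config (output location excluded)."""
        fields = asdict(self)
        fields.pop("outdir", None)
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_subject(config: RunConfig) -> dict:
    """Run the full per-subject pipeline and return the report dict.

    When ``config.outdir`` is set, the report JSON, compartment masks and
    normalized maps are written there.
    """
    config.validate()
    if config.outdir:
        Path(config.outdir).mkdir(parents=True, exist_ok=True)
    report: dict = {
        "subject_id": config.subject_id,
        "software_version": __version__,
        "config_hash": config.hash(),
    }

    with _stage("io"):
        adc = read_volume(config.adc, modality="ADC")
        rcbv = read_volume(config.rcbv, modality="rCBV")
        ce = read_mask(config.ce, label="CE")
        nawm = read_mask(config.nawm, label="NAWM")
        items = [adc, rcbv, ce, nawm]
        flair = None
        if config.flair:
            flair = read_mask(config.flair, label="FLAIR")
            items.append(flair)
        if not check_grid_compatibility(items):
            raise ValueError("input volumes/masks are not on one grid")

    with _stage("habitat"):
        model = HabitatModel.from_raw(
            adc, rcbv, ce, nawm,
            quantile_method=config.quantile_method,
            min_ce_voxels=config.min_ce_voxels,
        )
        habitat = model.fit()
        report["habitat"] = habitat.to_dict()
        if flair is not None:
            from .habitat import mask_volume

            report["habitat"]["abs_volumes_cm3"]["FLAIR"] = mask_volume(flair)

    report["mrsi"] = None
    if config.mrsi:
        if not Path(config.mrsi).exists():
            warnings.warn(f"MRSI table {config.mrsi} missing; metabolite fields omitted")
        else:
            with _stage("mrsi"):
                grid = MRSIGrid.from_csv(
                    config.mrsi, ce.shape, quality_max_sd=config.mrsi_quality_max_sd
                )
                comp = {k: habitat.masks[k] for k in ("ADC_L-rCBV_L", "ADC_H-rCBV_L", "CEC")}
                table = compartment_metabolite_table(comp, grid, ce)
                report["mrsi"] = {
                    f"{row.metabolite}:{row.compartment}": (
                        None if np.isnan(row.value) else float(row.value)
                    )
                    for row in table.itertuples()
                }
                report["mrsi_n_voxels"] = {
                    f"{row.metabolite}:{row.compartment}": int(row.n_mrsi_voxels)
                    for row in table.itertuples()
                }

    report["dti"] = None
    if config.eigenvalues and config.p_abnormal and config.q_abnormal:
        with _stage("dti"):
            l1, l2, l3 = (read_volume(p) for p in config.eigenvalues)
            eig = TensorEigenvalues.from_arrays(l1.data, l2.data, l3.data)
            pq = compute_pq(eig)
            p_abn = read_mask(config.p_abnormal)
            q_abn = read_mask(config.q_abnormal)
            p_margin, q_margin = abnormality_margins(p_abn, q_abn, ce)
            pheno = classify_phenotype(
                p_margin, q_margin,
                t_min_mm=config.dti_t_min_mm,
                t_diff_mm=config.dti_t_diff_mm,
                override_label=config.phenotype_override,
            )
            report["dti"] = {
                "p_margin_mm": p_margin,
                "q_margin_mm": q_margin,
                "phenotype": pheno.label,
            }
            if config.outdir:
                out = Path(config.outdir)
                from .volume_io import ParametricVolume

                write_volume(ParametricVolume(pq.p, ce.voxel_dims, ce.affine, "p"),
                             out / f"{config.subject_id}_p.nii.gz")
                write_volume(ParametricVolume(pq.q, ce.voxel_dims, ce.affine, "q"),
                             out / f"{config.subject_id}_q.nii.gz")

    if config.outdir:
        with _stage("write"):
            out = Path(config.outdir)
            out.mkdir(parents=True, exist_ok=True)
            for name in ("ADC_L-rCBV_L", "ADC_H-rCBV_L", "CEC"):
                safe = name.replace("-", "_").replace("/", "_")
                write_mask(habitat.masks[name], out / f"{config.subject_id}_{safe}.nii.gz")
            import nibabel as nib

            lab = nib.Nifti1Image(habitat.labelled_volume(), ce.affine)
            nib.save(lab, str(out / f"{config.subject_id}_compartments.nii.gz"))
            with open(out / f"{config.subject_id}_report.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
                fh.write("\n")

    return report


# ---------------------------------------------------------------------------
# cohort level
# ---------------------------------------------------------------------------

_CLINICAL_CANDIDATES = [
    "idh1_mutant", "mgmt_methylated", "sex_male", "age", "eor_partial", "ce_vol",
]

_CUTPOINT_DEFAULTS = [
    "ce_vol", "flair_vol", "adcl_rcbvl_vol", "adch_rcbvl_vol",
    "lac_cr_adcl", "lac_cr_adch", "lac_cr_cec",
]


def run_cohort(
    cohort: pd.DataFrame,
    outcome: str = "pfs",
    candidates: list[str] | None = None,
    cutpoint_covariates: list[str] | None = None,
    minprop: float = 0.1,
    stepwise: str = "both",
    min_subjects: int = 10,
    outdir: str | Path | None = None,
) -> dict:
    """Cohort-level analyses on a per-subject feature table.

    Returns a dict with descriptive group comparisons, Spearman correlations,
    cutpoint/log-rank dichotomizations and Cox models.  Survival stages are
    skipped (with a warning) below ``min_subjects`` subjects.
    """
    time_col, event_col = f"{outcome}_days", f"{outcome}_event"
    if time_col not in cohort.columns or event_col not in cohort.columns:
        raise ConfigError(f"cohort table lacks {time_col}/{event_col}")
    results: dict = {"n_subjects": int(len(cohort)), "outcome": outcome}

    # descriptive comparisons (volumes across clinical subgroups, Welch t)
    desc_rows = []
    vol_cols = [c for c in ("ce_vol", "flair_vol", "adch_rcbvl_vol", "adcl_rcbvl_vol")
                if c in cohort.columns]
    groupers: dict[str, pd.Series] = {}
    if "age" in cohort.columns:
        groupers["age>=60"] = cohort["age"] >= 60
    for g in ("sex_male", "eor_partial", "mgmt_methylated", "idh1_mutant"):
        if g in cohort.columns:
            groupers[g] = cohort[g] == 1
    for gname, flag in groupers.items():
        for v in vol_cols:
            sub = cohort[[v]].assign(flag=flag.to_numpy()).dropna()
            a = sub.loc[sub.flag, v].to_numpy()
            b = sub.loc[~sub.flag, v].to_numpy()
            if a.size < 2 or b.size < 2:
                continue
            res = group_compare(a, b, method="welch_t")
            desc_rows.append({
                "group": gname, "variable": v,
                "mean_yes": float(a.mean()), "mean_no": float(b.mean()),
                "p": res.pvalue,
            })
    desc = pd.DataFrame(desc_rows)
    if len(desc):
        desc["p_bh"] = bh_adjust(desc["p"].to_numpy())
    results["descriptive"] = desc

    # correlations of compartment volumes with CE/FLAIR burden
    corr_rows = []
    pairs = [(a, b) for a in ("adcl_rcbvl_vol", "adch_rcbvl_vol")
             for b in ("ce_vol", "flair_vol")
             if a in cohort.columns and b in cohort.columns]
    for a, b in pairs:
        sub = cohort[[a, b]].dropna()
        if len(sub) >= 3 and sub[a].nunique() > 1 and sub[b].nunique() > 1:
            rho, p = spearman(sub[a], sub[b])
            corr_rows.append({"x": a, "y": b, "rho": rho, "p": p, "n": len(sub)})
    results["correlations"] = pd.DataFrame(corr_rows)

    if len(cohort) < min_subjects:
        warnings.warn(
            f"cohort of {len(cohort)} < {min_subjects}; survival stages skipped"
        )
        results["survival"] = None
        return results

    surv: dict = {}
    base = cohort[[time_col, event_col]].notna().all(axis=1)
    base &= cohort[time_col] > 0

    # cutpoint dichotomization + Kaplan-Meier log-rank per marker
    cut_rows = []
    cut_covs = cutpoint_covariates if cutpoint_covariates is not None else [
        c for c in _CUTPOINT_DEFAULTS if c in cohort.columns
    ]
    for cov in cut_covs:
        sub = cohort.loc[base, [cov, time_col, event_col]].dropna()
        if len(sub) < 10 or sub[cov].nunique() < 2:
            continue
        try:
            cp = surv_cutpoint(sub[time_col], sub[event_col], sub[cov], minprop=minprop)
        except ValueError:
            continue
        stat, p = km_logrank(sub[time_col], sub[event_col], cp.groups)
        cut_rows.append({
            "covariate": cov, "threshold": cp.threshold,
            "max_std_logrank": cp.statistic,
            "n_low": cp.n_low, "n_high": cp.n_high,
            "logrank_chi2": stat, "logrank_p": p,
        })
    surv["cutpoints"] = pd.DataFrame(cut_rows)

    # multivariate Cox on the clinical candidate set (complete cases)
    cand = candidates if candidates is not None else [
        c for c in _CLINICAL_CANDIDATES if c in cohort.columns
    ]
    cand = [c for c in cand if cohort[c].nunique(dropna=True) > 1]
    sub = cohort.loc[base, cand + [time_col, event_col]].dropna()
    surv["n_complete_cases"] = int(len(sub))
    if len(sub) >= min_subjects and cand:
        X = sub[cand]
        t, e = sub[time_col], sub[event_col].astype(int)
        try:
            full = cox_fit(X, t, e)
            surv["multivariate"] = full.summary()
            surv["multivariate_aic"] = full.aic
        except ValueError as exc:
            warnings.warn(f"multivariate Cox failed: {exc}")
            surv["multivariate"] = None
        directions = ("forward", "backward") if stepwise == "both" else (stepwise,)
        for d in directions:
            try:
                fit = stepwise_cox(X, t, e, direction=d)
                surv[f"stepwise_{d}"] = {
                    "selected": fit.covariates,
                    "aic": fit.aic,
                    "summary": fit.summary(),
                    "trace": fit.step_trace,
                }
            except ValueError as exc:
                warnings.warn(f"stepwise ({d}) failed: {exc}")
                surv[f"stepwise_{d}"] = None
    results["survival"] = surv

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for key in ("descriptive", "correlations"):
            results[key].to_csv(out / f"{key}.csv", index=False)
        if results["survival"]:
            surv["cutpoints"].to_csv(out / "cutpoints.csv", index=False)
            mv = surv.get("multivariate")
            if mv is not None:
                mv.to_csv(out / "multivariate_cox.csv")
    return results
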