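"""Cohort-level statistics for habitat-imaging features.

Group comparisons (Welch t, Wilcoxon rank-sum, Kruskal–Wallis) with
Benjamini–Hochberg FDR control, Spearman correlation, Kaplan–Meier/log-rank
survival comparison, maximally-selected log-rank cutpoint dichotomization,
and Cox proportional-hazards modelling with forward/backward stepwise AIC
selection.

Standard tests are delegated to scipy/statsmodels/lifelines; the
cutpoint search and the stepwise selector are implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupTestResult",
    "CutpointResult",
    "SurvivalFit",
    "group_compare",
    "bh_adjust",
    "spearman",
    "surv_cutpoint",
    "km_logrank",
    "cox_fit",
    "stepwise_cox",
]


class GroupTestResult(NamedTuple):
    statistic: float
    pvalue: float
    method: str


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    for g in out:
        if g.size == 0:
            raise ValueError("empty group")
        if not np.isfinite(g).all():
            raise ValueError("non-finite values in a group")
    return out


def group_compare(*groups: Sequence[float], method: str = "welch_t") -> GroupTestResult:
    """Two-sided group comparison.

    ``method``:
      - ``welch_t`` — Welch two-sample t-test (2 groups, each n >= 2);
      - ``wilcoxon`` — Wilcoxon rank-sum / Mann-Whitney (2 groups);
      - ``kruskal`` — Kruskal-Wallis rank-sum (>= 2 groups).
    """
    gs = _as_groups(groups)
    if method == "welch_t":
        if len(gs) != 2:
            raise ValueError("welch_t requires exactly two groups")
        if any(g.size < 2 for g in gs):
            raise ValueError("welch_t requires n >= 2 per group")
        res = sps.ttest_ind(gs[0], gs[1], equal_var=False)
        return GroupTestResult(float(res.statistic), float(res.pvalue), method)
    if method == "wilcoxon":
        if len(gs) != 2:
            raise ValueError("wilcoxon rank-sum requires exactly two groups")
        res = sps.mannwhitneyu(gs[0], gs[1], alternative="two-sided", method="asymptotic")
        return GroupTestResult(float(res.statistic), float(min(res.pvalue, 1.0)), method)
    if method == "kruskal":
        res = sps.kruskal(*gs)
        return GroupTestResult(float(res.statistic), float(res.pvalue), method)
    raise ValueError(f"unknown method {method!r}")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR control).

    Adjusted values never fall below the raw ones, preserve the significance
    ordering, and are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (rho, p) of two paired vectors, n >= 3."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must be paired")
    if xa.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    rho, p = sps.spearmanr(xa, ya)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# log-rank machinery (two-sample, standardized) used by the cutpoint search
# ---------------------------------------------------------------------------

def standardized_logrank(
    time: np.ndarray, event: np.ndarray, in_low: np.ndarray
) -> float:
    """Standardized two-sample log-rank statistic z = (O1 - E1) / sqrt(V).

    ``in_low`` flags membership of the first group.  Uses the hypergeometric
    variance with the finite-population tie correction.  Returns 0 when no
    events or a degenerate risk set make the variance vanish.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    in_low = np.asarray(in_low, dtype=bool)
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], in_low[order]
    n = t.size

    uniq, first = np.unique(t, return_index=True)
    o_minus_e = 0.0
    var = 0.0
    for j, start in enumerate(first):
        stop = first[j + 1] if j + 1 < first.size else n
        at_risk = n - start
        at_risk_low = int(g[start:].sum())
        d = int(e[start:stop].sum())
        if d == 0 or at_risk <= 1:
            continue
        d_low = int((e[start:stop] & g[start:stop]).sum())
        frac = at_risk_low / at_risk
        o_minus_e += d_low - d * frac
        var += d * frac * (1.0 - frac) * (at_risk - d) / (at_risk - 1)
    if var <= 0:
        return 0.0
    return o_minus_e / math.sqrt(var)


@dataclass(frozen=True)
class CutpointResult:
    """Optimal dichotomization threshold for a continuous covariate.

    ``threshold`` is the midpoint between the two adjacent unique covariate
    values whose split maximizes the absolute standardized log-rank
    statistic; ``statistic`` is that maximal |z|.  ``groups`` labels each
    subject 'low' (covariate <= threshold) or 'high'.
    """

    threshold: float
    statistic: float
    groups: np.ndarray
    n_low: int
    n_high: int


def surv_cutpoint(
    time: Sequence[float],
    event: Sequence[int],
    covariate: Sequence[float],
    minprop: float = 0.1,
) -> CutpointResult:
    """Maximally selected log-rank dichotomization of a continuous covariate.

    Candidate splits are the midpoints between consecutive unique covariate
    values; only splits leaving at least ``minprop`` of subjects on each side
    are admissible.  The split maximizing the absolute standardized log-rank
    statistic is selected (ties broken toward the smaller threshold).

    Note the selected statistic is maximally selected: the naive log-rank
    p-value computed after dichotomization is anti-conservative.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if not (t.size == e.size == x.size):
        raise ValueError("time, event and covariate must have equal length")
    if t.size < 10:
        raise ValueError("need n >= 10 for cutpoint estimation")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; no cutpoint exists")
    n = x.size
    min_count = int(np.ceil(minprop * n))
    uniq = np.unique(x)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    counts_low = np.searchsorted(np.sort(x), candidates, side="right")
    admissible = (counts_low >= min_count) & (n - counts_low >= min_count)
    candidates = candidates[admissible]
    if candidates.size == 0:
        raise ValueError("no admissible split satisfies minprop on both sides")

    best_z = -np.inf
    best_thr = math.nan
    for thr in candidates:
        z = abs(standardized_logrank(t, e, x <= thr))
        if z > best_z + 1e-12:
            best_z = z
            best_thr = thr
    groups = np.where(x <= best_thr, "low", "high")
    return CutpointResult(
        threshold=float(best_thr),
        statistic=float(best_z),
        groups=groups,
        n_low=int((x <= best_thr).sum()),
        n_high=int((x > best_thr).sum()),
    )


def cutpoint_permutation_pvalue(
    time: Sequence[float],
    event: Sequence[int],
    covariate: Sequence[float],
    minprop: float = 0.1,
    n_perm: int = 500,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation-corrected p-value for the maximally selected statistic.

    The naive post-dichotomization log-rank p inflates type-I error; this
    re-runs the cutpoint search on covariate permutations and reports the
    fraction of permuted maxima at or above the observed one.
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(covariate, dtype=float)
    observed = surv_cutpoint(time, event, x, minprop).statistic
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(x)
        try:
            stat = surv_cutpoint(time, event, perm, minprop).statistic
        except ValueError:
            continue
        if stat >= observed:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


def km_logrank(
    time: Sequence[float], event: Sequence[int], group: Sequence
) -> tuple[float, float]:
    """Log-rank test (chi-square statistic, p) across >= 2 groups.

    With no events anywhere the statistic is 0 (p = 1).  Kaplan–Meier curves
    for plotting are available through :func:`km_curves`.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    labels = np.unique(g)
    if labels.size < 2:
        raise ValueError("log-rank requires at least two groups")
    if e.sum() == 0:
        return 0.0, 1.0
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def km_curves(
    time: Sequence[float], event: Sequence[int], group: Sequence
) -> dict[str, KaplanMeierFitter]:
    """Fitted Kaplan–Meier estimator per group, keyed by group label."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    out: dict[str, KaplanMeierFitter] = {}
    for lab in np.unique(g):
        sel = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel], label=str(lab))
        out[str(lab)] = kmf
    return out


def plot_km(time, event, group, path, title: str = "") -> None:
    """Write a Kaplan–Meier plot (one curve per group) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for kmf in km_curves(time, event, group).values():
        kmf.plot_survival_function(ax=ax)
    stat, p = km_logrank(time, event, group)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_title(title or f"log-rank chi2={stat:.2f}, p={p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Cox proportional hazards (lifelines-backed) and stepwise AIC selection
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    """Cox model results: hazard ratios, Wald CIs, p-values, partial AIC.

    ``covariates`` may be empty (the null model), in which case only the AIC
    and log partial likelihood are meaningful.
    """

    covariates: list[str]
    coef: pd.Series
    se: pd.Series
    hazard_ratio: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    pvalue: pd.Series
    aic: float
    log_likelihood: float
    n: int
    n_events: int
    step_trace: list[dict] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Table with one row per covariate: HR, 95% CI, p."""
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "HR": self.hazard_ratio,
                "CI95_low": self.ci_lower,
                "CI95_high": self.ci_upper,
                "p": self.pvalue,
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        head = (
            f"<SurvivalFit n={self.n} events={self.n_events} "
            f"AIC={self.aic:.2f} covariates={self.covariates}>"
        )
        return head


def null_log_partial_likelihood(time: Sequence[float], event: Sequence[int]) -> float:
    """Log partial likelihood of the covariate-free Cox model.

    With all risk scores equal to 1, each group of d tied events at a time
    with n subjects at risk contributes -sum_{l=0}^{d-1} log(n - l) (the
    Efron and Breslow conventions coincide in the null model).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = t.size
    uniq, first = np.unique(t, return_index=True)
    ll = 0.0
    for j, start in enumerate(first):
        stop = first[j + 1] if j + 1 < first.size else n
        at_risk = n - start
        d = int(e[start:stop].sum())
        for l in range(d):
            ll -= math.log(at_risk - l)
    return ll


def efron_derivatives(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron-tie log partial likelihood with gradient and Hessian at ``beta``."""
    X = np.asarray(X, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    order = np.argsort(t, kind="stable")
    X, t, e = X[order], t[order], e[order]
    n, k = X.shape
    xb = X @ beta
    psi = np.exp(xb)
    # suffix (risk-set) sums of psi, psi*x and psi*x*x^T
    s0 = np.cumsum(psi[::-1])[::-1]
    s1 = np.cumsum((psi[:, None] * X)[::-1], axis=0)[::-1]
    xxt = X[:, :, None] * X[:, None, :]
    s2 = np.cumsum((psi[:, None, None] * xxt)[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(k)
    hess = np.zeros((k, k))
    uniq, first = np.unique(t, return_index=True)
    for j, start in enumerate(first):
        stop = first[j + 1] if j + 1 < first.size else n
        tied = np.arange(start, stop)[e[start:stop]]
        d = tied.size
        if d == 0:
            continue
        r0, r1, r2 = s0[start], s1[start], s2[start]
        d0 = psi[tied].sum()
        d1 = (psi[tied][:, None] * X[tied]).sum(axis=0)
        d2 = (psi[tied][:, None, None] * xxt[tied]).sum(axis=0)
        ll += xb[tied].sum()
        grad += X[tied].sum(axis=0)
        for l in range(d):
            frac = l / d
            den = r0 - frac * d0
            num1 = r1 - frac * d1
            num2 = r2 - frac * d2
            ll -= math.log(den)
            grad -= num1 / den
            hess -= num2 / den - np.outer(num1, num1) / den**2
    return ll, grad, hess


def efron_score(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """Gradient of the Efron-tie log partial likelihood at ``beta``.

    Diagnostic helper: at a converged estimate the score norm should be
    numerically zero.
    """
    return efron_derivatives(X, time, event, beta)[1]


def _null_fit(time, event) -> SurvivalFit:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    ll = null_log_partial_likelihood(t, e)
    empty = pd.Series(dtype=float)
    return SurvivalFit(
        covariates=[],
        coef=empty,
        se=empty,
        hazard_ratio=empty,
        ci_lower=empty,
        ci_upper=empty,
        pvalue=empty,
        aic=-2.0 * ll,
        log_likelihood=ll,
        n=t.size,
        n_events=int(e.sum()),
    )


def cox_fit(
    covariates: pd.DataFrame,
    time: Sequence[float],
    event: Sequence[int],
) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron tie handling, Wald 95% CIs).

    Requires more events than covariates and a full-rank, non-constant
    design; collinear designs raise ``ValueError``.  Model AIC is the
    partial-likelihood AIC, -2 logPL + 2k.
    """
    X = covariates.copy()
    if not isinstance(X, pd.DataFrame):
        raise TypeError("covariates must be a DataFrame")
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be 0/1")
    if X.shape[1] == 0:
        return _null_fit(t, e)
    if X.isna().any().any():
        raise ValueError("missing covariate values; apply complete-case filtering first")
    k = X.shape[1]
    if int(e.sum()) < k + 1:
        raise ValueError(f"need at least {k + 1} events for {k} covariates, got {int(e.sum())}")
    arr = X.to_numpy(dtype=float)
    if np.any(np.ptp(arr, axis=0) == 0):
        const = [c for c in X.columns if X[c].nunique() == 1]
        raise ValueError(f"constant covariate(s): {const}")
    centered = arr - arr.mean(axis=0)
    if np.linalg.matrix_rank(centered) < k:
        raise ValueError("collinear covariate design (rank-deficient)")

    df = X.copy()
    df["_time"] = t
    df["_event"] = e
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise ValueError(f"Cox model failed to converge: {exc}") from exc

    # polish the lifelines estimate with Newton steps on the Efron partial
    # likelihood until the score vanishes numerically, and take Wald
    # inference from the observed information at the polished optimum
    beta = cph.params_.to_numpy(dtype=float)
    ll, grad, hess = efron_derivatives(arr, t, e, beta)
    for _ in range(25):
        if np.linalg.norm(grad) < 1e-9:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular information matrix: {exc}") from exc
        beta = beta + step
        ll, grad, hess = efron_derivatives(arr, t, e, beta)
    if not np.isfinite(grad).all() or np.linalg.norm(grad) > 1e-6:
        raise ValueError(
            f"Cox model failed to converge: score norm {np.linalg.norm(grad):.3g}"
        )
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z975 = sps.norm.ppf(0.975)
    idx = pd.Index(X.columns, name="covariate")
    coef = pd.Series(beta, index=idx)
    se_s = pd.Series(se, index=idx)
    zval = coef / se_s
    return SurvivalFit(
        covariates=list(X.columns),
        coef=coef,
        se=se_s,
        hazard_ratio=np.exp(coef),
        ci_lower=np.exp(coef - z975 * se_s),
        ci_upper=np.exp(coef + z975 * se_s),
        pvalue=pd.Series(2.0 * sps.norm.sf(np.abs(zval)), index=idx),
        aic=-2.0 * ll + 2.0 * k,
        log_likelihood=float(ll),
        n=t.size,
        n_events=int(e.sum()),
    )


def stepwise_cox(
    covariates: pd.DataFrame,
    time: Sequence[float],
    event: Sequence[int],
    direction: str = "forward",
) -> SurvivalFit:
    """Greedy stepwise Cox selection by partial-likelihood AIC.

    ``forward`` starts from the null model and repeatedly adds the single
    covariate giving the largest AIC decrease; ``backward`` starts from the
    full model and repeatedly drops one.  Either stops when no step
    decreases the AIC.  The returned fit carries the step trace.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    all_covs = list(covariates.columns)

    def fit_subset(cols: list[str]) -> SurvivalFit:
        return cox_fit(covariates[cols], t, e)

    trace: list[dict] = []
    if direction == "forward":
        current: list[str] = []
        current_fit = _null_fit(t, e)
    else:
        current = list(all_covs)
        current_fit = fit_subset(current)  # initial model unfittable -> raises
    trace.append({"step": 0, "action": "start", "covariate": None, "aic": current_fit.aic,
                  "model": list(current)})

    step = 0
    while True:
        step += 1
        pool = [c for c in all_covs if (c not in current) == (direction == "forward")]
        best: tuple[float, str, SurvivalFit] | None = None
        for c in pool:
            cols = current + [c] if direction == "forward" else [x for x in current if x != c]
            try:
                cand = fit_subset(cols) if cols else _null_fit(t, e)
            except ValueError:
                continue
            if best is None or cand.aic < best[0]:
                best = (cand.aic, c, cand)
        if best is None or best[0] >= current_fit.aic:
            break
        aic, c, cand = best
        current = cand.covariates
        current_fit = cand
        trace.append({
            "step": step,
            "action": "add" if direction == "forward" else "drop",
            "covariate": c,
            "aic": aic,
            "model": list(current),
        })

    current_fit.step_trace = trace
    return current_fit


def exhaustive_best_subset_cox(
    covariates: pd.DataFrame,
    time: Sequence[float],
    event: Sequence[int],
    max_covariates: int | None = None,
) -> SurvivalFit:
    """Best-AIC Cox model over all covariate subsets (small designs only)."""
    from itertools import combinations

    cols = list(covariates.columns)
    if max_covariates is None:
        max_covariates = len(cols)
    if len(cols) > 16:
        raise ValueError("exhaustive search limited to 16 covariates")
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    best = _null_fit(t, e)
    for r in range(1, min(len(cols), max_covariates) + 1):
        for subset in combinations(cols, r):
            try:
                cand = cox_fit(covariates[list(subset)], t, e)
            except ValueError:
                continue
            if cand.aic < best.aic:
                best = cand
    return best
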