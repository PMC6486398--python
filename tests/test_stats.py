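import math

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from habitatseg.stats import (
    bh_adjust,
    cox_fit,
    cutpoint_permutation_pvalue,
    efron_derivatives,
    efron_score,
    exhaustive_best_subset_cox,
    group_compare,
    km_curves,
    km_logrank,
    null_log_partial_likelihood,
    spearman,
    standardized_logrank,
    stepwise_cox,
    surv_cutpoint,
)
from habitatseg.synthetic import CohortSpec, make_cohort


def simulate_surv(rng, n, beta, censor=0.3, binary=True):
    x = (rng.random(n) < 0.5).astype(float) if binary else rng.normal(size=n)
    rate = 0.01 * np.exp(beta * x)
    t_event = rng.exponential(1 / rate)
    t_cens = rng.exponential(1 / (rate * censor / (1 - censor))) if censor else np.inf
    t = np.minimum(t_event, t_cens)
    e = (t_event <= t_cens).astype(int)
    return t, e, x


class TestGroupCompare:
    def test_identical_groups_rank_test_p_one(self):
        res = group_compare([1, 2, 3], [1, 2, 3], method="wilcoxon")
        assert res.pvalue == 1.0

    def test_kruskal_identical_groups_statistic_zero(self):
        res = group_compare([1, 2, 3], [1, 2, 3], [1, 2, 3], method="kruskal")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_welch_separated_groups(self):
        res = group_compare([1, 2, 3], [101, 102, 103], method="welch_t")
        assert res.pvalue < 0.001

    def test_welch_matches_scipy(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 2, 15)
        from scipy import stats as sps

        ref = sps.ttest_ind(a, b, equal_var=False)
        res = group_compare(a, b, method="welch_t")
        assert res.pvalue == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_compare([1.0], [], method="wilcoxon")

    def test_welch_needs_two_per_group(self):
        with pytest.raises(ValueError):
            group_compare([1.0], [2.0, 3.0], method="welch_t")


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_three_element_step_up_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_never_decreases_and_preserves_order(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 30))
            adj = bh_adjust(p)
            assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_adjacent_swap_rank_formula(self):
        # ranks (1,2,4,3,5): rho = 1 - 6*2 / (5*24) = 0.9
        rho, _ = spearman([1, 2, 3, 4, 5], [1, 2, 4, 3, 5])
        assert rho == pytest.approx(0.9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])


class TestSurvCutpoint:
    def test_perfect_separation_threshold_between_clusters(self, rng):
        n = 40
        x = np.concatenate([rng.uniform(0, 1, n // 2), rng.uniform(9, 10, n // 2)])
        t = np.concatenate([rng.uniform(10, 20, n // 2), rng.uniform(200, 300, n // 2)])
        e = np.ones(n, int)
        cp = surv_cutpoint(t, e, x)
        assert 1.0 < cp.threshold < 9.0

    def test_two_distinct_values_single_candidate(self):
        x = np.array([1.0] * 10 + [3.0] * 10)
        t = np.arange(1.0, 21.0)
        e = np.ones(20, int)
        cp = surv_cutpoint(t, e, x)
        assert cp.threshold == pytest.approx(2.0)
        assert cp.n_low == cp.n_high == 10

    @pytest.mark.parametrize("seed,n", [(0, 60), (1, 150), (2, 320)])
    def test_matches_exhaustive_lifelines_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        t, e, _ = simulate_surv(rng, n, 0.0)
        x = rng.normal(size=n)
        cp = surv_cutpoint(t, e, x, minprop=0.1)
        # independent oracle: lifelines log-rank at every admissible split
        uniq = np.unique(x)
        cands = (uniq[:-1] + uniq[1:]) / 2
        minc = int(np.ceil(0.1 * n))
        best = (-1.0, None)
        for c in cands:
            low = x <= c
            if low.sum() < minc or (~low).sum() < minc:
                continue
            r = logrank_test(t[low], t[~low], e[low], e[~low])
            z = math.sqrt(max(r.test_statistic, 0.0))
            if z > best[0] + 1e-12:
                best = (z, c)
        assert cp.threshold == pytest.approx(best[1])
        assert cp.statistic == pytest.approx(best[0], abs=1e-8)

    def test_minprop_respected(self, rng):
        t, e, _ = simulate_surv(rng, 100, 0.0)
        x = rng.normal(size=100)
        cp = surv_cutpoint(t, e, x, minprop=0.25)
        assert cp.n_low >= 25 and cp.n_high >= 25

    def test_constant_covariate_rejected(self, rng):
        t, e, _ = simulate_surv(rng, 30, 0.0)
        with pytest.raises(ValueError, match="constant"):
            surv_cutpoint(t, e, np.ones(30))

    def test_permutation_p_uniformish_under_null(self, rng):
        t, e, _ = simulate_surv(rng, 80, 0.0)
        x = rng.normal(size=80)
        p = cutpoint_permutation_pvalue(t, e, x, n_perm=60, rng=rng)
        assert 0.0 < p <= 1.0


class TestKMLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [5, 10, 15, 5, 10, 15]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        stat, p = km_logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_all_censored_statistic_zero(self):
        stat, p = km_logrank([1, 1, 1, 1], [0, 0, 0, 0], [0, 0, 1, 1])
        assert stat == 0.0 and p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            km_logrank([1, 2], [1, 1], [0, 0])

    def test_power_under_strong_effect(self):
        hits = 0
        runs = 40
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            t0 = rng.exponential(100, 200)
            t1 = rng.exponential(100 / 3, 200)
            t = np.concatenate([t0, t1])
            e = np.ones(400, int)
            g = np.repeat([0, 1], 200)
            if km_logrank(t, e, g)[1] < 0.01:
                hits += 1
        assert hits >= 0.95 * runs

    def test_standardized_logrank_matches_lifelines_chi2(self, rng):
        t, e, x = simulate_surv(rng, 120, 0.7)
        g = x > 0.5
        z = standardized_logrank(t, e, g)
        ref = logrank_test(t[g], t[~g], e[g], e[~g]).test_statistic
        assert z**2 == pytest.approx(ref, rel=1e-8)

    def test_km_curves_one_per_group(self, rng):
        t, e, x = simulate_surv(rng, 50, 0.0)
        curves = km_curves(t, e, x > 0.5)
        assert set(curves) == {"True", "False"}


class TestCoxFit:
    def test_parameter_recovery_rate(self):
        hits = 0
        runs = 10
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            t, e, x = simulate_surv(rng, 500, math.log(2.0))
            fit = cox_fit(pd.DataFrame({"x": x}), t, e)
            assert fit.ci_lower["x"] <= fit.hazard_ratio["x"] <= fit.ci_upper["x"]
            if 1.7 <= fit.hazard_ratio["x"] <= 2.35:
                hits += 1
        assert hits >= 0.9 * runs

    def test_score_vanishes_at_optimum(self, rng):
        t, e, x = simulate_surv(rng, 300, 0.5)
        X = pd.DataFrame({"x": x, "z": rng.normal(size=300)})
        fit = cox_fit(X, t, e)
        score = efron_score(X.to_numpy(), t, e, fit.coef.to_numpy())
        assert np.linalg.norm(score) < 1e-6

    def test_matches_lifelines_inference(self, rng):
        from lifelines import CoxPHFitter

        t, e, x = simulate_surv(rng, 250, 0.6)
        X = pd.DataFrame({"x": x})
        fit = cox_fit(X, t, e)
        df = X.assign(t=t, e=e)
        ref = CoxPHFitter().fit(df, "t", "e")
        assert fit.coef["x"] == pytest.approx(ref.params_["x"], abs=1e-4)
        assert fit.se["x"] == pytest.approx(ref.summary["se(coef)"]["x"], rel=1e-4)
        assert fit.aic == pytest.approx(ref.AIC_partial_, abs=1e-3)

    def test_duplicated_covariate_flagged(self, rng):
        t, e, x = simulate_surv(rng, 100, 0.5)
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="collinear"):
            cox_fit(X, t, e)

    def test_constant_covariate_rejected(self, rng):
        t, e, _ = simulate_surv(rng, 50, 0.0)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"c": np.ones(50)}), t, e)

    def test_too_few_events_rejected(self):
        t = np.arange(1.0, 6.0)
        e = np.array([1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="events"):
            cox_fit(pd.DataFrame({"x": [1.0, 2, 3, 4, 5]}), t, e)

    def test_null_logpl_matches_efron_at_zero(self, rng):
        t, e, x = simulate_surv(rng, 80, 0.4)
        # duplicate times to exercise tie handling
        t = np.round(t, -1) + 1.0
        ll0 = null_log_partial_likelihood(t, e)
        ll, _, _ = efron_derivatives(np.zeros((80, 1)), t, e, np.zeros(1))
        assert ll0 == pytest.approx(ll, abs=1e-10)

    def test_null_model_fit(self, rng):
        t, e, _ = simulate_surv(rng, 60, 0.0)
        fit = cox_fit(pd.DataFrame(index=range(60)), t, e)
        assert fit.covariates == []
        assert fit.aic == pytest.approx(-2 * null_log_partial_likelihood(t, e))


class TestStepwiseCox:
    def test_single_candidate_kept_iff_aic_improves(self):
        rng = np.random.default_rng(11)
        t, e, x = simulate_surv(rng, 300, math.log(3.0))
        X = pd.DataFrame({"x": x})
        fit = stepwise_cox(X, t, e, "forward")
        single = cox_fit(X, t, e)
        null_aic = -2 * null_log_partial_likelihood(t, e)
        if single.aic < null_aic:
            assert fit.covariates == ["x"]
        else:
            assert fit.covariates == []

    def test_noise_only_usually_selects_nothing(self):
        rng = np.random.default_rng(3)
        t, e, _ = simulate_surv(rng, 200, 0.0)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        fw = stepwise_cox(X, t, e, "forward")
        ex = exhaustive_best_subset_cox(X, t, e)
        assert set(fw.covariates) == set(ex.covariates)

    def test_true_covariate_selected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t, e, x = simulate_surv(rng, 400, math.log(3.0))
            X = pd.DataFrame(rng.normal(size=(400, 4)), columns=list("nmop"))
            X["x"] = x
            fw = stepwise_cox(X, t, e, "forward")
            if "x" in fw.covariates:
                hits += 1
        assert hits >= 9

    def test_forward_backward_trace_recorded(self, rng):
        t, e, x = simulate_surv(rng, 250, 1.0)
        X = pd.DataFrame({"x": x, "noise": rng.normal(size=250)})
        for direction in ("forward", "backward"):
            fit = stepwise_cox(X, t, e, direction)
            assert fit.step_trace[0]["action"] == "start"
            aics = [s["aic"] for s in fit.step_trace]
            assert all(b < a for a, b in zip(aics, aics[1:]))

    def test_bad_direction_rejected(self, rng):
        t, e, x = simulate_surv(rng, 50, 0.0)
        with pytest.raises(ValueError, match="direction"):
            stepwise_cox(pd.DataFrame({"x": x}), t, e, "sideways")


class TestCohortIntegration:
    def test_planted_beta_recovered_from_generated_cohort(self):
        spec = CohortSpec(
            n=500,
            covariates={"x": ("binary", 0.5)},
            betas={"x": math.log(2.0)},
            censoring_rate=0.3,
            mgmt_missing_fraction=0.0,
            seed=9,
        )
        df, truth = make_cohort(spec)
        fit = cox_fit(df[["x"]], df["pfs_days"], df["pfs_event"])
        assert 1.7 <= fit.hazard_ratio["x"] <= 2.35

    def test_null_cohort_hr_near_one(self):
        spec = CohortSpec(
            n=500,
            covariates={"x": ("binary", 0.5)},
            betas={},
            censoring_rate=0.3,
            mgmt_missing_fraction=0.0,
            seed=4,
        )
        df, _ = make_cohort(spec)
        fit = cox_fit(df[["x"]], df["pfs_days"], df["pfs_event"])
        assert 0.8 <= fit.hazard_ratio["x"] <= 1.25
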