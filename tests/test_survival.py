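import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from lifelines.statistics import multivariate_logrank_test

from mrbalance import survival as surv
from mrbalance.cohort import tune_uniform_censoring


class TestKM:
    def test_all_censored_survival_one(self):
        curve = surv.km_curve([1, 2, 3], [0, 0, 0])
        assert curve.times.size == 0  # no drops: survival identically 1

    def test_three_events(self):
        curve = surv.km_curve([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_censor_before_event_hand_computed(self):
        # times 1(event), 1.5(censored), 2(event), 3(event)
        # S(1)=3/4; S(2)=3/4 * 1/2 = 3/8; S(3)=0
        curve = surv.km_curve([1, 1.5, 2, 3], [1, 0, 1, 1])
        np.testing.assert_allclose(curve.survival, [0.75, 0.375, 0.0])

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, size=200)
        curve = surv.km_curve(t, np.ones(200))
        emp = [(t > ti).mean() for ti in curve.times]
        np.testing.assert_allclose(curve.survival, emp, atol=1e-12)

    def test_matches_lifelines(self, rng):
        t = rng.exponential(10, size=300).round(1)
        e = (rng.random(300) < 0.7).astype(int)
        curve = surv.km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = pd.Series(curve.survival, index=curve.times)
        theirs = kmf.survival_function_["KM_estimate"]
        for ti, si in ours.items():
            assert si == pytest.approx(theirs.loc[ti], abs=1e-10)

    def test_all_zero_times_error(self):
        with pytest.raises(surv.SurvivalError):
            surv.km_curve([0, 0], [1, 1])


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 0, 1, 1, 0]
        res = surv.logrank_test(t + t, e + e, [0] * 5 + [1] * 5)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_five_identical_groups(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 1, 0, 1, 1]
        res = surv.logrank_test(t * 5, e * 5, np.repeat(np.arange(5), 5))
        assert res.df == 4
        assert res.p_value == pytest.approx(1.0)

    def test_power_on_planted_rate_ratio(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            t = np.concatenate([r.exponential(1.0, 200), r.exponential(3.0, 200)])
            g = np.repeat([0, 1], 200)
            res = surv.logrank_test(t, np.ones(400), g)
            hits += res.p_value < 0.001
        assert hits >= 95

    def test_matches_lifelines_two_group(self, rng):
        t = rng.exponential(5, 200).round(2)
        e = (rng.random(200) < 0.8).astype(int)
        g = (rng.random(200) < 0.5).astype(int)
        ours = surv.logrank_test(t, e, g)
        theirs = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert ours.statistic == pytest.approx(theirs.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(theirs.p_value, rel=1e-9)

    def test_matches_lifelines_k_group(self, rng):
        t = rng.exponential(5, 300).round(2)
        e = (rng.random(300) < 0.8).astype(int)
        g = rng.integers(0, 4, 300)
        ours = surv.logrank_test(t, e, g)
        theirs = multivariate_logrank_test(t, g, e)
        assert ours.statistic == pytest.approx(theirs.test_statistic, rel=1e-9)

    def test_empty_group_errors(self):
        with pytest.raises(surv.SurvivalError):
            surv.logrank_test([1, 2], [1, 1], [0, 0])

    def test_score_test_equals_logrank_tie_free(self, rng):
        t = rng.exponential(5, 150)  # continuous: no ties
        e = (rng.random(150) < 0.7).astype(int)
        g = (rng.random(150) < 0.5).astype(float)
        lr = surv.logrank_test(t, e, g.astype(int))
        score, _ = surv.cox_score_test(t, e, g)
        assert abs(lr.statistic - score) < 1e-6


class TestCox:
    def sim(self, seed, n=500, beta=0.7, binary=False):
        r = np.random.default_rng(seed)
        x = (r.random(n) < 0.5).astype(float) if binary else r.standard_normal(n)
        t = r.exponential(np.exp(-beta * x))
        c = r.exponential(2.0, n)
        return np.minimum(t, c), (t <= c).astype(int), x

    def test_matches_lifelines_efron(self):
        t, e, x = self.sim(1, n=400)
        ours = surv.cox_fit(t, e, x, ties="efron", names=["x"])
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert ours.beta[0] == pytest.approx(cph.params_["x"], abs=1e-5)
        assert ours.se[0] == pytest.approx(cph.standard_errors_["x"], abs=1e-5)

    def test_matches_lifelines_multivariate(self, rng):
        n = 300
        X = rng.standard_normal((n, 3))
        t = rng.exponential(np.exp(-(0.5 * X[:, 0] - 0.3 * X[:, 2])))
        e = np.ones(n)
        ours = surv.cox_fit(t, e, X, names=["a", "b", "c"])
        df = pd.DataFrame({"t": t, "e": e, "a": X[:, 0], "b": X[:, 1], "c": X[:, 2]})
        cph = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(ours.beta, cph.params_.values, atol=1e-4)

    def test_consistency_binary_unit_log_hr(self):
        t, e, x = self.sim(7, n=2000, beta=1.0, binary=True)
        fit = surv.cox_fit(t, e, x)
        assert 0.9 < fit.beta[0] < 1.1

    def test_null_coverage(self):
        covered = 0
        reps = 200
        for seed in range(reps):
            r = np.random.default_rng(1000 + seed)
            n = 1000
            x = r.standard_normal(n)
            t = r.exponential(1.0, n)  # independent of x
            fit = surv.cox_fit(t, np.ones(n), x)
            lo = fit.beta[0] - 1.959963985 * fit.se[0]
            hi = fit.beta[0] + 1.959963985 * fit.se[0]
            covered += lo <= 0 <= hi
        assert covered / reps == pytest.approx(0.95, abs=0.04)

    def test_time_rescaling_invariance(self):
        t, e, x = self.sim(3)
        f1 = surv.cox_fit(t, e, x)
        f2 = surv.cox_fit(2 * t, e, x)
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-9)

    def test_duplication_invariance_breslow(self):
        t, e, x = self.sim(4, n=200)
        f1 = surv.cox_fit(t, e, x, ties="breslow")
        f2 = surv.cox_fit(
            np.concatenate([t, t]), np.concatenate([e, e]),
            np.concatenate([x, x]), ties="breslow",
        )
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-7)

    def test_hr_ci_brackets_hr(self):
        t, e, x = self.sim(5)
        fit = surv.cox_fit(t, e, x)
        assert fit.ci_low[0] < fit.hr[0] < fit.ci_high[0]
        assert fit.hr[0] > 0

    def test_constant_covariate_errors(self, rng):
        with pytest.raises(surv.SurvivalError, match="constant"):
            surv.cox_fit(rng.exponential(1, 50), np.ones(50), np.ones(50))

    def test_perfect_separation_raises(self):
        # covariate perfectly orders survival: monotone likelihood
        n = 60
        t = np.arange(1.0, n + 1.0)
        x = np.arange(n, dtype=float)
        with pytest.raises((surv.ConvergenceError, surv.SurvivalError)):
            surv.cox_fit(t, np.ones(n), x)

    def test_missing_covariates_dropped(self, rng):
        t, e, x = self.sim(6, n=100)
        x = x.copy()
        x[:10] = np.nan
        fit = surv.cox_fit(t, e, x)
        assert fit.n_dropped == 10
        assert fit.n == 90


class TestCutpoint:
    def planted(self, seed, n=1000, cut=3.0, censor=0.2):
        r = np.random.default_rng(seed)
        m = r.uniform(0, 6, n)
        h = 0.001 * np.where(m < cut, 2.0, 1.0)
        t_lat = r.exponential(1 / h)
        c, _ = tune_uniform_censoring(t_lat, r.random(n), censor)
        return m, np.minimum(t_lat, c), (t_lat <= c).astype(int)

    def test_step_hazard_recovery(self):
        hits = 0
        for seed in range(20):
            m, t, e = self.planted(seed)
            res = surv.optimal_cutpoint(m, t, e)
            hits += abs(res.threshold - 3.0) <= 0.3
        assert hits >= 18

    def test_statistic_is_exhaustive_maximum(self):
        m, t, e = self.planted(0, n=200)
        res = surv.optimal_cutpoint(m, t, e)
        brute = max(
            surv.logrank_test(t, e, (m >= thr).astype(int)).statistic
            for thr in res.grid
        )
        assert res.statistic == brute

    def test_null_permutation_calibration(self):
        ok = 0
        reps = 10
        for seed in range(reps):
            r = np.random.default_rng(seed)
            n = 100
            m = r.uniform(0, 6, n)
            t = r.exponential(1.0, n)  # no MAA-survival relation
            res = surv.optimal_cutpoint(
                m, t, np.ones(n), n_perm=100, seed=seed
            )
            ok += res.permutation_p > 0.01
        assert ok >= 9

    def test_modes_agree_on_monotone_effect(self):
        m, t, e = self.planted(5, n=600, cut=3.0)
        lr = surv.optimal_cutpoint(m, t, e, mode="logrank")
        cx = surv.optimal_cutpoint(m, t, e, mode="cox_scan")
        assert abs(lr.threshold - cx.threshold) <= 0.5
        assert abs(lr.threshold - 3.0) <= 0.5 and abs(cx.threshold - 3.0) <= 0.5

    def test_group_sizes_sum(self):
        m, t, e = self.planted(2, n=300)
        res = surv.optimal_cutpoint(m, t, e)
        assert res.n_below + res.n_above == 300

    def test_too_few_subjects_errors(self, rng):
        with pytest.raises(surv.SurvivalError):
            surv.optimal_cutpoint(
                rng.random(30), rng.exponential(1, 30), np.ones(30)
            )


class TestStageStratified:
    def simulate(self, seed, beta_maa=-0.3, beta_stage=0.0, n=1500):
        r = np.random.default_rng(seed)
        m = r.uniform(0, 6, n)
        stage = r.choice(
            ["I", "II", "IIIA", "IIIB", "IV"], n, p=[0.35, 0.25, 0.2, 0.1, 0.1]
        )
        step = pd.Series(stage).map(
            {"I": 0, "II": 1, "IIIA": 2, "IIIB": 2, "IV": 3}
        ).to_numpy()
        lam = np.exp(beta_maa * m + beta_stage * step)
        t = r.exponential(1 / lam)
        clin = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "os_time": t,
                "os_event": np.ones(n, dtype=int),
                "stage": stage,
                "sex": r.choice(["M", "F"], n),
                "age": r.normal(65, 8, n),
                "pack_years": r.gamma(2, 20, n),
            }
        )
        return m, clin

    def test_stage_independent_effect_recovered_per_stage(self):
        hits, total = 0, 0
        for seed in range(10):
            m, clin = self.simulate(seed)
            res = surv.stage_stratified_analysis(m, clin)
            for stage, fit in res["univariate_by_stage"].items():
                if fit.get("skipped"):
                    continue
                lo, hi = fit["covariates"]["maa"]["hr_ci"]
                total += 1
                hits += lo <= np.exp(-0.3) <= hi
        assert total > 0
        assert hits / total >= 0.9

    def test_stage_only_effect_maa_ci_covers_null(self):
        covered = 0
        for seed in range(10):
            m, clin = self.simulate(seed, beta_maa=0.0, beta_stage=0.5)
            res = surv.stage_stratified_analysis(m, clin)
            lo, hi = res["multivariate"]["covariates"]["maa"]["hr_ci"]
            covered += lo <= 1.0 <= hi
        assert covered >= 8

    def test_iiia_iiib_pooled_in_multivariate_design(self):
        stages = pd.Series(["I", "IIIA", "IIIB", "II", "IV"])
        dummies = surv._stage_dummies(stages)
        assert dummies.loc[1, "stage_III"] == 1.0
        assert dummies.loc[2, "stage_III"] == 1.0
        assert dummies.loc[0].sum() == 0.0

    def test_small_stage_skipped(self):
        m, clin = self.simulate(0, n=300)
        clin.loc[clin["stage"] == "IIIB", "os_event"] = 0  # kill IIIB events
        res = surv.stage_stratified_analysis(m, clin)
        if "IIIB" in res["univariate_by_stage"]:
            assert res["univariate_by_stage"]["IIIB"].get("skipped", False)
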