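"""Stratification and validation statistics against hand/brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from lncpair.evaluate import (
    aic_optimal_cutoff,
    assign_risk_groups,
    chi_square_test,
    clinical_association_tests,
    independent_prognostic_analysis,
    km_estimate,
    logrank_test,
    td_roc_auc,
)

from conftest import toy_survival


# ---------------------------------------------------------------------------
# independent reference implementations (test-local)
# ---------------------------------------------------------------------------


def km_product_limit(time, event, t):
    """Hand product-limit estimator evaluated at t (right-continuous)."""
    s = 1.0
    for u in sorted(set(time[event == 1])):
        if u > t:
            break
        n_at_risk = np.sum(time >= u)
        d = np.sum((time == u) & (event == 1))
        s *= 1.0 - d / n_at_risk
    return s


def ipcw_auc_brute(scores, time, event, horizon):
    """Explicit weighted pairwise enumeration of the cumulative/dynamic AUC."""
    cens_time = time
    cens_event = 1 - event
    cases = [i for i in range(len(time)) if time[i] <= horizon and event[i] == 1]
    controls = [j for j in range(len(time)) if time[j] > horizon]
    num = den = 0.0
    for i in cases:
        w = 1.0 / km_product_limit(cens_time, cens_event, time[i] - 1e-9)
        for j in controls:
            if scores[i] > scores[j]:
                num += w
            elif scores[i] == scores[j]:
                num += 0.5 * w
        den += w * len(controls)
    return num / den


def logrank_brute(time, event, grp):
    """2x2 hypergeometric accumulation of the log-rank chi-square."""
    o_minus_e = 0.0
    var = 0.0
    for u in sorted(set(time[event == 1])):
        at = time >= u
        n = at.sum()
        n1 = (at & (grp == 1)).sum()
        d = ((time == u) & (event == 1)).sum()
        d1 = ((time == u) & (event == 1) & (grp == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


class TestKM:
    def test_three_subject_hand_example(self):
        surv = toy_survival([1, 2, 3], [1, 0, 1])
        km = km_estimate(surv)
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(2) == pytest.approx(2 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)
        assert km.survival_at(0.5) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(1, 50)
        km = km_estimate(toy_survival(t, np.ones(50)))
        for u in np.quantile(t, [0.2, 0.5, 0.9]):
            assert km.survival_at(u) == pytest.approx(np.mean(t > u), abs=1e-12)

    def test_all_censored_flat_at_one(self):
        km = km_estimate(toy_survival([1, 2, 3], [0, 0, 0]))
        assert (km.survival == 1.0).all()

    def test_duplicate_subject_invariance(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(1, 30)
        e = (rng.random(30) < 0.7).astype(int)
        km1 = km_estimate(toy_survival(t, e))
        km2 = km_estimate(toy_survival(np.tile(t, 2), np.tile(e, 2)))
        for u in np.linspace(0.1, t.max(), 7):
            assert km1.survival_at(u) == pytest.approx(km2.survival_at(u), abs=1e-12)

    def test_empty_group_errors(self):
        surv = toy_survival([1.0], [1])
        with pytest.raises(ValueError):
            km_estimate(surv.subset([]))


class TestLogrank:
    def _toy(self):
        rng = np.random.default_rng(2)
        time = np.concatenate([rng.integers(1, 8, 10), rng.integers(3, 12, 10)]).astype(
            float
        )
        event = (rng.random(20) < 0.8).astype(int)
        grp = np.array([1] * 10 + [0] * 10)
        return time, event, grp

    def test_matches_hypergeometric_accumulation(self):
        time, event, grp = self._toy()
        surv = toy_survival(time, event)
        groups = pd.Series(grp, index=surv.sample_ids)
        res = logrank_test(surv, groups)
        assert res.statistic == pytest.approx(logrank_brute(time, event, grp), rel=1e-9)

    def test_relabeling_symmetric(self):
        time, event, grp = self._toy()
        surv = toy_survival(time, event)
        a = logrank_test(surv, pd.Series(grp, index=surv.sample_ids))
        b = logrank_test(surv, pd.Series(1 - grp, index=surv.sample_ids))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_single_group_errors(self):
        surv = toy_survival([1, 2], [1, 1])
        with pytest.raises(ValueError):
            logrank_test(surv, pd.Series([1, 1], index=surv.sample_ids))


# ---------------------------------------------------------------------------
# IPCW time-dependent ROC
# ---------------------------------------------------------------------------


class TestTdROC:
    def test_constant_scores_give_half(self):
        surv = toy_survival([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1])
        scores = pd.Series(1.0, index=surv.sample_ids)
        with pytest.warns(UserWarning):
            roc = td_roc_auc(scores, surv, 3.5)
        assert roc.auc == pytest.approx(0.5)

    def test_perfect_marker_auc_one(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.exponential(1, 25))
        surv = toy_survival(t, np.ones(25))
        scores = pd.Series(-t, index=surv.sample_ids)
        assert td_roc_auc(scores, surv, np.median(t)).auc == pytest.approx(1.0)
        assert td_roc_auc(-scores, surv, np.median(t)).auc == pytest.approx(0.0)

    def test_hand_built_censored_example_matches_brute_force(self):
        """n=12 with 2 censored subjects: AUC equals weighted enumeration."""
        time = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12], dtype=float)
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 1, 1, 1])
        rng = np.random.default_rng(4)
        scores_arr = rng.normal(size=12) - 0.3 * time
        surv = toy_survival(time, event)
        scores = pd.Series(scores_arr, index=surv.sample_ids)
        for horizon in (4.5, 6.5, 9.5):
            got = td_roc_auc(scores, surv, horizon).auc
            expected = ipcw_auc_brute(scores_arr, time, event, horizon)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(1, 40)
        e = (rng.random(40) < 0.8).astype(int)
        surv = toy_survival(t, e)
        s = pd.Series(rng.normal(size=40), index=surv.sample_ids)
        h = float(np.median(t))
        assert td_roc_auc(s, surv, h).auc == pytest.approx(
            td_roc_auc(3.0 * s + 11.0, surv, h).auc, abs=1e-12
        )

    def test_monotone_sweep(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(1, 40)
        surv = toy_survival(t, np.ones(40))
        roc = td_roc_auc(pd.Series(rng.normal(size=40), index=surv.sample_ids), surv,
                         float(np.median(t)))
        assert (np.diff(roc.sensitivity) >= -1e-12).all()
        assert (np.diff(roc.specificity) <= 1e-12).all()

    def test_horizon_out_of_range_errors(self):
        surv = toy_survival([1, 2, 3], [1, 1, 1])
        s = pd.Series([3.0, 2.0, 1.0], index=surv.sample_ids)
        with pytest.raises(ValueError):
            td_roc_auc(s, surv, 10.0)


# ---------------------------------------------------------------------------
# AIC cutoff and risk groups
# ---------------------------------------------------------------------------


def efron_free_loglik(beta, x, time, event):
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestAicCutoff:
    def _clusters(self, seed, n=60):
        """Two risk clusters on discrete score levels (as a sum of a few
        binary pair indicators would produce) with hazard ratio exp(1.5)."""
        rng = np.random.default_rng(seed)
        scores = np.concatenate(
            [rng.choice([0.0, 0.25, 0.5], n), rng.choice([2.0, 2.25, 2.5], n)]
        )
        hazard = np.where(scores > 1.5, np.exp(1.5), 1.0) * 0.5
        t = rng.exponential(1.0 / hazard)
        surv = toy_survival(t, np.ones(2 * n))
        return pd.Series(scores, index=surv.sample_ids), surv

    def test_recovers_separating_cutoff(self):
        hits = 0
        for seed in range(10):
            scores, surv = self._clusters(seed)
            res = aic_optimal_cutoff(scores, surv)
            hits += 0.5 < res.cutoff < 2.0
        assert hits >= 9

    def test_candidate_aics_match_independent_refits(self):
        scores, surv = self._clusters(0, n=25)
        res = aic_optimal_cutoff(scores, surv)
        x_all = scores.to_numpy()
        t = surv.time.to_numpy()
        e = surv.event.to_numpy()
        for cut in list(res.aic_by_candidate.index)[::7]:
            x = (x_all > cut).astype(float)
            opt = minimize_scalar(
                lambda b: -efron_free_loglik(b, x, t, e), bounds=(-6, 6),
                method="bounded", options={"xatol": 1e-10},
            )
            expected = 2.0 + 2.0 * opt.fun
            assert res.aic_by_candidate[cut] == pytest.approx(expected, abs=1e-5)

    def test_group_floor_respected(self):
        scores, surv = self._clusters(1)
        res = aic_optimal_cutoff(scores, surv, min_group_frac=0.10)
        n = len(scores)
        n_high = (scores > res.cutoff).sum()
        assert min(n_high, n - n_high) >= 0.10 * n

    def test_all_equal_scores_error(self):
        surv = toy_survival([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError):
            aic_optimal_cutoff(pd.Series(1.0, index=surv.sample_ids), surv)


class TestAssignGroups:
    def test_boundary_is_strict(self):
        scores = pd.Series({"a": 1.0, "b": 1.0 + 1e-9, "c": 0.5})
        groups = assign_risk_groups(scores, 1.0)
        assert groups.tolist() == ["low", "high", "low"]

    def test_partition_sizes(self):
        rng = np.random.default_rng(7)
        scores = pd.Series(rng.normal(size=50))
        groups = assign_risk_groups(scores, 0.0)
        assert (groups == "high").sum() + (groups == "low").sum() == 50


# ---------------------------------------------------------------------------
# clinical association and independence
# ---------------------------------------------------------------------------


class TestClinicalTests:
    def test_chi_square_hand_value(self):
        chi2, p = chi_square_test(np.array([[20, 10], [10, 20]]))
        assert chi2 == pytest.approx(20 / 3, abs=1e-9)
        assert 0 < p < 0.05

    def test_single_level_covariate_errors(self):
        rng = np.random.default_rng(8)
        idx = [f"P{i}" for i in range(20)]
        scores = pd.Series(rng.normal(size=20), index=idx)
        groups = pd.Series(["high", "low"] * 10, index=idx)
        clin = pd.DataFrame({"stage": [2] * 20}, index=idx)
        with pytest.raises(ValueError):
            clinical_association_tests(scores, groups, clin, covariates=["stage"])

    def test_monotone_dependence_detected(self):
        rng = np.random.default_rng(9)
        n = 120
        idx = [f"P{i}" for i in range(n)]
        stage = rng.integers(1, 5, n)
        scores = pd.Series(0.8 * stage + rng.normal(size=n), index=idx)
        groups = assign_risk_groups(scores, float(scores.median()))
        clin = pd.DataFrame({"stage": stage}, index=idx)
        out = clinical_association_tests(scores, groups, clin, covariates=["stage"])
        kw = out[out["test"] == "kruskal-wallis"].iloc[0]
        assert kw["p"] < 1e-6


class TestIndependence:
    def _cohort(self, seed, n=200, score_signal=True):
        rng = np.random.default_rng(seed)
        idx = [f"P{i}" for i in range(n)]
        score = rng.normal(size=n)
        stage = rng.integers(1, 5, n)
        lp = score if score_signal else np.zeros(n)
        t = rng.exponential(np.exp(-lp))
        surv = toy_survival(t, np.ones(n), index=idx)
        clin = pd.DataFrame(
            {
                "age": rng.integers(40, 85, n),
                "gender": rng.choice(["MALE", "FEMALE"], n),
                "stage": stage,
            },
            index=idx,
        )
        return pd.Series(score, index=idx), clin, surv

    def test_true_score_significant_stage_not(self):
        scores, clin, surv = self._cohort(0)
        uni, multi = independent_prognostic_analysis(scores, clin, surv)
        assert multi.loc["risk_score", "p"] < 1e-4
        assert multi.loc["stage", "p"] > 0.01

    def test_permuted_covariate_hr_near_one(self):
        scores, clin, surv = self._cohort(1, score_signal=False)
        _, multi = independent_prognostic_analysis(scores, clin, surv)
        assert multi["HR"].between(0.8, 1.25).all()

    def test_univariate_table_matches_direct_single_covariate_fit(self):
        from lncpair.signature import fit_cox_ph

        scores, clin, surv = self._cohort(2, n=80)
        uni, _ = independent_prognostic_analysis(scores, clin, surv)
        direct = fit_cox_ph(scores.to_frame("risk_score"), surv)
        assert uni.loc["risk_score", "beta"] == pytest.approx(
            direct.table.loc["risk_score", "beta"], abs=1e-10
        )
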