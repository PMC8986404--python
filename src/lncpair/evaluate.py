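"""Risk stratification and validation statistics.

Time-dependent ROC uses the cumulative-case / dynamic-control definition
with inverse-probability-of-censoring weights (IPCW): at horizon t, cases
are subjects with an observed event by t, controls are subjects still at
risk beyond t, case i is weighted by 1/G(T_i-) and every control by 1/G(t),
where G is the Kaplan-Meier estimate of the censoring survival function.
The risk-score cutoff is chosen by minimizing the AIC (2k - 2 logPL, k = 1)
of a single-covariate Cox fit on the binary high/low indicator over
candidate cutoffs; group comparisons use the standard log-rank statistic
and rank tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .datatypes import SurvivalData
from .signature import CoxFitResult, fit_cox_ph

logger = logging.getLogger(__name__)

HIGH = "high"
LOW = "low"


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit curve: timeline, survival probability, numbers at risk."""

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(surv: SurvivalData) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one group of subjects."""
    if len(surv.sample_ids) == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time, surv.event)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    survival = kmf.survival_function_.iloc[:, 0].to_numpy()
    at_risk = (
        kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy()
    )
    return KMCurve(timeline=timeline, survival=survival, at_risk=at_risk)


@dataclass
class LogrankResult:
    statistic: float
    p: float
    df: int = 1


def logrank_test(surv: SurvivalData, groups: pd.Series) -> LogrankResult:
    """Log-rank chi-square over >=2 non-empty groups."""
    g = groups.reindex(surv.sample_ids)
    if g.isna().any():
        raise ValueError("group labels missing for some samples")
    levels = g.unique()
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if len(levels) == 2:
        a, b = (g == levels[0], g == levels[1])
        res = _ll_logrank(
            surv.time[a], surv.time[b], surv.event[a], surv.event[b]
        )
        return LogrankResult(float(res.test_statistic), float(res.p_value))
    res = multivariate_logrank_test(surv.time, g, surv.event)
    return LogrankResult(
        float(res.test_statistic), float(res.p_value), df=len(levels) - 1
    )


# ---------------------------------------------------------------------------
# IPCW time-dependent ROC
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def _censoring_survival(surv: SurvivalData) -> KMCurve:
    """KM of the censoring distribution (events and censorings swapped)."""
    flipped = SurvivalData(
        pd.DataFrame(
            {"time": surv.time, "event": 1 - surv.event}, index=surv.sample_ids
        )
    )
    return km_estimate(flipped)


def td_roc_auc(scores: pd.Series, surv: SurvivalData, horizon: float) -> ROCResult:
    """Cumulative/dynamic IPCW ROC and AUC at one horizon.

    AUC is the IPCW-weighted probability that a random case scores above a
    random control (ties count 1/2), which equals the trapezoidal area under
    the weighted ROC sweep.
    """
    s = scores.reindex(surv.sample_ids).to_numpy(dtype=float)
    if np.isnan(s).any():
        raise ValueError("scores missing for some samples")
    time = surv.time.to_numpy(dtype=float)
    event = surv.event.to_numpy()
    if horizon <= 0 or horizon >= time.max():
        raise ValueError("horizon must lie within observed follow-up")

    case = (time <= horizon) & (event == 1)
    control = time > horizon
    if case.sum() == 0:
        raise ValueError("no events before the horizon")
    if control.sum() == 0:
        raise ValueError("no controls beyond the horizon")

    G = _censoring_survival(surv)
    # left limit G(T-): survival just before the case's event time
    g_case = np.array([G.survival_at(t - 1e-9) for t in time[case]])
    if (g_case <= 0).any():
        keep = g_case > 0
        logger.warning("dropping %d cases with zero IPCW mass", int((~keep).sum()))
        case_idx = np.flatnonzero(case)[keep]
        case = np.zeros_like(case)
        case[case_idx] = True
        g_case = g_case[keep]
    w_case = 1.0 / g_case  # controls share the constant weight 1/G(horizon)

    s_case, s_ctrl = s[case], s[control]
    if np.ptp(s) == 0:
        warnings.warn("all scores identical; AUC = 0.5", stacklevel=2)

    thresholds = np.unique(s)[::-1]
    wsum = w_case.sum()
    sens = np.array([(w_case[s_case > c]).sum() / wsum for c in thresholds])
    spec = np.array([(s_ctrl <= c).mean() for c in thresholds])

    gt = (s_case[:, None] > s_ctrl[None, :]).astype(float)
    gt += 0.5 * (s_case[:, None] == s_ctrl[None, :])
    auc = float((w_case @ gt).sum() / (wsum * len(s_ctrl)))
    return ROCResult(
        horizon=float(horizon),
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
    )


# ---------------------------------------------------------------------------
# AIC-optimal cutoff and risk groups
# ---------------------------------------------------------------------------


def assign_risk_groups(scores: pd.Series, cutoff: float) -> pd.Series:
    """Score strictly above the cutoff -> "high"; at or below -> "low"."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return pd.Series(
        np.where(scores.to_numpy(dtype=float) > cutoff, HIGH, LOW),
        index=scores.index,
        name="risk_group",
    )


@dataclass
class CutoffResult:
    cutoff: float
    aic_by_candidate: pd.Series
    groups: pd.Series


def _binary_cox_max_loglik(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Maximized Efron log partial likelihood of a single binary covariate.

    With a binary covariate the likelihood depends on the data only through
    per-event-time at-risk and event counts in each arm, so the profile can
    be evaluated in O(n) per beta and maximized by bounded scalar search.
    """
    order = np.argsort(time, kind="stable")
    t, e, xb = time[order], event[order], x[order].astype(float)
    # suffix counts: at risk at t_i = all j with t_j >= t_i
    n_total = len(t)
    suffix_x = np.cumsum(xb[::-1])[::-1]
    first = np.searchsorted(t, t, side="left")
    ev = e == 1
    ev_times, grp_idx = np.unique(t[ev], return_inverse=True)
    pos = np.searchsorted(t, ev_times, side="left")
    n_risk = n_total - pos
    n1_risk = suffix_x[pos]
    d = np.bincount(grp_idx)
    d1 = np.bincount(grp_idx, weights=xb[ev])

    # flatten the Efron correction terms: one entry per (event time, l<d)
    grp = np.repeat(np.arange(len(d)), d)
    frac = np.concatenate([np.arange(k) / k for k in d]) if len(d) else np.array([])

    def neg_ll(beta: float) -> float:
        eb = np.exp(beta)
        sum_risk = (n_risk - n1_risk) + n1_risk * eb
        sum_d = (d - d1) + d1 * eb
        ll = beta * d1.sum() - np.log(sum_risk[grp] - frac * sum_d[grp]).sum()
        return -ll

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        neg_ll, bounds=(-15.0, 15.0), method="bounded", options={"xatol": 1e-10}
    )
    return -float(res.fun)


def aic_optimal_cutoff(
    scores: pd.Series,
    surv: SurvivalData,
    min_group_frac: float = 0.10,
) -> CutoffResult:
    """Cutoff minimizing the AIC of the binary high/low Cox model.

    Candidates are the midpoints of consecutive sorted unique scores,
    restricted so each side keeps at least ``min_group_frac`` of the
    samples.  AIC = 2*1 - 2*logPL of the one-covariate fit.
    """
    s = scores.reindex(surv.sample_ids).astype(float)
    uniq = np.unique(s.to_numpy())
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct scores")
    if surv.n_events < 2:
        raise ValueError("need at least 2 events")
    n = len(s)
    arr = s.to_numpy()
    time = surv.time.to_numpy(dtype=float)
    event = surv.event.to_numpy()
    candidates = []
    for cut in (uniq[:-1] + uniq[1:]) / 2.0:
        n_high = int((arr > cut).sum())
        if min(n_high, n - n_high) >= min_group_frac * n:
            candidates.append(cut)
    if not candidates:
        raise ValueError("no admissible cutoff candidates")

    aics = {}
    for cut in candidates:
        aics[cut] = 2.0 - 2.0 * _binary_cox_max_loglik(arr > cut, time, event)
    aic = pd.Series(aics, name="aic").sort_index()
    best = float(aic.idxmin())
    return CutoffResult(
        cutoff=best, aic_by_candidate=aic, groups=assign_risk_groups(s, best)
    )


# ---------------------------------------------------------------------------
# clinical association and independence analyses
# ---------------------------------------------------------------------------


def clinical_association_tests(
    scores: pd.Series,
    groups: pd.Series,
    clinical: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Risk score / risk group vs clinical covariates.

    Per covariate: score distribution across 2 levels -> Wilcoxon rank-sum;
    across >2 levels -> Kruskal-Wallis; risk-group membership vs the
    covariate -> chi-square on the contingency table (no continuity
    correction).  Returns a tidy frame (covariate, test, statistic, p).
    """
    covariates = covariates or ["age", "gender", "stage", "T", "N", "M"]
    rows = []
    for cov in covariates:
        col = clinical[cov].reindex(scores.index)
        mask = col.notna()
        levels = col[mask].unique()
        if len(levels) < 2:
            raise ValueError(f"covariate {cov!r} has a single level")
        vals = [scores[mask][col[mask] == lv].to_numpy() for lv in sorted(levels)]
        if len(levels) == 2:
            stat, p = stats.mannwhitneyu(*vals, alternative="two-sided")
            test = "wilcoxon-rank-sum"
        else:
            stat, p = stats.kruskal(*vals)
            test = "kruskal-wallis"
        rows.append({"covariate": cov, "test": test, "statistic": stat, "p": p})

        table = pd.crosstab(groups[mask], col[mask])
        if table.shape[0] > 1 and table.shape[1] > 1:
            chi2, chi_p, _, _ = stats.chi2_contingency(table, correction=False)
            rows.append(
                {"covariate": cov, "test": "chi-square", "statistic": chi2, "p": chi_p}
            )
    return pd.DataFrame(rows)


def chi_square_test(table: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Pearson chi-square on a contingency table, no continuity correction."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


def _design_matrix(
    scores: pd.Series, clinical: pd.DataFrame, stage_coding: str = "ordinal"
) -> pd.DataFrame:
    X = pd.DataFrame(index=scores.index)
    X["risk_score"] = scores.astype(float)
    X["age"] = pd.to_numeric(clinical["age"].reindex(scores.index), errors="coerce")
    gender = clinical["gender"].reindex(scores.index)
    X["gender"] = (gender.astype(str).str.upper().isin(["MALE", "M", "1"])).astype(float)
    stage = pd.to_numeric(clinical["stage"].reindex(scores.index), errors="coerce")
    if stage_coding == "ordinal":
        X["stage"] = stage
    else:
        for lv in sorted(stage.dropna().unique())[1:]:
            X[f"stage_{int(lv)}"] = (stage == lv).astype(float)
    return X


def independent_prognostic_analysis(
    scores: pd.Series,
    clinical: pd.DataFrame,
    surv: SurvivalData,
    stage_coding: str = "ordinal",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Is the risk score prognostic after adjusting for clinical covariates?

    Returns (univariate table, multivariate table): one single-covariate Cox
    fit per term, then one joint fit, each row carrying beta, HR, 95% CI and
    the Wald p.  Complete cases only; a warning is logged when there are
    fewer than 10 complete cases per covariate.
    """
    X = _design_matrix(scores, clinical, stage_coding)
    complete = X.dropna()
    if len(complete) < 10 * X.shape[1]:
        logger.warning(
            "only %d complete cases for %d covariates", len(complete), X.shape[1]
        )
    sub = surv.align(complete.index)
    complete = complete.loc[sub.sample_ids]

    uni_rows = []
    for col in complete.columns:
        try:
            fit = fit_cox_ph(complete[[col]], sub)
            uni_rows.append(fit.table)
        except ValueError as err:
            logger.warning("univariate fit for %s failed: %s", col, err)
    uni = pd.concat(uni_rows) if uni_rows else pd.DataFrame()
    multi = fit_cox_ph(complete, sub).table
    return uni, multi
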