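"""Prognostic pair selection and the risk score.

The selection funnel mirrors the standard pair-signature recipe:

1. univariate Cox screen per pair indicator (keep p < 0.05);
2. bootstrap-stabilized LASSO-Cox — on each of B patient resamples a full
   L1-penalized Cox path is fitted with the penalty chosen by k-fold
   cross-validated partial-likelihood deviance (minimum rule), and a pair's
   selection frequency is the number of resamples in which it enters the
   chosen support; pairs with frequency strictly above a count threshold
   (default 100 of 1000) survive;
3. an unpenalized multivariate Cox fit on the surviving pairs supplies the
   coefficients ``beta_i`` of the risk score ``RiskScore = sum_i beta_i S_i``.

Unpenalized fits use Efron tie handling (day-resolution survival data are
heavily tied); the penalized path and the cross-validation deviance use the
Breslow approximation, which is the convention of coordinate-descent Cox
solvers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .datatypes import SurvivalData
from .pairs import LncPair, PairFeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CoxFitResult",
    "fit_cox_ph",
    "univariate_cox_screen",
    "LassoCoxCVResult",
    "lasso_cox_cv",
    "StabilitySelectionResult",
    "bootstrap_stability_select",
    "RiskModel",
    "multivariate_cox_fit",
    "compute_risk_scores",
]


# ---------------------------------------------------------------------------
# unpenalized Cox (Efron ties) via lifelines
# ---------------------------------------------------------------------------


@dataclass
class CoxFitResult:
    """Wald table plus the maximized log partial likelihood.

    ``table`` is indexed by covariate with columns
    ``beta, se, HR, ci_low, ci_high, p`` (CI bounds on the HR scale).
    """

    table: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int

    @property
    def aic(self) -> float:
        return 2.0 * len(self.table) - 2.0 * self.log_likelihood


def _align(features: pd.DataFrame, surv: SurvivalData) -> pd.DataFrame:
    common = [s for s in features.index if s in surv.sample_ids]
    if len(common) < len(features):
        logger.warning(
            "dropping %d samples without survival data", len(features) - len(common)
        )
    return features.loc[common]


def fit_cox_ph(features: pd.DataFrame, surv: SurvivalData) -> CoxFitResult:
    """Cox proportional-hazards fit (Efron ties) of samples x covariates.

    Raises ``ValueError`` on fewer than 2 events or a constant covariate and
    re-raises non-convergence with diagnostics.
    """
    X = _align(features, surv)
    sub = surv.align(X.index)
    if sub.n_events < 2:
        raise ValueError(f"need >=2 events, got {sub.n_events}")
    sd = X.std(axis=0, ddof=0)
    const = sd.index[sd == 0].tolist()
    if const:
        raise ValueError(f"constant covariate(s): {const}")

    df = X.astype(float).copy()
    df["time"] = sub.time.to_numpy(dtype=float)
    df["event"] = sub.event.to_numpy()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:  # pragma: no cover - diagnostic path
        raise ValueError(f"Cox fit did not converge: {err}") from err
    s = cph.summary
    table = pd.DataFrame(
        {
            "beta": s["coef"],
            "se": s["se(coef)"],
            "HR": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    table.index.name = "covariate"
    return CoxFitResult(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=int(sub.n_events),
    )


def univariate_cox_screen(
    pm: PairFeatureMatrix, surv: SurvivalData, alpha: float = 0.05
) -> pd.DataFrame:
    """Single-covariate Cox fit per pair; keep pairs with Wald p < alpha.

    Individual fit failures (constant indicator in the matched samples,
    non-convergence) are logged and skipped, never fatal.  Returns the
    survivors as a DataFrame indexed by pair name with the Wald columns of
    :class:`CoxFitResult`.
    """
    rows = {}
    for name in pm.pair_names:
        feat = pm.values.loc[[name]].T.astype(float)
        try:
            res = fit_cox_ph(feat, surv)
        except ValueError as err:
            logger.warning("univariate screen skipped %s: %s", name, err)
            continue
        rows[name] = res.table.iloc[0]
    if not rows:
        return pd.DataFrame(columns=["beta", "se", "HR", "ci_low", "ci_high", "p"])
    out = pd.DataFrame(rows).T
    out.index.name = "pair"
    return out[out["p"] < alpha]


# ---------------------------------------------------------------------------
# penalized path + cross-validation
# ---------------------------------------------------------------------------


def breslow_loglik(
    lp: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow-approximation log partial likelihood at a linear predictor."""
    order = np.argsort(time, kind="stable")
    lp, time, event = lp[order], time[order], event[order]
    # suffix log-sum-exp of lp; risk set of t includes every j with time >= t
    m = lp.max() if len(lp) else 0.0
    suffix = np.cumsum(np.exp(lp - m)[::-1])[::-1]
    first = np.searchsorted(time, time, side="left")
    log_risk = m + np.log(suffix[first])
    return float(np.sum((lp - log_risk)[event == 1]))


def _cv_folds(
    n: int, k: int, event: np.ndarray, rng: np.random.Generator
) -> list[np.ndarray]:
    """Shuffled k-fold assignment; redraw if any training part lacks 2 events
    or any held-out part lacks an event."""
    for attempt in range(50):
        assign = rng.permutation(n) % k
        ok = all(
            event[assign != f].sum() >= 2 and event[assign == f].sum() >= 1
            for f in range(k)
        )
        if ok:
            if attempt:
                logger.warning("redrew CV folds %d time(s) (event-free fold)", attempt)
            return [assign == f for f in range(k)]
    raise ValueError("could not build cross-validation folds with events in each fold")


@dataclass
class LassoCoxCVResult:
    alpha: float
    coefs: pd.Series
    support: list[str]
    alphas: np.ndarray
    cv_deviance: np.ndarray | None


def _coxnet_path(X: np.ndarray, time, event, alphas, n_alphas, alpha_min_ratio):
    y = Surv.from_arrays(event.astype(bool), time)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0,
        alphas=alphas,
        n_alphas=n_alphas,
        alpha_min_ratio=alpha_min_ratio,
        fit_baseline_model=False,
    )
    model.fit(X, y)
    return model.alphas_, model.coef_  # coef_: (n_features, n_alphas)


def _lasso_cv_arrays(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    k: int,
    rng: np.random.Generator,
    alphas=None,
    n_alphas: int = 100,
    alpha_min_ratio: float = 1e-3,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray | None]:
    """Core CV-LASSO on numpy arrays; returns (alpha, coefs, alphas, cv_dev).

    The CV criterion is the Verweij–van Houwelingen partial-likelihood
    deviance: for each fold, -2 * (logPL of all data minus logPL of the
    training part, both at the training-fold coefficients), summed over folds
    and minimized over the path.
    """
    path_alphas, path_coefs = _coxnet_path(
        X, time, event, alphas, n_alphas, alpha_min_ratio
    )
    if len(path_alphas) == 1:
        return float(path_alphas[0]), path_coefs[:, 0], path_alphas, None

    folds = _cv_folds(len(time), k, event, rng)
    dev = np.zeros(len(path_alphas))
    for test_mask in folds:
        train = ~test_mask
        a_tr, c_tr = _coxnet_path(
            X[train], time[train], event[train], path_alphas, n_alphas, alpha_min_ratio
        )
        # coxnet may truncate the requested grid; align by position
        lp_all = X @ c_tr
        lp_tr = X[train] @ c_tr
        for j in range(len(a_tr)):
            ll_all = breslow_loglik(lp_all[:, j], time, event)
            ll_tr = breslow_loglik(lp_tr[:, j], time[train], event[train])
            dev[j] += -2.0 * (ll_all - ll_tr)
        dev[len(a_tr):] += np.inf  # alphas the fold never reached
    best = int(np.argmin(dev))
    return float(path_alphas[best]), path_coefs[:, best], path_alphas, dev


def lasso_cox_cv(
    features: pd.DataFrame,
    surv: SurvivalData,
    k: int = 10,
    seed: int | None = None,
    alphas: Sequence[float] | None = None,
    n_alphas: int = 100,
    alpha_min_ratio: float = 1e-3,
) -> LassoCoxCVResult:
    """L1-penalized Cox path with the penalty picked by k-fold CV deviance.

    Parameters
    ----------
    features : DataFrame, samples x features.
    surv : SurvivalData
    k : folds (>= 2); ignored when a single fixed ``alphas`` value is given.
    alphas : optional explicit penalty grid (descending).
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    X = _align(features.astype(float), surv)
    sub = surv.align(X.index)
    sd = X.std(axis=0, ddof=0)
    const = sd.index[sd == 0].tolist()
    if const:
        logger.warning("lasso_cox_cv: dropping constant feature(s) %s", const)
        X = X.drop(columns=const)
    if X.shape[1] == 0:
        raise ValueError("no non-constant features")
    rng = np.random.default_rng(seed)
    alpha, coefs, grid, dev = _lasso_cv_arrays(
        X.to_numpy(),
        sub.time.to_numpy(dtype=float),
        sub.event.to_numpy(),
        k,
        rng,
        alphas=None if alphas is None else np.asarray(alphas, dtype=float),
        n_alphas=n_alphas,
        alpha_min_ratio=alpha_min_ratio,
    )
    coefs = pd.Series(coefs, index=X.columns, name="coef")
    support = coefs.index[coefs != 0].tolist()
    return LassoCoxCVResult(alpha, coefs, support, grid, dev)


# ---------------------------------------------------------------------------
# bootstrap stability selection
# ---------------------------------------------------------------------------


@dataclass
class StabilitySelectionResult:
    """Per-pair selection counts over B bootstrap CV-LASSO runs."""

    frequency: pd.Series
    B: int
    freq_threshold: int
    lambda_rule: str = "cv-min-deviance"
    n_failures: int = 0

    @property
    def selected(self) -> list[str]:
        return self.frequency.index[self.frequency > self.freq_threshold].tolist()


def bootstrap_stability_select(
    features: pd.DataFrame,
    surv: SurvivalData,
    B: int = 1000,
    freq_threshold: int = 100,
    k: int = 10,
    seed: int | None = None,
    n_alphas: int = 100,
    alpha_min_ratio: float = 1e-3,
) -> StabilitySelectionResult:
    """Count, over B patient bootstrap resamples, how often each feature
    enters the CV-chosen LASSO-Cox support; select frequency > threshold.

    Each resample draws patients with replacement and runs the full CV-LASSO
    (path fit + k-fold penalty choice).  Individual resample failures are
    logged and counted; the run aborts only if more than 10% fail.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if freq_threshold >= B:
        raise ValueError("freq_threshold must be < B")
    X = _align(features.astype(float), surv)
    sub = surv.align(X.index)
    Xa = X.to_numpy()
    time = sub.time.to_numpy(dtype=float)
    event = sub.event.to_numpy()
    n, p = Xa.shape

    counts = np.zeros(p, dtype=int)
    n_failures = 0
    for child in np.random.SeedSequence(seed).spawn(B):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        Xb, tb, eb = Xa[idx], time[idx], event[idx]
        keep = Xb.std(axis=0) > 0
        if eb.sum() < max(2, k) or not keep.any():
            n_failures += 1
            logger.warning("bootstrap resample degenerate; skipped")
            continue
        try:
            _, coefs, _, _ = _lasso_cv_arrays(
                Xb[:, keep], tb, eb, k, rng,
                n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio,
            )
        except Exception as err:  # noqa: BLE001 - per-resample isolation
            n_failures += 1
            logger.warning("bootstrap resample failed: %s", err)
            continue
        sel = np.zeros(p, dtype=bool)
        sel[np.flatnonzero(keep)] = coefs != 0
        counts += sel
    if n_failures > 0.1 * B:
        raise RuntimeError(
            f"{n_failures}/{B} bootstrap resamples failed; aborting selection"
        )
    return StabilitySelectionResult(
        frequency=pd.Series(counts, index=X.columns, name="frequency"),
        B=B,
        freq_threshold=freq_threshold,
        n_failures=n_failures,
    )


# ---------------------------------------------------------------------------
# final model
# ---------------------------------------------------------------------------


@dataclass
class RiskModel:
    """Selected pairs with their multivariate Cox coefficients beta_i."""

    pair_names: list[str]
    coefficients: pd.Series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = self.coefficients.reindex(self.pair_names)
        if self.coefficients.isna().any():
            raise ValueError("one coefficient required per pair")

    @property
    def pairs(self) -> list[LncPair]:
        return [LncPair.from_name(n) for n in self.pair_names]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pairs": self.pair_names,
            "coefficients": {n: float(self.coefficients[n]) for n in self.pair_names},
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            pair_names=payload["pairs"],
            coefficients=pd.Series(payload["coefficients"]),
            metadata=payload.get("metadata", {}),
        )


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Greedy left-to-right rank filter: drop columns that add no rank."""
    kept: list[str] = []
    arr = np.empty((len(X), 0))
    for col in X.columns:
        cand = np.column_stack([arr, X[col].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand - cand.mean(axis=0)) > np.linalg.matrix_rank(
            arr - arr.mean(axis=0) if arr.size else arr
        ):
            kept.append(col)
            arr = cand
        else:
            logger.warning("dropping collinear feature %s", col)
    return X[kept]


def multivariate_cox_fit(
    selected: Sequence[str],
    pm: PairFeatureMatrix,
    surv: SurvivalData,
    metadata: dict | None = None,
) -> tuple[RiskModel, CoxFitResult]:
    """Joint Cox fit of the selected pair indicators -> final RiskModel."""
    selected = list(selected)
    if not selected:
        raise ValueError("no pairs selected")
    missing = [s for s in selected if s not in pm.pair_names]
    if missing:
        raise KeyError(f"selected pairs missing from matrix: {missing}")
    X = pm.values.loc[selected].T.astype(float)
    X = _drop_collinear(X)
    fit = fit_cox_ph(X, surv)
    model = RiskModel(
        pair_names=list(X.columns),
        coefficients=fit.table["beta"].copy(),
        metadata=metadata or {},
    )
    return model, fit


def compute_risk_scores(model: RiskModel, pm: PairFeatureMatrix) -> pd.Series:
    """RiskScore(sample) = sum_i beta_i * S_i(sample)."""
    missing = [p for p in model.pair_names if p not in pm.pair_names]
    if missing:
        raise KeyError(f"model pairs missing from matrix: {missing}")
    S = pm.values.loc[model.pair_names].to_numpy(dtype=float)
    beta = model.coefficients.to_numpy(dtype=float)
    return pd.Series(beta @ S, index=pm.sample_ids, name="risk_score")
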