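"""Model/Results interface for the pair-signature Cox model.

:class:`PairSignatureCox` is built from a binary pair-feature matrix and
survival data (or straight from a cohort via :meth:`from_cohort`, which runs
the immune-correlation and differential-expression screens and the pair
encoding).  ``fit`` runs the selection funnel — univariate Cox screen,
bootstrap-stabilized CV-LASSO, multivariate Cox — and returns a
:class:`PairSignatureCoxResults` carrying the coefficients, their Wald
uncertainties, stability frequencies and a ``summary()`` table; risk-score
prediction, AIC-cutoff stratification, KM/log-rank and time-dependent ROC
hang off the results object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluate, screen
from .datatypes import GeneExpressionMatrix, SurvivalData
from .evaluate import CutoffResult, KMCurve, LogrankResult, ROCResult
from .pairs import PairFeatureMatrix, encode_pairs, prevalence_filter
from .signature import (
    CoxFitResult,
    RiskModel,
    StabilitySelectionResult,
    bootstrap_stability_select,
    compute_risk_scores,
    multivariate_cox_fit,
    univariate_cox_screen,
)

logger = logging.getLogger(__name__)

DEFAULT_HORIZONS = (365.0, 730.0, 1095.0)


class InsufficientFeaturesError(ValueError):
    """The screening funnel left too few lncRNAs to form any pair."""


class PairSignatureCox:
    """Pair-based prognostic Cox model.

    Parameters
    ----------
    pair_matrix : PairFeatureMatrix
        Binary pair indicators (after any prevalence filtering).
    survival : SurvivalData
        Follow-up and clinical covariates; samples are matched by id.
    screen_alpha : float
        Univariate Wald-p threshold (strict <).
    n_bootstrap, freq_threshold, cv_folds : int
        Stability-selection settings: B resamples, count threshold
        (selection requires frequency strictly greater), CV folds for the
        LASSO penalty.
    """

    def __init__(
        self,
        pair_matrix: PairFeatureMatrix,
        survival: SurvivalData,
        screen_alpha: float = 0.05,
        n_bootstrap: int = 1000,
        freq_threshold: int = 100,
        cv_folds: int = 10,
    ) -> None:
        keep = [s for s in pair_matrix.sample_ids if s in survival.sample_ids]
        if not keep:
            raise ValueError("no overlap between pair matrix and survival samples")
        self.pair_matrix = pair_matrix.subset_samples(keep)
        self.survival = survival.align(keep)
        self.screen_alpha = screen_alpha
        self.n_bootstrap = n_bootstrap
        self.freq_threshold = freq_threshold
        self.cv_folds = cv_folds
        self.screen_info: dict = {}

    # -- constructors ----------------------------------------------------------
    @classmethod
    def from_cohort(
        cls,
        expr: GeneExpressionMatrix,
        survival: SurvivalData,
        immune_gene_ids: Sequence[str],
        r_min: float = 0.4,
        p_max: float = 0.001,
        lfc_threshold: float = 1.0,
        de_alpha: float = 0.05,
        prevalence_low: float = 0.2,
        prevalence_high: float = 0.8,
        corr_method: str = "pearson",
        corr_samples: str = "all",
        **model_kwargs,
    ) -> "PairSignatureCox":
        """Run screens and pair encoding on a full cohort, then build the model.

        The funnel: lncRNAs co-expressed with an immune gene (r > r_min,
        p < p_max) -> tumor/normal DE screen (|log2FC| >= lfc_threshold,
        BH-adjusted p < de_alpha) -> all pairwise 0/1 indicators ->
        prevalence filter.  Raises ``ValueError`` when fewer than two
        DE immune-related lncRNAs survive.
        """
        records = screen.correlate_lncrna_immune(
            expr, immune_gene_ids, method=corr_method, samples=corr_samples
        )
        immune_lnc = screen.select_immune_lncrnas(records, r_min=r_min, p_max=p_max)
        if len(immune_lnc) < 2:
            raise InsufficientFeaturesError(
                "fewer than 2 lncRNAs passed the immune-correlation screen"
            )
        de = screen.differential_expression(
            expr, immune_lnc, lfc_threshold=lfc_threshold, alpha=de_alpha
        )
        de_ids = de.loc[de["passes"], "lncrna_id"].tolist()
        if len(de_ids) < 2:
            raise InsufficientFeaturesError(
                f"need >=2 differentially expressed immune lncRNAs, got {len(de_ids)}"
            )
        tumor_expr = expr.subset_samples(expr.tumor_ids)
        pm = prevalence_filter(
            encode_pairs(tumor_expr, de_ids), prevalence_low, prevalence_high
        )
        model = cls(pm, survival, **model_kwargs)
        model.screen_info = {
            "n_lncrna": int(len(expr.lncrna_ids)),
            "n_immune_lncrna": len(immune_lnc),
            "immune_lncrna_ids": immune_lnc,
            "n_de_irlncrna": len(de_ids),
            "de_irlncrna_ids": de_ids,
            "de_table": de,
            "n_pairs_encoded": len(de_ids) * (len(de_ids) - 1) // 2,
            "n_pairs_after_prevalence": len(pm.pair_names),
        }
        logger.info(
            "screen funnel: %d lncRNAs -> %d immune -> %d DE -> %d pairs kept",
            len(expr.lncrna_ids),
            len(immune_lnc),
            len(de_ids),
            len(pm.pair_names),
        )
        return model

    # -- fitting ---------------------------------------------------------------
    def fit(self, seed: int | None = None) -> "PairSignatureCoxResults":
        """Run the selection funnel and final Cox fit.

        A cohort without any prognostic pair (nothing passes the univariate
        screen, or no frequency exceeds the threshold) yields an *empty*
        results object rather than an error.
        """
        uni = univariate_cox_screen(self.pair_matrix, self.survival, self.screen_alpha)
        stability = None
        model = None
        fit = None
        if len(uni):
            feats = self.pair_matrix.values.loc[uni.index].T.astype(float)
            stability = bootstrap_stability_select(
                feats,
                self.survival,
                B=self.n_bootstrap,
                freq_threshold=self.freq_threshold,
                k=self.cv_folds,
                seed=seed,
            )
            if stability.selected:
                model, fit = multivariate_cox_fit(
                    stability.selected,
                    self.pair_matrix,
                    self.survival,
                    metadata={
                        "seed": seed,
                        "n_bootstrap": self.n_bootstrap,
                        "freq_threshold": self.freq_threshold,
                        "cv_folds": self.cv_folds,
                        "screen_alpha": self.screen_alpha,
                    },
                )
        else:
            logger.info("no pair passed the univariate screen")
        return PairSignatureCoxResults(
            model_spec=self,
            risk_model=model,
            cox_fit=fit,
            univariate=uni,
            stability=stability,
            seed=seed,
        )


@dataclass
class Stratification:
    cutoff: float
    rule: str
    groups: pd.Series
    km_high: KMCurve
    km_low: KMCurve
    logrank: LogrankResult
    aic_by_candidate: pd.Series | None = None


@dataclass
class PairSignatureCoxResults:
    """Fitted pair signature: estimates, uncertainties and evaluation."""

    model_spec: PairSignatureCox
    risk_model: RiskModel | None
    cox_fit: CoxFitResult | None
    univariate: pd.DataFrame
    stability: StabilitySelectionResult | None
    seed: int | None = None
    _scores: pd.Series | None = field(default=None, repr=False)

    # -- estimates -------------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.risk_model is None

    @property
    def params(self) -> pd.Series:
        if self.is_empty:
            return pd.Series(dtype=float, name="beta")
        return self.cox_fit.table["beta"]

    @property
    def bse(self) -> pd.Series:
        return pd.Series(dtype=float) if self.is_empty else self.cox_fit.table["se"]

    @property
    def hazard_ratios(self) -> pd.Series:
        return pd.Series(dtype=float) if self.is_empty else self.cox_fit.table["HR"]

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(dtype=float) if self.is_empty else self.cox_fit.table["p"]

    def conf_int(self) -> pd.DataFrame:
        if self.is_empty:
            return pd.DataFrame(columns=["ci_low", "ci_high"])
        return self.cox_fit.table[["ci_low", "ci_high"]]

    # -- prediction ------------------------------------------------------------
    @property
    def risk_scores(self) -> pd.Series:
        """Risk scores of the training samples."""
        if self._scores is None:
            self._scores = self.predict_risk(self.model_spec.pair_matrix)
        return self._scores

    def predict_risk(self, pair_matrix: PairFeatureMatrix) -> pd.Series:
        if self.is_empty:
            return pd.Series(
                0.0, index=pair_matrix.sample_ids, name="risk_score"
            )
        return compute_risk_scores(self.risk_model, pair_matrix)

    # -- evaluation ------------------------------------------------------------
    def roc(self, horizons: Sequence[float] = DEFAULT_HORIZONS) -> dict[float, ROCResult]:
        return {
            float(h): evaluate.td_roc_auc(self.risk_scores, self.model_spec.survival, h)
            for h in horizons
        }

    def stratify(
        self,
        rule: str = "aic",
        min_group_frac: float = 0.10,
        youden_horizon: float = 365.0,
    ) -> Stratification:
        """Dichotomize at the AIC-optimal cutoff (default) or, with
        ``rule="youden"``, at the 1-year-ROC Youden point."""
        surv = self.model_spec.survival
        scores = self.risk_scores
        aic_table = None
        if rule == "aic":
            res: CutoffResult = evaluate.aic_optimal_cutoff(
                scores, surv, min_group_frac=min_group_frac
            )
            cutoff, groups, aic_table = res.cutoff, res.groups, res.aic_by_candidate
        elif rule == "youden":
            roc = evaluate.td_roc_auc(scores, surv, youden_horizon)
            j = roc.sensitivity + roc.specificity - 1.0
            cutoff = float(roc.thresholds[int(np.argmax(j))])
            groups = evaluate.assign_risk_groups(scores, cutoff)
        else:
            raise ValueError(f"unknown cutoff rule {rule!r}")
        km_high = evaluate.km_estimate(surv.subset(groups.index[groups == "high"]))
        km_low = evaluate.km_estimate(surv.subset(groups.index[groups == "low"]))
        lr = evaluate.logrank_test(surv, groups)
        return Stratification(
            cutoff=cutoff,
            rule=rule,
            groups=groups,
            km_high=km_high,
            km_low=km_low,
            logrank=lr,
            aic_by_candidate=aic_table,
        )

    # -- reporting -------------------------------------------------------------
    def summary(self) -> str:
        surv = self.model_spec.survival
        lines = [
            "Pair-signature Cox model",
            "=" * 64,
            f"samples: {len(surv.sample_ids)}    events: {surv.n_events}",
            f"pairs screened: {len(self.model_spec.pair_matrix.pair_names)}"
            f"    univariate survivors: {len(self.univariate)}",
        ]
        if self.stability is not None:
            lines.append(
                f"bootstraps: {self.stability.B}    frequency threshold: "
                f">{self.stability.freq_threshold}    selected: "
                f"{len(self.stability.selected)}"
            )
        if self.is_empty:
            lines.append("\n(no prognostic pairs selected — empty signature)")
            return "\n".join(lines)
        tab = self.cox_fit.table.copy()
        tab["freq"] = self.stability.frequency.reindex(tab.index)
        lines.append("")
        lines.append(
            tab[["beta", "se", "HR", "ci_low", "ci_high", "p", "freq"]].to_string(
                float_format=lambda v: f"{v:.4f}"
            )
        )
        lines.append("")
        lines.append(f"log partial likelihood: {self.cox_fit.log_likelihood:.4f}")
        return "\n".join(lines)

    # -- plotting --------------------------------------------------------------
    def plot_km(self, strat: Stratification | None = None, ax=None):
        import matplotlib.pyplot as plt

        strat = strat or self.stratify()
        if ax is None:
            _, ax = plt.subplots()
        for km, label in ((strat.km_high, "high risk"), (strat.km_low, "low risk")):
            ax.step(km.timeline, km.survival, where="post", label=label)
        ax.set_xlabel("time (days)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        ax.legend()
        ax.set_title(f"log-rank p = {strat.logrank.p:.3g}")
        return ax

    def plot_roc(self, horizons: Sequence[float] = DEFAULT_HORIZONS, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for h, roc in self.roc(horizons).items():
            ax.plot(
                1 - roc.specificity,
                roc.sensitivity,
                label=f"{h / 365:.0f} y (AUC = {roc.auc:.3f})",
            )
        ax.plot([0, 1], [0, 1], ls="--", c="grey")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax
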