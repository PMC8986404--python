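"""End-to-end pipeline runner.

``run_pipeline`` chains screen -> DE -> pair encoding -> prevalence filter
-> univariate Cox -> bootstrap-stabilized LASSO -> multivariate Cox -> risk
scores -> time-dependent ROC -> AIC cutoff -> KM/log-rank -> clinical
association and independence analyses -> immune landscape, writing every
intermediate artifact plus a manifest into the output directory.  A cohort
with no prognostic signal ends gracefully after the selection stage with an
empty signature recorded in the manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, evaluate, immune
from .io import PipelineConfig, read_clinical, read_expression, read_gene_list
from .model import InsufficientFeaturesError, PairSignatureCox

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", **kw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the in-memory result bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    bundle: dict = {"config": config}
    stage = "read-inputs"
    try:
        clinical = read_clinical(config.clinical)
        expr = read_expression(
            config.expression,
            config.gene_kinds,
            tumor_samples=list(clinical.sample_ids),
        )
        immune_genes = [
            g for g in read_gene_list(config.immune_genes) if g in set(expr.mrna_ids)
        ]

        stage = "screen-and-pairs"
        try:
            spec = PairSignatureCox.from_cohort(
                expr,
                clinical,
                immune_genes,
                r_min=config.r_min,
                p_max=config.p_max,
                lfc_threshold=config.lfc_threshold,
                de_alpha=config.de_alpha,
                prevalence_low=config.prevalence_low,
                prevalence_high=config.prevalence_high,
                corr_method=config.corr_method,
                corr_samples=config.corr_samples,
                screen_alpha=config.screen_alpha,
                n_bootstrap=config.n_bootstrap,
                freq_threshold=config.freq_threshold,
                cv_folds=config.cv_folds,
            )
        except InsufficientFeaturesError as err:
            logger.info("screen funnel empty (%s); reporting empty signature", err)
            _finish(outdir, config, {"empty_signature": True, "reason": str(err)})
            bundle["results"] = None
            return bundle
        info = spec.screen_info
        (outdir / "immune_lncrnas.txt").write_text(
            "".join(f"{g}\n" for g in info["immune_lncrna_ids"])
        )
        _write_tsv(info["de_table"], outdir / "de_results.tsv", index=False)
        _write_tsv(spec.pair_matrix.values, outdir / "pair_matrix.tsv")
        _write_tsv(
            spec.pair_matrix.prevalence.rename("prevalence").to_frame(),
            outdir / "pair_prevalence.tsv",
        )

        stage = "signature-selection"
        results = spec.fit(seed=config.seed)
        bundle["results"] = results
        _write_tsv(results.univariate, outdir / "univariate_cox.tsv")
        if results.stability is not None:
            _write_tsv(
                results.stability.frequency.to_frame(), outdir / "stability_frequency.tsv"
            )
        funnel = {
            **{k: v for k, v in info.items() if isinstance(v, (int, float))},
            "n_univariate_survivors": int(len(results.univariate)),
            "n_selected": 0 if results.is_empty else len(results.risk_model.pair_names),
            "empty_signature": results.is_empty,
        }
        if results.is_empty:
            logger.info("empty signature; evaluation stages skipped")
            _finish(outdir, config, funnel)
            return bundle

        results.risk_model.to_json(outdir / "risk_model.json")
        _write_tsv(results.cox_fit.table, outdir / "multivariate_cox.tsv")
        scores = results.risk_scores
        _write_tsv(scores.to_frame(), outdir / "risk_scores.tsv")

        stage = "roc"
        aucs = {}
        horizons = [
            h for h in config.roc_horizons if h < float(spec.survival.time.max())
        ]
        for h, roc in results.roc(horizons).items():
            aucs[h] = roc.auc
            _write_tsv(
                pd.DataFrame(
                    {
                        "threshold": roc.thresholds,
                        "sensitivity": roc.sensitivity,
                        "specificity": roc.specificity,
                    }
                ),
                outdir / f"roc_{int(h)}d.tsv",
                index=False,
            )
        (outdir / "auc.json").write_text(
            json.dumps({f"{int(h)}d": v for h, v in aucs.items()}, indent=2) + "\n"
        )
        bundle["aucs"] = aucs

        stage = "stratification"
        strat = results.stratify(
            rule=config.cutoff_rule, min_group_frac=config.min_group_frac
        )
        bundle["stratification"] = strat
        _write_tsv(strat.groups.to_frame(), outdir / "risk_groups.tsv")
        for km, name in ((strat.km_high, "high"), (strat.km_low, "low")):
            _write_tsv(
                pd.DataFrame(
                    {
                        "time": km.timeline,
                        "survival": km.survival,
                        "at_risk": km.at_risk,
                    }
                ),
                outdir / f"km_{name}.tsv",
                index=False,
            )
        (outdir / "cutoff.json").write_text(
            json.dumps(
                {
                    "cutoff": strat.cutoff,
                    "rule": strat.rule,
                    "logrank_statistic": strat.logrank.statistic,
                    "logrank_p": strat.logrank.p,
                    "n_high": int((strat.groups == "high").sum()),
                    "n_low": int((strat.groups == "low").sum()),
                },
                indent=2,
            )
            + "\n"
        )

        stage = "clinical-association"
        clin = spec.survival.table.copy()
        # dichotomize age for the rank tests; continuous age stays in the Cox fits
        clin["age"] = np.where(clin["age"] > 65, ">65", "<=65")
        usable = [
            c
            for c in ("age", "gender", "stage", "T", "N", "M")
            if clin[c].dropna().nunique() > 1
        ]
        assoc = evaluate.clinical_association_tests(
            scores, strat.groups, clin, covariates=usable
        )
        _write_tsv(assoc, outdir / "clinical_association.tsv", index=False)
        uni, multi = evaluate.independent_prognostic_analysis(
            scores, spec.survival.table, spec.survival
        )
        _write_tsv(uni, outdir / "independence_univariate.tsv")
        _write_tsv(multi, outdir / "independence_multivariate.tsv")
        bundle["independence"] = (uni, multi)

        if config.gene_sets:
            stage = "immune-landscape"
            sets = immune.read_gmt(config.gene_sets)
            tumor_expr = expr.subset_samples(spec.survival.sample_ids)
            sc = immune.ssgsea_scores(tumor_expr, sets, alpha=config.ssgsea_alpha)
            _write_tsv(sc, outdir / "ssgsea_scores.tsv")
            comp = immune.compare_groups(sc, strat.groups)
            _write_tsv(comp, outdir / "immune_group_comparison.tsv")
            rho = immune.spearman_with_risk(sc, scores)
            _write_tsv(rho, outdir / "immune_risk_spearman.tsv")
            strat_surv, skipped = immune.score_stratified_survival(sc, spec.survival)
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "signature": r.signature,
                            "logrank_statistic": r.logrank.statistic,
                            "logrank_p": r.logrank.p,
                        }
                        for r in strat_surv
                    ]
                ),
                outdir / "immune_stratified_survival.tsv",
                index=False,
            )
            chk = immune.checkpoint_expression_compare(tumor_expr, strat.groups)
            _write_tsv(chk, outdir / "checkpoint_comparison.tsv")
            bundle["immune"] = {
                "scores": sc,
                "comparison": comp,
                "spearman": rho,
                "stratified": strat_surv,
                "skipped": skipped,
            }

        _finish(outdir, config, funnel)
        return bundle
    except StageError:
        raise
    except Exception as err:
        logger.error("stage %s failed: %s", stage, err)
        raise StageError(stage, err) from err


def _finish(outdir: Path, config: PipelineConfig, funnel: dict) -> None:
    manifest = {
        "package": "lncpair",
        "version": __version__,
        "seed": config.seed,
        "funnel": funnel,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
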