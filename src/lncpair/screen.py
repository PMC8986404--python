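"""Immune-related lncRNA identification and differential-expression screen.

Stage one of the pipeline: lncRNAs are called immune-related when they
co-express with at least one gene from an immune gene list (r > 0.4,
p < 0.001 by default), and the immune-related set is then screened for
tumor-vs-normal differential expression (|log2FC| >= 1 and BH-adjusted
p < 0.05 by default).  All statistics are computed on log2(x+1) values.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneExpressionMatrix

logger = logging.getLogger(__name__)


def _corr_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    # two-sided t test on the correlation coefficient, n-2 df
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def correlate_lncrna_immune(
    expr: GeneExpressionMatrix,
    immune_gene_ids: Sequence[str],
    method: str = "pearson",
    samples: str = "all",
) -> pd.DataFrame:
    """Correlate every lncRNA with every immune gene on log2(x+1) scale.

    Parameters
    ----------
    expr : GeneExpressionMatrix
    immune_gene_ids : sequence of str
        Must be a subset of the matrix's mRNA ids.
    method : {"pearson", "spearman"}
    samples : {"all", "tumor"}
        Which samples enter the correlation.

    Returns
    -------
    DataFrame with columns ``lncrna_id, immune_gene_id, r, p`` — one row per
    (lncRNA, immune gene) combination.  Genes with zero variance are skipped
    with a logged warning and yield no rows.
    """
    immune_ids = list(dict.fromkeys(immune_gene_ids))
    if not immune_ids:
        raise ValueError("immune gene list is empty")
    missing = set(immune_ids) - set(expr.mrna_ids)
    if missing:
        raise KeyError(f"immune genes not among mRNA ids: {sorted(missing)[:5]}")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    cols = expr.sample_ids if samples == "all" else expr.tumor_ids
    if len(cols) < 3:
        raise ValueError("need at least 3 samples for correlation")

    log = np.log2(expr.values.loc[:, cols] + 1.0)
    lnc = log.loc[expr.lncrna_ids]
    imm = log.loc[immune_ids]
    if method == "spearman":
        lnc = lnc.rank(axis=1)
        imm = imm.rank(axis=1)

    def _drop_constant(df: pd.DataFrame, label: str) -> pd.DataFrame:
        sd = df.std(axis=1, ddof=1)
        const = sd.index[sd == 0]
        if len(const):
            logger.warning("skipping %d constant %s gene(s)", len(const), label)
        return df.loc[sd > 0]

    lnc = _drop_constant(lnc, "lncRNA")
    imm = _drop_constant(imm, "immune")
    if lnc.empty or imm.empty:
        return pd.DataFrame(columns=["lncrna_id", "immune_gene_id", "r", "p"])

    n = len(cols)
    zl = (lnc - lnc.mean(axis=1).to_numpy()[:, None]).to_numpy()
    zl /= np.linalg.norm(zl, axis=1, keepdims=True)
    zi = (imm - imm.mean(axis=1).to_numpy()[:, None]).to_numpy()
    zi /= np.linalg.norm(zi, axis=1, keepdims=True)
    r = zl @ zi.T
    p = _corr_pvalue(r, n)

    li, ii = np.meshgrid(np.arange(len(lnc)), np.arange(len(imm)), indexing="ij")
    return pd.DataFrame(
        {
            "lncrna_id": lnc.index.to_numpy()[li.ravel()],
            "immune_gene_id": imm.index.to_numpy()[ii.ravel()],
            "r": r.ravel(),
            "p": p.ravel(),
        }
    )


def select_immune_lncrnas(
    records: pd.DataFrame, r_min: float = 0.4, p_max: float = 0.001
) -> list[str]:
    """lncRNAs with at least one correlation r > r_min and p < p_max (strict)."""
    if records.empty:
        return []
    hit = records[(records["r"] > r_min) & (records["p"] < p_max)]
    return sorted(hit["lncrna_id"].unique())


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1, monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch(tumor: np.ndarray, normal: np.ndarray) -> float:
    return stats.ttest_ind(tumor, normal, axis=1, equal_var=False).pvalue


def differential_expression(
    expr: GeneExpressionMatrix,
    lnc_ids: Sequence[str],
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    test: str | Callable = "welch",
) -> pd.DataFrame:
    """Tumor-vs-normal differential expression on log2(x+1) values.

    logFC is the difference of group means of log2(x+1); p-values come from a
    per-gene two-group test (Welch's t by default, or any callable
    ``test(tumor_matrix, normal_matrix) -> p_vector``), BH-adjusted across
    the tested lncRNAs.  A gene passes when ``|logFC| >= lfc_threshold`` and
    ``p_adj < alpha``.

    Returns a DataFrame with columns
    ``lncrna_id, logFC, p_raw, p_adj, passes`` in the input gene order.
    """
    ids = list(dict.fromkeys(lnc_ids))
    if not ids:
        raise ValueError("no lncRNA ids supplied")
    missing = [i for i in ids if i not in expr.gene_ids]
    if missing:
        raise KeyError(f"ids missing from matrix: {missing[:5]}")
    tumor_ids, normal_ids = expr.tumor_ids, expr.normal_ids
    if len(tumor_ids) < 2 or len(normal_ids) < 2:
        raise ValueError("differential expression requires >=2 samples per group")

    log = np.log2(expr.values.loc[ids] + 1.0)
    tumor = log.loc[:, tumor_ids].to_numpy()
    normal = log.loc[:, normal_ids].to_numpy()
    logfc = tumor.mean(axis=1) - normal.mean(axis=1)

    fn = _welch if test == "welch" else test
    if not callable(fn):
        raise ValueError(f"unknown test {test!r}")
    p_raw = np.asarray(fn(tumor, normal), dtype=float)
    # a gene constant and identical in both groups has an undefined statistic;
    # it cannot pass, so give it p = 1
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    p_adj = benjamini_hochberg(p_raw)
    passes = (np.abs(logfc) >= lfc_threshold) & (p_adj < alpha)
    return pd.DataFrame(
        {
            "lncrna_id": ids,
            "logFC": logfc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "passes": passes,
        }
    )
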