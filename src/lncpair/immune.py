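"""Single-sample gene-set enrichment and immune-landscape comparisons.

The ssGSEA score of a gene set in one sample is computed from that sample's
expression ranks alone: genes are ranked (average ranks for ties, highest
expression = highest rank), the ranked list is walked from the top, and the
enrichment score is the sum over positions of the difference between the
weighted in-set cumulative distribution (weights = rank**alpha, normalized
within the set) and the uniform out-of-set cumulative distribution.  Scores
are then min-max normalized per signature across samples so group contrasts
are scale-free.  Because only within-sample ranks enter, the score is
invariant to strictly increasing per-sample transforms of expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneExpressionMatrix, SurvivalData
from .evaluate import HIGH, LOW, KMCurve, LogrankResult, km_estimate, logrank_test

logger = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, genes = parts[0], [g for g in parts[2:] if g]
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        if not genes:
            raise ValueError(f"empty gene set {name!r}")
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    lines = [f"{name}\tna\t" + "\t".join(genes) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def _ssgsea_one_sample(
    ranks: np.ndarray, in_set: np.ndarray, alpha: float
) -> float:
    """Running-sum enrichment for one sample.

    ranks: average expression ranks (1..N, highest expression = N);
    in_set: boolean membership mask aligned with ranks.
    """
    order = np.argsort(-ranks, kind="stable")  # walk from highest expression
    r, m = ranks[order], in_set[order]
    w = np.where(m, r.astype(float) ** alpha, 0.0)
    cdf_in = np.cumsum(w) / w.sum()
    out = (~m).astype(float)
    cdf_out = np.cumsum(out) / out.sum()
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_scores(
    expr: GeneExpressionMatrix | pd.DataFrame,
    sets: dict[str, list[str]],
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """ssGSEA score matrix, signatures x samples.

    Each set is intersected with the measured genes and must then hold at
    least 2 genes and be a proper subset of the gene universe.  With
    ``normalize`` each signature row is min-max scaled to [0, 1] across
    samples (left unscaled if constant).
    """
    table = expr.values if isinstance(expr, GeneExpressionMatrix) else expr
    if not sets:
        raise ValueError("no gene sets supplied")
    genes = table.index
    masks = {}
    for name, members in sets.items():
        mask = genes.isin(set(members))
        k = int(mask.sum())
        if k < 2:
            raise ValueError(f"gene set {name!r} has <2 measured genes")
        if k == len(genes):
            raise ValueError(f"gene set {name!r} covers the whole gene universe")
        masks[name] = mask

    ranks = table.rank(axis=0, method="average").to_numpy()
    out = np.empty((len(masks), table.shape[1]))
    for i, (name, mask) in enumerate(masks.items()):
        for j in range(table.shape[1]):
            out[i, j] = _ssgsea_one_sample(ranks[:, j], mask, alpha)
    scores = pd.DataFrame(out, index=list(masks), columns=table.columns)
    if normalize:
        lo = scores.min(axis=1)
        span = scores.max(axis=1) - lo
        keep = span > 0
        scores.loc[keep] = scores.loc[keep].sub(lo[keep], axis=0).div(
            span[keep], axis=0
        )
    return scores


def compare_groups(scores: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-signature Wilcoxon rank-sum between high- and low-risk samples."""
    g = groups.reindex(scores.columns)
    hi, lo = g == HIGH, g == LOW
    if hi.sum() < 2 or lo.sum() < 2:
        raise ValueError("each risk group needs at least 2 samples")
    rows = []
    for name, row in scores.iterrows():
        a, b = row[hi.to_numpy()], row[lo.to_numpy()]
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "signature": name,
                "statistic": float(stat),
                "p": float(p),
                "median_high": float(np.median(a)),
                "median_low": float(np.median(b)),
                "significant": bool(p < 0.05),
            }
        )
    return pd.DataFrame(rows).set_index("signature")


def spearman_with_risk(scores: pd.DataFrame, risk_scores: pd.Series) -> pd.DataFrame:
    """Spearman correlation of each signature score with the risk score."""
    rs = risk_scores.reindex(scores.columns)
    if rs.isna().any():
        raise ValueError("risk scores missing for some samples")
    if len(rs) < 4:
        raise ValueError("need at least 4 paired samples")
    rows = []
    for name, row in scores.iterrows():
        if np.ptp(row.to_numpy()) == 0:
            logger.warning("signature %s constant; skipped", name)
            continue
        rho, p = stats.spearmanr(row.to_numpy(), rs.to_numpy())
        rows.append({"signature": name, "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows).set_index("signature") if rows else pd.DataFrame(
        columns=["rho", "p"]
    )


@dataclass
class StratifiedSurvival:
    signature: str
    km_high: KMCurve
    km_low: KMCurve
    logrank: LogrankResult


def score_stratified_survival(
    scores: pd.DataFrame, surv: SurvivalData
) -> tuple[list[StratifiedSurvival], list[str]]:
    """Median-split each signature (ties to the low stratum) and compare
    survival of the strata; degenerate signatures are skipped and reported.

    Returns (results, skipped signature names).
    """
    results, skipped = [], []
    for name, row in scores.iterrows():
        vals = row.reindex(surv.sample_ids)
        med = float(np.median(vals))
        strata = pd.Series(
            np.where(vals > med, HIGH, LOW), index=surv.sample_ids
        )
        if len(strata.unique()) < 2:
            logger.warning("signature %s: degenerate median split; skipped", name)
            skipped.append(name)
            continue
        results.append(
            StratifiedSurvival(
                signature=name,
                km_high=km_estimate(surv.subset(strata.index[strata == HIGH])),
                km_low=km_estimate(surv.subset(strata.index[strata == LOW])),
                logrank=logrank_test(surv, strata),
            )
        )
    return results, skipped


CHECKPOINT_GENES = ("PDCD1", "CTLA4", "LAG3")


def checkpoint_expression_compare(
    expr: GeneExpressionMatrix,
    groups: pd.Series,
    gene_ids: tuple[str, ...] = CHECKPOINT_GENES,
) -> pd.DataFrame:
    """Rank-sum comparison of log2(x+1) checkpoint-gene expression between
    risk groups; genes absent from the matrix are reported, not fatal."""
    g = groups.dropna()
    log = np.log2(expr.values.loc[:, g.index] + 1.0)
    rows = []
    for gene in gene_ids:
        if gene not in expr.gene_ids:
            rows.append(
                {"gene": gene, "status": "missing", "statistic": np.nan, "p": np.nan}
            )
            continue
        a = log.loc[gene, (g == HIGH).to_numpy()]
        b = log.loc[gene, (g == LOW).to_numpy()]
        if np.ptp(log.loc[gene]) == 0:
            rows.append(
                {"gene": gene, "status": "constant", "statistic": np.nan, "p": 1.0}
            )
            continue
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {"gene": gene, "status": "tested", "statistic": float(stat), "p": float(p)}
        )
    return pd.DataFrame(rows).set_index("gene")
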