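"""Synthetic TCGA-like cohorts with known ground truth.

The generator emulates the inputs of the pipeline at desk scale: a
tumor/normal bulk expression matrix on an FPKM-like scale in which

* a known subset of lncRNAs is generated as a noisy linear function of one
  immune mRNA each, so their log-scale Pearson correlation concentrates near
  a target (``immune_corr_target``);
* a known subset of lncRNAs carries a tumor-vs-normal mean shift of
  ``de_log2fc`` on the log2 scale;
* survival times for tumor samples are exponential with hazard
  ``baseline_hazard * exp(sum_k beta_k * S_k)``, where ``S_k`` are binary
  pair indicators computed exactly as :func:`lncpair.pairs.encode_pairs`
  computes them, so downstream model fits have a recoverable answer;
* independent exponential censoring is calibrated numerically to a target
  censoring fraction, and ordinal stage is mildly tilted by the true linear
  predictor so independence analyses face realistic confounding.

A single integer seed feeds a hierarchy of generator streams (one per
component), so enlarging the gene panel does not perturb the survival draws.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import NORMAL, TUMOR, GeneExpressionMatrix, SurvivalData
from .pairs import LncPair, encode_pairs

logger = logging.getLogger(__name__)

_STREAMS = ("mrna", "lncrna", "survival", "censoring", "clinical")


def lnc_id(i: int) -> str:
    return f"LNC{i + 1:04d}"


def imm_id(i: int) -> str:
    return f"IMM{i + 1:04d}"


@dataclass
class CohortConfig:
    """Ground-truth recipe for one synthetic cohort.

    ``true_pairs`` are (lnc_a, lnc_b, beta) triples; beta is the log-hazard
    contribution of the pair indicator.  Pairs given in non-canonical
    orientation (a > b) are canonicalized with the sign of beta flipped,
    since the reversed indicator is the complement of the canonical one.
    """

    n_tumor: int = 300
    n_normal: int = 40
    n_lncrna: int = 80
    n_immune_mrna: int = 60
    n_true_immune_lnc: int = 40
    n_true_de_lnc: int = 30
    true_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    baseline_hazard: float = 5e-4  # events per day
    censoring_rate: float = 0.3
    de_log2fc: float = 2.0
    immune_corr_target: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_tumor",
            "n_normal",
            "n_lncrna",
            "n_immune_mrna",
            "n_true_immune_lnc",
            "n_true_de_lnc",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_true_immune_lnc > self.n_lncrna:
            raise ValueError("n_true_immune_lnc exceeds n_lncrna")
        if self.n_true_de_lnc > self.n_lncrna:
            raise ValueError("n_true_de_lnc exceeds n_lncrna")
        if self.n_true_immune_lnc > self.n_immune_mrna:
            raise ValueError("need one immune mRNA per true immune lncRNA")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not 0 < self.immune_corr_target <= 1:
            raise ValueError("immune_corr_target must lie in (0, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")

        valid = {lnc_id(i) for i in range(self.n_lncrna)}
        canon: list[tuple[str, str, float]] = []
        seen: set[str] = set()
        for a, b, beta in self.true_pairs:
            if a not in valid or b not in valid:
                raise ValueError(f"true pair ({a}, {b}) references unknown lncRNA")
            pair = LncPair.canonical(a, b)
            if pair.name in seen:
                raise ValueError(f"true pair repeated: {pair.name}")
            seen.add(pair.name)
            canon.append((pair.id_a, pair.id_b, beta if (a, b) == tuple(pair) else -beta))
        self.true_pairs = canon

    # -- derived ground truth --------------------------------------------------
    @property
    def true_immune_lnc_ids(self) -> list[str]:
        return [lnc_id(i) for i in range(self.n_true_immune_lnc)]

    @property
    def true_de_lnc_ids(self) -> list[str]:
        return [lnc_id(i) for i in range(self.n_true_de_lnc)]

    def _streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {n: np.random.default_rng(s) for n, s in zip(_STREAMS, children)}


@dataclass
class SyntheticCohort:
    expression: GeneExpressionMatrix
    clinical: SurvivalData
    config: CohortConfig

    @property
    def truth(self) -> dict:
        c = self.config
        return {
            "true_immune_lnc_ids": c.true_immune_lnc_ids,
            "true_de_lnc_ids": c.true_de_lnc_ids,
            "true_pairs": [list(p) for p in c.true_pairs],
        }


def generate_expression(config: CohortConfig) -> GeneExpressionMatrix:
    """Draw the tumor+normal expression matrix for a config.

    Log2 expression is normal per gene (means U(1,6) for lncRNAs, U(3,8) for
    mRNAs; sds U(0.8,1.5)) and exponentiated to an FPKM-like scale.  True
    immune lncRNAs mix the standardized log2 value of their assigned immune
    mRNA with independent noise at weight r = ``immune_corr_target``; both
    members of every true pair share a mean so the pair indicator stays
    informative (prevalence near 0.5).
    """
    streams = config._streams()
    n_s = config.n_tumor + config.n_normal
    samples = [f"TUM{i + 1:04d}" for i in range(config.n_tumor)] + [
        f"NOR{i + 1:04d}" for i in range(config.n_normal)
    ]
    groups = pd.Series(
        [TUMOR] * config.n_tumor + [NORMAL] * config.n_normal, index=samples
    )

    rng_m = streams["mrna"]
    mrna_ids = [imm_id(i) for i in range(config.n_immune_mrna)]
    mu_m = rng_m.uniform(3, 8, config.n_immune_mrna)
    sd_m = rng_m.uniform(0.8, 1.5, config.n_immune_mrna)
    log_m = mu_m[:, None] + sd_m[:, None] * rng_m.standard_normal(
        (config.n_immune_mrna, n_s)
    )

    rng_l = streams["lncrna"]
    lnc_ids = [lnc_id(i) for i in range(config.n_lncrna)]
    mu_l = rng_l.uniform(1, 6, config.n_lncrna)
    sd_l = rng_l.uniform(0.8, 1.5, config.n_lncrna)
    # pair members share the first member's location so P(A > B) stays
    # well inside the prevalence window
    idx = {g: i for i, g in enumerate(lnc_ids)}
    for a, b, _ in config.true_pairs:
        mu_l[idx[b]] = mu_l[idx[a]]
        sd_l[idx[b]] = sd_l[idx[a]]

    noise = rng_l.standard_normal((config.n_lncrna, n_s))
    z_lnc = noise.copy()
    r = config.immune_corr_target
    z_m = (log_m - log_m.mean(axis=1, keepdims=True)) / log_m.std(axis=1, keepdims=True)
    for i in range(config.n_true_immune_lnc):
        z_lnc[i] = r * z_m[i] + np.sqrt(1.0 - r**2) * noise[i]
    log_l = mu_l[:, None] + sd_l[:, None] * z_lnc
    tumor_mask = (groups == TUMOR).to_numpy()
    log_l[: config.n_true_de_lnc, tumor_mask] += config.de_log2fc

    values = pd.DataFrame(
        np.exp2(np.vstack([log_l, log_m])),
        index=pd.Index(lnc_ids + mrna_ids, name="gene_id"),
        columns=samples,
    )
    kinds = pd.Series(
        ["lncRNA"] * config.n_lncrna + ["mRNA"] * config.n_immune_mrna,
        index=values.index,
    )
    return GeneExpressionMatrix(values, kinds, groups)


def _solve_censoring_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean P(C < T) = target."""

    def frac(c: float) -> float:
        return float(np.mean(c / (c + hazards))) - target

    hi = hazards.max() * target / (1 - target) * 10 + 1.0
    while frac(hi) < 0:
        hi *= 10
    return brentq(frac, 1e-12, hi, xtol=1e-12)


def generate_survival(
    expr: GeneExpressionMatrix, config: CohortConfig
) -> SurvivalData:
    """Draw survival and clinical covariates for the tumor samples.

    Event times are exponential with per-sample hazard
    ``baseline_hazard * exp(linear predictor)`` built from the true pair
    indicators; censoring is independent exponential with its rate solved so
    the expected censored fraction equals ``censoring_rate``.  Times are
    rounded up to whole days, producing the ties a day-resolution registry
    would show.
    """
    streams = config._streams()
    tumor_ids = list(expr.tumor_ids)
    if not tumor_ids:
        raise ValueError("no tumor samples in expression matrix")
    n = len(tumor_ids)

    lp = np.zeros(n)
    if config.true_pairs:
        ids = sorted({g for a, b, _ in config.true_pairs for g in (a, b)})
        pm = encode_pairs(expr, ids).subset_samples(tumor_ids)
        for a, b, beta in config.true_pairs:
            lp += beta * pm.values.loc[LncPair(a, b).name].to_numpy()

    hazards = config.baseline_hazard * np.exp(lp)
    rng_s = streams["survival"]
    t_event = rng_s.exponential(1.0 / hazards)
    if config.censoring_rate > 0:
        c_rate = _solve_censoring_rate(hazards, config.censoring_rate)
        t_cens = streams["censoring"].exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.ceil(np.minimum(t_event, t_cens))
    event = (t_event <= t_cens).astype(int)

    rng_c = streams["clinical"]
    age = np.clip(np.round(rng_c.normal(66, 11, n)), 30, 90).astype(int)
    gender = np.where(rng_c.random(n) < 0.5, "MALE", "FEMALE")
    # ordered-logit style stage: latent = scaled lp + logistic noise
    z = (lp - lp.mean()) / (lp.std() if lp.std() > 0 else 1.0)
    latent = 0.5 * z + rng_c.logistic(size=n)
    cuts = np.quantile(latent, [0.2, 0.55, 0.85])
    stage = 1 + np.searchsorted(cuts, latent)
    t_stage = np.clip(stage + rng_c.integers(-1, 2, n), 1, 4)
    n_stage = np.clip(stage - 2 + rng_c.integers(0, 2, n), 0, 2)
    m_stage = (stage == 4).astype(int)

    table = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age": age,
            "gender": gender,
            "stage": stage,
            "T": t_stage,
            "N": n_stage,
            "M": m_stage,
        },
        index=pd.Index(tumor_ids, name="sample_id"),
    )
    return SurvivalData(table)


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Expression + survival + truth for one config (deterministic in seed)."""
    expr = generate_expression(config)
    clinical = generate_survival(expr, config)
    return SyntheticCohort(expr, clinical, config)


def write_fixture(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as the plain-text fixture set read by :mod:`lncpair.io`.

    Emits ``expression.tsv`` (first column ``gene_id``), ``gene_kinds.tsv``,
    ``clinical.tsv``, ``immune_genes.txt`` (one id per line) and
    ``truth.json``.  The directory must already exist; nothing is written
    otherwise.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    paths = {
        "expression": directory / "expression.tsv",
        "gene_kinds": directory / "gene_kinds.tsv",
        "clinical": directory / "clinical.tsv",
        "immune_genes": directory / "immune_genes.txt",
        "truth": directory / "truth.json",
    }
    expr = cohort.expression
    expr.values.rename_axis("gene_id").to_csv(paths["expression"], sep="\t")
    expr.gene_kind.rename("kind").rename_axis("gene_id").to_csv(
        paths["gene_kinds"], sep="\t"
    )
    cohort.clinical.table.rename_axis("sample_id").to_csv(paths["clinical"], sep="\t")
    paths["immune_genes"].write_text(
        "".join(f"{g}\n" for g in expr.mrna_ids)
    )
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2) + "\n")
    return paths
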