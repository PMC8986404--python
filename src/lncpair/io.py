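"""Readers, writers and the pipeline configuration.

File dialects (all plain text):

* expression TSV — first column ``gene_id``, remaining columns sample ids,
  cells non-negative numbers;
* gene-kind TSV — columns ``gene_id, kind`` with kind in {lncRNA, mRNA};
* clinical TSV — columns ``sample_id, time, event, age, gender, stage, T, N, M``;
* gene list — one id per line;
* gene sets — standard GMT;
* model / manifest / truth — JSON.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .datatypes import CLINICAL_COLUMNS, NORMAL, TUMOR, GeneExpressionMatrix, SurvivalData

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Malformed input file or configuration."""


def read_gene_list(path: str | Path) -> list[str]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return [ln for ln in lines if ln]


def read_expression(
    path: str | Path,
    gene_kinds: str | Path | pd.Series,
    tumor_samples: list[str] | None = None,
) -> GeneExpressionMatrix:
    """Read an expression TSV into a validated matrix.

    ``gene_kinds`` is a kind TSV path or a Series mapping gene id -> kind;
    ``tumor_samples`` lists the tumor sample ids (typically the clinical
    table's index) — everything else is labelled normal.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as err:
        raise ValidationError(f"empty expression file: {path}") from err
    if df.empty or df.index.name != "gene_id":
        raise ValidationError(
            f"expression file must start with a 'gene_id' column: {path}"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene id(s): {dup[:5]}")
    if not all(pd.api.types.is_numeric_dtype(t) for t in df.dtypes):
        raise ValidationError("non-numeric expression values")
    if (df.to_numpy() < 0).any():
        raise ValidationError("negative expression values")

    if isinstance(gene_kinds, (str, Path)):
        kinds = pd.read_csv(gene_kinds, sep="\t", index_col=0)["kind"]
    else:
        kinds = gene_kinds
    tumor = set(tumor_samples or [])
    groups = pd.Series(
        [TUMOR if s in tumor else NORMAL for s in df.columns], index=df.columns
    )
    try:
        return GeneExpressionMatrix(df, kinds, groups)
    except ValueError as err:
        raise ValidationError(str(err)) from err


def write_expression(expr: GeneExpressionMatrix, path: str | Path) -> None:
    expr.values.rename_axis("gene_id").to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> SurvivalData:
    """Read the clinical TSV; rows with missing or non-positive time or a
    missing event are dropped with a logged count; a non-binary event is an
    error."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
    except (pd.errors.EmptyDataError, ValueError) as err:
        raise ValidationError(f"malformed clinical file {path}: {err}") from err
    missing = [c for c in ("time", "event") if c not in df.columns]
    if missing:
        raise ValidationError(f"clinical file missing column(s) {missing}")
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA

    bad_event = df["event"].dropna()[~df["event"].dropna().isin([0, 1])]
    if len(bad_event):
        raise ValidationError(
            f"event values outside {{0,1}} for samples {bad_event.index.tolist()[:5]}"
        )
    ok = df["time"].notna() & (df["time"] > 0) & df["event"].notna()
    if (~ok).any():
        logger.warning("dropping %d clinical rows with invalid time/event", (~ok).sum())
    return SurvivalData(df[ok].copy())


def write_clinical(surv: SurvivalData, path: str | Path) -> None:
    surv.table.rename_axis("sample_id").to_csv(path, sep="\t")


@dataclass
class PipelineConfig:
    """Fully resolved settings of one pipeline run.

    Threshold defaults are the published ones: immune correlation r > 0.4 at
    p < 0.001; DE |log2FC| >= 1 at BH-adjusted p < 0.05; prevalence window
    [0.2, 0.8]; univariate screen p < 0.05; 1000 bootstraps with frequency
    > 100 and 10-fold CV; ROC horizons 1/2/3 years; AIC cutoff rule.
    """

    expression: str = ""
    gene_kinds: str = ""
    clinical: str = ""
    immune_genes: str = ""
    gene_sets: str = ""  # optional GMT; immune landscape skipped when empty
    outdir: str = "results"
    seed: int = 0

    r_min: float = 0.4
    p_max: float = 0.001
    corr_method: str = "pearson"
    corr_samples: str = "all"
    lfc_threshold: float = 1.0
    de_alpha: float = 0.05
    prevalence_low: float = 0.2
    prevalence_high: float = 0.8
    screen_alpha: float = 0.05
    n_bootstrap: int = 1000
    freq_threshold: int = 100
    cv_folds: int = 10
    roc_horizons: list[float] = field(default_factory=lambda: [365.0, 730.0, 1095.0])
    cutoff_rule: str = "aic"
    min_group_frac: float = 0.10
    ssgsea_alpha: float = 0.25

    def __post_init__(self) -> None:
        checks = [
            (0 <= self.r_min <= 1, "r_min in [0,1]"),
            (0 < self.p_max <= 1, "p_max in (0,1]"),
            (0 < self.de_alpha < 1, "de_alpha in (0,1)"),
            (0 <= self.prevalence_low < self.prevalence_high <= 1, "prevalence bounds"),
            (0 < self.screen_alpha < 1, "screen_alpha in (0,1)"),
            (self.n_bootstrap >= 1, "n_bootstrap >= 1"),
            (0 <= self.freq_threshold < self.n_bootstrap, "freq_threshold < B"),
            (self.cv_folds >= 2, "cv_folds >= 2"),
            (self.cutoff_rule in ("aic", "youden"), "cutoff_rule"),
            (self.ssgsea_alpha > 0, "ssgsea_alpha > 0"),
        ]
        for ok, what in checks:
            if not ok:
                raise ValidationError(f"config constraint violated: {what}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
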