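"""Core in-memory containers: expression matrices and survival tables.

Both containers are thin, validated wrappers around pandas objects so the
rest of the package can rely on their invariants (non-negative expression,
unique ids, positive follow-up times, binary event indicators) without
re-checking them at every call site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"

CLINICAL_COLUMNS = ["time", "event", "age", "gender", "stage", "T", "N", "M"]


@dataclass
class GeneExpressionMatrix:
    """Genes x samples expression on a linear (FPKM-like) scale.

    Parameters
    ----------
    values : DataFrame
        Non-negative expression, index = gene ids, columns = sample ids.
    gene_kind : Series
        ``"lncRNA"`` or ``"mRNA"`` per gene, indexed like ``values``.
    sample_group : Series
        ``"tumor"`` or ``"normal"`` per sample, indexed by sample id.
    """

    values: pd.DataFrame
    gene_kind: pd.Series
    sample_group: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if v.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (v.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        self.gene_kind = self.gene_kind.reindex(v.index)
        if self.gene_kind.isna().any():
            raise ValueError("gene_kind missing for some genes")
        bad = set(self.gene_kind.unique()) - {"lncRNA", "mRNA"}
        if bad:
            raise ValueError(f"unknown gene kinds: {bad}")
        self.sample_group = self.sample_group.reindex(v.columns)
        if self.sample_group.isna().any():
            raise ValueError("sample_group missing for some samples")
        bad = set(self.sample_group.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown sample groups: {bad}")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def lncrna_ids(self) -> pd.Index:
        return self.values.index[self.gene_kind == "lncRNA"]

    @property
    def mrna_ids(self) -> pd.Index:
        return self.values.index[self.gene_kind == "mRNA"]

    @property
    def tumor_ids(self) -> pd.Index:
        return self.values.columns[self.sample_group == TUMOR]

    @property
    def normal_ids(self) -> pd.Index:
        return self.values.columns[self.sample_group == NORMAL]

    def log2p1(self) -> pd.DataFrame:
        """log2(x + 1) transform used throughout the pipeline."""
        return np.log2(self.values + 1.0)

    def subset_samples(self, sample_ids) -> "GeneExpressionMatrix":
        return GeneExpressionMatrix(
            self.values.loc[:, sample_ids],
            self.gene_kind,
            self.sample_group.loc[sample_ids],
        )


@dataclass
class SurvivalData:
    """Per-sample follow-up time, event indicator and clinical covariates.

    ``table`` is indexed by sample id and carries at least ``time`` (>0) and
    ``event`` (0/1); the clinical covariates ``age, gender, stage, T, N, M``
    may contain missing values but the columns are always present.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise ValueError("duplicate sample ids in survival data")
        for col in ("time", "event"):
            if col not in t.columns:
                raise ValueError(f"survival table missing column {col!r}")
        for col in CLINICAL_COLUMNS:
            if col not in t.columns:
                t[col] = np.nan
        if (t["time"] <= 0).any():
            raise ValueError("follow-up times must be positive")
        if not t["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        self.table = t

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def time(self) -> pd.Series:
        return self.table["time"]

    @property
    def event(self) -> pd.Series:
        return self.table["event"].astype(int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, sample_ids) -> "SurvivalData":
        return SurvivalData(self.table.loc[sample_ids].copy())

    def align(self, sample_ids) -> "SurvivalData":
        """Restrict to the intersection with ``sample_ids``, preserving their order."""
        keep = [s for s in sample_ids if s in self.table.index]
        return SurvivalData(self.table.loc[keep].copy())
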