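"""Binary lncRNA-pair features.

The pair encoding is the normalization-free core of the method: for an
unordered pair of lncRNAs (A, B), a sample scores 1 when A's expression
strictly exceeds B's in that sample and 0 otherwise.  Because the feature
depends only on the within-sample ordering of the two genes, it is invariant
to any strictly increasing per-sample transform of the expression vector —
no cross-sample normalization is needed before pooling cohorts.

Near-constant features carry no prognostic contrast, so pairs whose fraction
of ones across samples falls outside a prevalence window (default [0.2, 0.8],
inclusive) are removed before modelling.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .datatypes import GeneExpressionMatrix

logger = logging.getLogger(__name__)


class LncPair(NamedTuple):
    """Canonically oriented unordered pair: ``id_a < id_b`` lexicographically."""

    id_a: str
    id_b: str

    @property
    def name(self) -> str:
        return f"{self.id_a}|{self.id_b}"

    @classmethod
    def from_name(cls, name: str) -> "LncPair":
        a, b = name.split("|")
        return cls(a, b)

    @classmethod
    def canonical(cls, a: str, b: str) -> "LncPair":
        if a == b:
            raise ValueError(f"pair members must differ: {a!r}")
        return cls(a, b) if a < b else cls(b, a)


@dataclass
class PairFeatureMatrix:
    """Binary pair indicators, pairs x samples.

    ``values`` has index = pair names ("A|B", canonical orientation) and int
    cells in {0, 1}.  ``prevalence`` (fraction of ones per pair) is always
    recomputable from ``values``.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("pair feature values must be 0 or 1")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate pair names")
        self.values = self.values.astype(np.int8)

    @property
    def pairs(self) -> list[LncPair]:
        return [LncPair.from_name(n) for n in self.values.index]

    @property
    def pair_names(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def prevalence(self) -> pd.Series:
        return self.values.mean(axis=1)

    def subset_samples(self, sample_ids) -> "PairFeatureMatrix":
        return PairFeatureMatrix(self.values.loc[:, sample_ids])


def encode_pairs(
    expr: GeneExpressionMatrix | pd.DataFrame, lnc_ids: Sequence[str]
) -> PairFeatureMatrix:
    """Encode every unordered lncRNA pair as a 0/1 feature per sample.

    For the canonical pair (A, B) with A < B, a sample is 1 iff
    expression(A) > expression(B) strictly in that sample; ties encode 0.

    Parameters
    ----------
    expr : GeneExpressionMatrix or DataFrame
        Expression with genes in rows.  Only the rows in ``lnc_ids`` are used.
    lnc_ids : sequence of str
        At least two lncRNA ids present in ``expr``.
    """
    table = expr.values if isinstance(expr, GeneExpressionMatrix) else expr
    ids = list(dict.fromkeys(lnc_ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 lncRNA ids to form pairs")
    missing = [i for i in ids if i not in table.index]
    if missing:
        raise KeyError(f"lncRNA ids missing from expression matrix: {missing[:5]}")

    ids = sorted(ids)
    mat = table.loc[ids].to_numpy(dtype=float)
    combos = list(itertools.combinations(range(len(ids)), 2))
    out = np.empty((len(combos), mat.shape[1]), dtype=np.int8)
    n_ties = 0
    for row, (i, j) in enumerate(combos):
        gt = mat[i] > mat[j]
        n_ties += int(np.sum(mat[i] == mat[j]))
        out[row] = gt
    if n_ties:
        logger.warning("encode_pairs: %d tied comparisons encoded as 0", n_ties)
    names = [f"{ids[i]}|{ids[j]}" for i, j in combos]
    return PairFeatureMatrix(pd.DataFrame(out, index=names, columns=table.columns))


def prevalence_filter(
    pm: PairFeatureMatrix, low: float = 0.2, high: float = 0.8
) -> PairFeatureMatrix:
    """Keep pairs whose prevalence lies in [low, high] (inclusive)."""
    if low >= high:
        raise ValueError(f"low must be < high (got {low}, {high})")
    prev = pm.prevalence
    keep = prev.index[(prev >= low) & (prev <= high)]
    logger.info("prevalence_filter: %d of %d pairs kept", len(keep), len(prev))
    return PairFeatureMatrix(pm.values.loc[keep])
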