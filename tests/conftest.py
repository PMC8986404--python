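"""Shared fixtures: small synthetic cohorts and toy survival data."""

import logging

import numpy as np
import pandas as pd
import pytest

from lncpair.datatypes import GeneExpressionMatrix, SurvivalData
from lncpair.simulate import CohortConfig, lnc_id, simulate_cohort

logging.getLogger("lncpair").setLevel(logging.ERROR)

TRUE_PAIRS = [
    (lnc_id(0), lnc_id(1), 0.8),
    (lnc_id(2), lnc_id(3), -0.8),
    (lnc_id(4), lnc_id(5), 0.6),
]
TRUE_PAIR_NAMES = {f"{a}|{b}": beta for a, b, beta in TRUE_PAIRS}


def strong_signal_config(seed: int = 0, n_tumor: int = 300, **kw) -> CohortConfig:
    """Cohort with three prognostic pairs of known effect among noise pairs."""
    defaults = dict(
        n_tumor=n_tumor,
        n_normal=30,
        n_lncrna=20,
        n_immune_mrna=20,
        n_true_immune_lnc=6,
        n_true_de_lnc=6,
        true_pairs=list(TRUE_PAIRS),
        censoring_rate=0.3,
        seed=seed,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


def null_signal_config(seed: int = 0, **kw) -> CohortConfig:
    """Cohort whose survival is independent of every pair feature."""
    defaults = dict(
        n_tumor=150,
        n_normal=25,
        n_lncrna=14,
        n_immune_mrna=14,
        n_true_immune_lnc=8,
        n_true_de_lnc=8,
        true_pairs=[],
        censoring_rate=0.3,
        seed=seed,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def strong_cohort():
    return simulate_cohort(strong_signal_config(seed=0))


@pytest.fixture(scope="session")
def null_cohort():
    return simulate_cohort(null_signal_config(seed=0))


def random_expression(
    rng: np.random.Generator, n_genes: int, n_samples: int, n_normal: int = 0
) -> GeneExpressionMatrix:
    """Unstructured positive expression matrix for oracle tests."""
    genes = [f"G{i:03d}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    values = pd.DataFrame(
        rng.lognormal(2.0, 1.0, (n_genes, n_samples)), index=genes, columns=samples
    )
    group = ["normal" if i < n_normal else "tumor" for i in range(n_samples)]
    return GeneExpressionMatrix(
        values,
        pd.Series("lncRNA", index=values.index),
        pd.Series(group, index=values.columns),
    )


def toy_survival(
    time, event, index=None, rng: np.random.Generator | None = None
) -> SurvivalData:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    idx = index if index is not None else [f"P{i:03d}" for i in range(len(time))]
    return SurvivalData(pd.DataFrame({"time": time, "event": event}, index=idx))
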