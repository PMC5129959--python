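import numpy as np
import pandas as pd
import pytest

from milispread import CohortConfig, ExpressionMatrix, PlantedEffects, generate_cohort


def small_config(seed: int = 0, **overrides) -> CohortConfig:
    """Desk-scale cohort layout used across tests (documented in docs/methods.md)."""
    defaults = dict(
        n_patients=23,
        n_coding=300,
        n_lncrna=100,
        n_mirna=60,
        n_pirna=20,
        n_snrna=10,
        n_snorna=10,
        lib_size_mean=5e5,
        n_gene_sets=20,
        gene_set_size=15,
        n_up_mirnas=4,
        targets_per_mirna=12,
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def cohort():
    """One planted-effects cohort shared by read-only tests."""
    return generate_cohort(small_config(seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    return generate_cohort(small_config(seed=12), PlantedEffects.null())


def make_matrix(values, biotypes=None, scale="raw", lib_sizes=None) -> ExpressionMatrix:
    """Small ExpressionMatrix from a 2-D array; default biotype coding."""
    values = np.asarray(values)
    n_feat, n_samp = values.shape
    index = [f"f{i}" for i in range(n_feat)]
    cols = [f"s{j}" for j in range(n_samp)]
    if biotypes is None:
        biotypes = ["coding"] * n_feat
    df = pd.DataFrame(values, index=index, columns=cols)
    bt = pd.Series(biotypes, index=index)
    ls = None if lib_sizes is None else pd.Series(lib_sizes, index=cols, dtype=float)
    return ExpressionMatrix(values=df, biotype=bt, lib_sizes=ls, scale=scale)
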