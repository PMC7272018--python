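import numpy as np
import pandas as pd
import pytest

from pathrisk import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A cohort small enough for per-test use but with every component."""
    return SimulationConfig(
        n_case=30,
        n_control=30,
        n_genes=400,
        n_planted_up=40,
        n_planted_down=30,
        effect_size=1.5,
        n_terms=8,
        genes_per_term=(8, 15),
        seed=2024,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def toy_expr():
    """4 genes x 4 samples with exactly known values."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [2.0, 2.0, 2.0, 2.0],
         [0.0, 1.0, 0.0, 1.0],
         [5.0, 3.0, 1.0, -1.0]],
        index=["G1", "G2", "G3", "G4"],
        columns=["s1", "s2", "s3", "s4"],
    )


def two_group_matrix(rng, n_genes, n_per_group, shift_genes=(), shift=0.0):
    """Gene x sample Gaussian matrix; ``shift_genes`` rows shifted in group 2."""
    cols = [f"c{i}" for i in range(n_per_group)] + [f"t{i}" for i in range(n_per_group)]
    values = rng.normal(size=(n_genes, 2 * n_per_group))
    idx = [f"g{i}" for i in range(n_genes)]
    df = pd.DataFrame(values, index=idx, columns=cols)
    for g in shift_genes:
        df.loc[g, df.columns[n_per_group:]] += shift
    labels = pd.Series(
        ["control"] * n_per_group + ["case"] * n_per_group, index=cols
    )
    return df, labels
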