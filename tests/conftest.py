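import numpy as np
import pandas as pd
import pytest

from prostasig import SimConfig, generate_cohort, nonneg_transform, score_pathways


@pytest.fixture(scope="session")
def default_cohort():
    """Reference study conditions: 2000 genes x 300 samples, seed 1."""
    config = SimConfig(seed=1)
    expr, clinical, truth = generate_cohort(config)
    return config, expr, clinical, truth


@pytest.fixture(scope="session")
def default_zscores(default_cohort):
    _, expr, _, truth = default_cohort
    return score_pathways(expr, truth.pathway_sets)


@pytest.fixture(scope="session")
def default_nonneg(default_zscores):
    return nonneg_transform(default_zscores)


def small_config(**overrides) -> SimConfig:
    """A reduced cohort for fast functional tests."""
    base = dict(
        n_genes=800,
        n_samples=90,
        genes_per_pathway=20,
        n_de_genes_per_subgroup=40,
        seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture()
def small_cohort():
    config = small_config()
    expr, clinical, truth = generate_cohort(config)
    return config, expr, clinical, truth


@pytest.fixture()
def tiny_matrix():
    """4 genes x 3 samples with distinct, hand-checkable values."""
    return pd.DataFrame(
        np.array([[1.0, 4.0, 2.0],
                  [2.0, 5.0, 1.0],
                  [3.0, 6.0, 4.0],
                  [4.0, 7.0, 3.0]]),
        index=["g1", "g2", "g3", "g4"],
        columns=["s1", "s2", "s3"],
    )
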