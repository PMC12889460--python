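"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pandas as pd
import pytest

from missense_states import (
    HmmModel,
    SimulationConfig,
    binarize,
    emission_likelihood,
    simulate_dataset,
    simulate_model,
)


def brute_force_posteriors(model: HmmModel, codes: np.ndarray):
    """Exhaustive path enumeration: exact posteriors and log-likelihood.

    Independent of the forward-backward implementation: sums the joint
    probability of every one of the K^T state paths directly.
    """
    K = model.n_states
    T = codes.shape[0]
    b = np.array([emission_likelihood(model, codes[t]) for t in range(T)])
    total = 0.0
    post = np.zeros((T, K))
    for path in itertools.product(range(K), repeat=T):
        p = model.initial[path[0]] * b[0, path[0]]
        for t in range(1, T):
            p *= model.transition[path[t - 1], path[t]] * b[t, path[t]]
        total += p
        for t in range(T):
            post[t, path[t]] += p
    return post / total, float(np.log(total))


def random_model(rng: np.random.Generator, K: int, M: int) -> HmmModel:
    return HmmModel(
        rng.dirichlet(np.ones(K)),
        rng.dirichlet(np.ones(K), size=K),
        rng.uniform(0.05, 0.95, (K, M)),
    )


@pytest.fixture(scope="session")
def oracle():
    return brute_force_posteriors


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated world: 4 states, 8 scores, 60 genes x 40 positions."""
    config = SimulationConfig(
        seed=101, K=4, M=8, n_genes=60, positions_per_gene=40, alts_per_position=2
    )
    model = simulate_model(config)
    dataset = simulate_dataset(model, config)
    codes = binarize(dataset.table, threshold=dataset.band_threshold)
    return config, model, dataset, codes


@pytest.fixture()
def toy_table():
    """A 6-variant, 2-gene table with one score column, hand-checkable."""
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 4 + ["chr2"] * 2,
            "pos": [100, 100, 105, 110, 50, 55],
            "ref": ["A", "A", "C", "G", "T", "A"],
            "alt": ["T", "G", "T", "A", "C", "C"],
            "gene": ["g1", "g1", "g1", "g1", "g2", "g2"],
            "aaref": ["P", "P", "L", "K", "R", "S"],
            "aaalt": ["L", "R", "F", "N", "H", "T"],
            "s1": [0.95, 0.2, 0.5, np.nan, 0.8, 0.1],
        }
    )
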