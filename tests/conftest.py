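"""Shared fixtures: a small simulated dataset and one analyzed run.

Everything is generated programmatically at test time with fixed seeds;
session scope keeps the (cheap but not free) network ensemble runs to a
minimum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fractomap.pipeline import RunConfig, analyze
from fractomap.simulate import SimulationConfig, simulate_dataset


def small_sim_config(**overrides) -> SimulationConfig:
    base = dict(
        n_compartments=4, n_fractions=10, n_replicates=3, seed=123,
        markers_per_compartment=(15, 25), unannotated_singles=(20, 30),
        doubles_per_compartment=(15, 25), triples_per_compartment=(5, 10),
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate_dataset(small_sim_config())


@pytest.fixture(scope="session")
def tiny_two_condition_dataset():
    return simulate_dataset(small_sim_config(n_conditions=2, seed=321))


@pytest.fixture(scope="session")
def tiny_run(tiny_dataset):
    cfg = RunConfig(seed=5, rounds=1, runs=2, tune=False)
    return analyze(tiny_dataset.fractionation, tiny_dataset.markers, cfg,
                   totals=tiny_dataset.totals)


@pytest.fixture(scope="session")
def tiny_two_condition_run(tiny_two_condition_dataset):
    ds = tiny_two_condition_dataset
    cfg = RunConfig(seed=5, rounds=1, runs=2, tune=False)
    return analyze(ds.fractionation, ds.markers, cfg, totals=ds.totals)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_simplex(rng, n: int) -> np.ndarray:
    x = rng.dirichlet(np.ones(n))
    return x / x.sum()
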