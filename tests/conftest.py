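import numpy as np
import pandas as pd
import pytest

from secromine.preprocess import ProteinMatrix
from secromine.synthetic import SimulationConfig, simulate_experiment


def tiny_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Small but fully structured study for fast unit tests."""
    defaults = dict(
        n_antibodies=60,
        n_antibodies_extended=80,
        n_panel1_missing=2,
        secretome_cell_lines=8,
        secretome_control_arrays=3,
        train_pdac=10,
        train_cp=6,
        train_healthy=8,
        test_pdac=6,
        test_cp=6,
        test_healthy=6,
        n_secretome_markers=10,
        n_serum_markers=12,
        n_shared_markers=3,
        n_cp_confounded=2,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_experiment():
    """One full-scale default simulation shared by read-only tests."""
    return simulate_experiment(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def tiny_experiment():
    return simulate_experiment(tiny_config(seed=3))


def make_matrix(M: pd.DataFrame, groups, cohorts=None) -> ProteinMatrix:
    return ProteinMatrix.from_m(M, groups, cohorts)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
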