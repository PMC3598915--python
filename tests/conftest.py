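import numpy as np
import pytest

from survtransfer import ModelConfig, SimConfig, generate_multicenter
from survtransfer.survival import SurvivalOutcome, arrays_to_outcomes


@pytest.fixture(scope="session")
def model_config():
    # threshold relaxed from the library default so that small synthetic
    # cohorts (n=150) still yield non-empty gene signatures
    return ModelConfig(selection_threshold=0.01)


@pytest.fixture(scope="session")
def four_center_study():
    """Four synthetic centers with planted clinical and gene signal."""
    cfg = SimConfig(
        n_centers=4,
        n_patients_per_center=(150, 150, 150, 150),
        n_genes=120,
        n_prognostic_genes=8,
        gene_effects=0.15,
        seed=11,
    )
    return generate_multicenter(cfg)


@pytest.fixture(scope="session")
def two_center_study():
    """Two larger centers for resampling tests (center_b split 55/rest)."""
    cfg = SimConfig(
        n_centers=2,
        n_patients_per_center=(250, 250),
        n_genes=120,
        n_prognostic_genes=8,
        gene_effects=0.15,
        seed=23,
    )
    return generate_multicenter(cfg)


@pytest.fixture
def toy_outcomes():
    """Six patients, all events, fully separated between two groups."""
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    events = np.ones(6, dtype=int)
    groups = np.array([0, 0, 0, 1, 1, 1])
    return arrays_to_outcomes(times, events), groups


def random_censored_outcomes(rng, n):
    times = rng.exponential(1.0, size=n) + 1e-3
    events = rng.integers(0, 2, size=n)
    if events.sum() == 0:
        events[0] = 1
    return arrays_to_outcomes(times, events)
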