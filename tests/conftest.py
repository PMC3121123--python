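import numpy as np
import pytest

from bindstack.stacker import TrainingConfig
from bindstack.synthetic import ComplexSpec, build_toy_complex, simulate_dataset


@pytest.fixture(scope="session")
def toy_complex():
    """Four residues at scripted distances straddling the 3.5 A cutoff."""
    structure, truth = build_toy_complex(
        ComplexSpec(residue_distances=(3.0, 3.4, 3.6, 7.0))
    )
    return structure, truth


@pytest.fixture(scope="session")
def scripted_complex():
    """Thirty residues spanning 2.0-9.0 A minimum protein-DNA distances."""
    distances = tuple(np.round(np.linspace(2.0, 9.0, 30), 3))
    structure, truth = build_toy_complex(
        ComplexSpec(residue_distances=distances, dna_length=40)
    )
    return structure, truth


@pytest.fixture(scope="session")
def small_dataset():
    """Simulated six-predictor dataset at benchmark imbalance, n=1500."""
    return simulate_dataset(1500, seed=11)


@pytest.fixture
def fast_config():
    """Single-point hyperparameter grid for tests not about model selection."""
    return TrainingConfig(cost_grid=(1.0,), gamma_grid=(0.5,), rng_seed=5)
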