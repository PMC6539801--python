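import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sirmsmix.chemistry import assign_atom_properties, parse_molecule

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pentane():
    return parse_molecule("CCCCC", "n-pentane", add_hydrogens=False)


@pytest.fixture(scope="session")
def benzene():
    return parse_molecule("c1ccccc1", "benzene", add_hydrogens=False)


@pytest.fixture(scope="session")
def acetone_heavy():
    return assign_atom_properties(
        parse_molecule("CC(C)=O", "acetone", add_hydrogens=False)
    )


@pytest.fixture(scope="session")
def ethanol():
    return assign_atom_properties(parse_molecule("CCO", "ethanol", add_hydrogens=True))


@pytest.fixture(scope="session")
def small_regression():
    """A well-conditioned 8x2 least-squares instance with known generator."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(8, 2))
    beta = np.array([3.0, -1.5])
    y = 5.0 + X @ beta + rng.normal(scale=0.3, size=8)
    return X, y


@pytest.fixture(scope="session")
def tiny_dataset():
    """One small synthetic mixture dataset shared across tests (generation
    reuses the process-wide descriptor caches, so this is cheap after the
    first use)."""
    from sirmsmix.synthetic_data import simulate_dataset

    return simulate_dataset(n_mixtures=40, seed=123, n_active=3)
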