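import numpy as np
import pytest

from weanabc import (
    SMCConfig,
    default_fixture_spec,
    default_qp,
    default_turnover_table,
    generate_population,
    run_smc,
)

# Published discrete turnover rates (per year) for ages 0-20:
# mineral, collagen, and the quartic-polynomial smoothing of collagen.
REFERENCE_MINERAL = np.array([
    1.217, 0.908, 0.786, 0.700, 0.629, 0.571, 0.527, 0.492, 0.462, 0.434,
    0.407, 0.378, 0.349, 0.319, 0.289, 0.258, 0.227, 0.194, 0.158, 0.118,
])
REFERENCE_COLLAGEN = np.array([
    1.474, 1.059, 0.892, 0.776, 0.682, 0.611, 0.558, 0.520, 0.489, 0.461,
    0.432, 0.402, 0.370, 0.337, 0.302, 0.267, 0.231, 0.193, 0.151, 0.104,
])
REFERENCE_QP = np.array([
    1.413, 1.134, 0.924, 0.771, 0.664, 0.590, 0.540, 0.507, 0.483, 0.463,
    0.441, 0.416, 0.386, 0.349, 0.306, 0.260, 0.213, 0.171, 0.139, 0.124,
])


@pytest.fixture(scope="session")
def table():
    return default_turnover_table()


@pytest.fixture(scope="session")
def qp():
    return default_qp()


@pytest.fixture(scope="session")
def fixture_population():
    """Deterministic synthetic assemblage with known weaning parameters."""
    spec = default_fixture_spec(seed=3, n_subadults=30)
    return spec, generate_population(spec)


@pytest.fixture(scope="session")
def fitted(fixture_population):
    """One ABC-SMC fit of the fixture population, shared across tests."""
    _, pop = fixture_population
    return run_smc(pop, config=SMCConfig(n_particles=1500, n_stages=5, seed=11))
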