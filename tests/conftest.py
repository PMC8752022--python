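import numpy as np
import pytest

from mhecosim.causal import build_default_network, propagate
from mhecosim.ecosystem import GeneratorParams, generate_ecosystem
from mhecosim.montecarlo import SimulationConfig, run_simulation
from mhecosim.pipeline import fit_models, propagation_models
from mhecosim.scenarios import default_scenarios


@pytest.fixture(scope="session")
def default_params():
    return GeneratorParams(seed=7)


@pytest.fixture(scope="session")
def default_table(default_params):
    return generate_ecosystem(default_params)


@pytest.fixture(scope="session")
def fitted_models(default_table):
    return fit_models(default_table)


@pytest.fixture(scope="session")
def network(fitted_models):
    return build_default_network(propagation_models(fitted_models))


@pytest.fixture(scope="session")
def dist_pre(network, default_table):
    with pytest.warns(UserWarning, match="positive exponent"):
        return propagate(network, default_table)


@pytest.fixture(scope="session")
def small_mc(dist_pre, default_table):
    """A small but non-trivial Monte Carlo result for indicator tests."""
    config = SimulationConfig(
        scenarios=default_scenarios(default_table.to_frame().columns, 5),
        n_replicates=60,
        seed=11,
        orientations=("input", "output"),
    )
    return run_simulation(dist_pre, config, default_table)
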