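import numpy as np
import pytest

import celldose as cd


@pytest.fixture(scope="session")
def lu():
    return cd.lu177()


@pytest.fixture(scope="session")
def water():
    return cd.builtin("water")


@pytest.fixture(scope="session")
def gold():
    return cd.builtin("gold")


@pytest.fixture()
def model():
    return cd.CellModel()


@pytest.fixture()
def gold_shell_model():
    return cd.standard_gold_shell_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def scenario_svalues():
    """Session-wide Monte Carlo S-values for the scenario compartments."""
    model = cd.CellModel()
    rng = np.random.default_rng(42)
    return model, cd.compute_scenario_s_values(
        model, cd.TransportConfig(), 8000, rng)
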