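import numpy as np
import pandas as pd
import pytest

from deweight import CovariateRoles, DisparityDataset, SimulationConfig, generate


def make_dataset(Z, Y, ses: dict, health: dict) -> DisparityDataset:
    """Assemble a small DisparityDataset from plain sequences."""
    roles = CovariateRoles(
        group="group",
        minority_level=1,
        outcome="Y",
        ses=tuple(ses),
        health=tuple(health),
    )
    return DisparityDataset(
        Z=np.asarray(Z),
        Y=np.asarray(Y, dtype=float),
        X_s=pd.DataFrame(ses),
        X_h=pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in health.items()}),
        roles=roles,
    )


@pytest.fixture
def tiny_dataset():
    """Four subjects, one binary SES column, one health column."""
    return make_dataset(
        Z=[1, 1, 0, 0],
        Y=[1, 0, 1, 0],
        ses={"edu": [1, 0, 1, 0]},
        health={"sev": [0.5, -0.2, 0.1, 0.4]},
    )


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def medium_data(default_config):
    """One n=2000 draw from the default generator, shared across tests."""
    return generate(default_config, seed=42, n=2000)
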