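import numpy as np
import pytest

from pahbind import GeneratorConfig, packaged_fixture, read_titration_csv


@pytest.fixture(scope="session")
def naphthalene_series():
    """The packaged naphthalene titration (11 points, mol/L)."""
    return read_titration_csv(packaged_fixture("table1_naphthalene.csv"))


@pytest.fixture()
def noiseless_cfg():
    return GeneratorConfig(seed=0, noise_level=0.0)


@pytest.fixture()
def table1_grid():
    """The titration's protein-concentration grid in mol/L."""
    return np.array([0, 0.12, 0.24, 0.48, 0.96, 1.9, 3.8,
                     7.7, 15.4, 30.75, 61.5]) * 1e-6
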