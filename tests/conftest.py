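import numpy as np
import pytest

import sonolens as sl


@pytest.fixture(scope="session")
def water():
    return sl.Medium.water()


@pytest.fixture(scope="session")
def config():
    return sl.ExperimentConfig()


@pytest.fixture(scope="session")
def planar_tx():
    return sl.get_preset("tx_0.5_44")


@pytest.fixture(scope="session")
def focused_tx():
    return sl.get_preset("h204")


@pytest.fixture(scope="session")
def material():
    return sl.LensMaterial()


@pytest.fixture(scope="session")
def lut_500k(material):
    return sl.build_phase_height_lut(material, 0.5e6)


@pytest.fixture(scope="session")
def grid_2d(planar_tx, water):
    """Standard 2-D free-field design grid for the planar preset."""
    return sl.SimulationGrid.from_frequency(
        planar_tx.f0, water.c0, 7, nx=229, nz=179
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
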