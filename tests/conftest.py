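import numpy as np
import pytest

from aiseap.cable import StimulusSpec, simulate
from aiseap.cli_io import ExperimentConfig
from aiseap.morphology import build_soma_axon


@pytest.fixture(scope="session")
def default_config() -> ExperimentConfig:
    return ExperimentConfig()


@pytest.fixture(scope="session")
def sim_ais45():
    """Default axonal-initiation simulation, AIS 45 μm from the soma."""
    morph, layout = build_soma_axon(ais_start=45.0)
    return simulate(morph, layout, stim=StimulusSpec())


@pytest.fixture(scope="session")
def sim_ais0():
    """Axonal-initiation simulation with the AIS abutting the soma."""
    morph, layout = build_soma_axon(ais_start=0.0)
    return simulate(morph, layout, stim=StimulusSpec())


@pytest.fixture(scope="session")
def sim_somatic():
    """Somatic-initiation simulation (all active channels on the soma)."""
    morph, layout = build_soma_axon(ais_start=45.0,
                                    channel_config="somatic_initiation")
    return simulate(morph, layout, stim=StimulusSpec(amplitude=1.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
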