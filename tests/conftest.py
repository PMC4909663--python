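import numpy as np
import pytest

from peepabsorb import (
    Compartment,
    LungModel,
    VentilatorSettings,
    calibrate_two_compartment_patient,
)
from peepabsorb.config import SolverConfig


@pytest.fixture(scope="session")
def default_settings() -> VentilatorSettings:
    """VT 0.5 L, RR 20/min, Ti 1 s -> Te 2 s, constant flow 0.5 L/s."""
    return VentilatorSettings(tidal_volume=0.5, respiratory_rate=20.0,
                              inspiratory_time=1.0, applied_peep=0.0)


@pytest.fixture(scope="session")
def mixed_lung_model(default_settings) -> LungModel:
    """Two-compartment model with compartmental auto-PEEPs 4 and 10 cmH2O."""
    return calibrate_two_compartment_patient(4.0, 10.0, default_settings)


@pytest.fixture(scope="session")
def single_rc() -> LungModel:
    """R 20 cmH2O.s/L, C 0.05 L/cmH2O (tau 1 s), noiseless."""
    return LungModel((Compartment(resistance=20.0, compliance=0.05),),
                     noise_sd=0.0)


@pytest.fixture()
def noiseless_solver() -> SolverConfig:
    return SolverConfig(noise_sd=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
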