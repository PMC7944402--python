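import numpy as np
import pytest

from kvshift import GroundTruth, MutantConfig, VoltageProtocol


@pytest.fixture
def protocol() -> VoltageProtocol:
    """Standard step protocol: -80..+50 mV in 10-mV steps, V_K = -80 mV."""
    return VoltageProtocol(test_voltages=tuple(np.arange(-80.0, 51.0, 10.0)))


@pytest.fixture
def noiseless_truth() -> GroundTruth:
    return GroundTruth(noise_sd=0.0, seed=0)


EIGHT_MUTANT_CONFIGS = [
    MutantConfig("WT"),
    MutantConfig("2R", has_2R=True),
    MutantConfig("R362Q", R362Q=True),
    MutantConfig("2R/R362Q", has_2R=True, R362Q=True),
    MutantConfig("W454A", W454A=True),
    MutantConfig("2R/W454A", has_2R=True, W454A=True),
    MutantConfig("R362Q/W454A", R362Q=True, W454A=True),
    MutantConfig("2R/R362Q/W454A", has_2R=True, R362Q=True, W454A=True),
]

SITE_TRUTH = {
    "S3S4": -17.0,
    "WT_362_454": -15.0,
    "R362Q": -34.0,
    "W454A": -6.0,
    "R362Q_W454A": -31.0,
}


@pytest.fixture
def eight_mutant_configs() -> list[MutantConfig]:
    return list(EIGHT_MUTANT_CONFIGS)


@pytest.fixture
def site_truth() -> dict[str, float]:
    return dict(SITE_TRUTH)
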