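import numpy as np
import pytest

from topoproof.energetics import EnergeticsModel, PlasmidSpec, equilibrium_distribution
from topoproof.experiments import default_alpha
from topoproof.gate_cycle import GateModel, calibrate_p0


@pytest.fixture(scope="session")
def pbr322():
    return PlasmidSpec("pBR322", 4300)


@pytest.fixture(scope="session")
def ycp50():
    return PlasmidSpec("YCp50", 7900)


@pytest.fixture(scope="session")
def energetics_4k(pbr322):
    return EnergeticsModel.from_plasmid(pbr322)


@pytest.fixture(scope="session")
def energetics_8k(ycp50):
    return EnergeticsModel.from_plasmid(ycp50)


@pytest.fixture(scope="session")
def eq_4k(energetics_4k):
    return equilibrium_distribution(energetics_4k)


@pytest.fixture(scope="session")
def eq_8k(energetics_8k):
    return equilibrium_distribution(energetics_8k)


@pytest.fixture(scope="session")
def calibrated_gate(energetics_4k):
    """p0 matching the 0.50 single-passage conversion of ΔLk=−2 into ΔLk=0,
    α from the benchmark steady/equilibrium ratio pair (0.17, 0.35)."""
    return GateModel(p0=calibrate_p0(0.50, -2, 0, energetics_4k), alpha=default_alpha())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
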