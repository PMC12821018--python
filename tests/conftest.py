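import numpy as np
import pytest

from elastimap import Cantilever, Indenter, simulate_curve
from elastimap.synthetic import QUIET, NoiseModel


@pytest.fixture(scope="session")
def indenter():
    return Indenter()  # 44.65 um bead


@pytest.fixture(scope="session")
def soft_cantilever():
    return Cantilever(spring_constant=0.09, identifier="tipless-soft")


@pytest.fixture(scope="session")
def quiet_curve(soft_cantilever, indenter):
    """Noise-free reference curve: K = 250 Pa, 30 nN at 20 um/s."""
    return simulate_curve(250.0, cantilever=soft_cantilever, indenter=indenter,
                          noise=QUIET)


@pytest.fixture(scope="session")
def noisy_curve(soft_cantilever, indenter):
    """Same protocol with 1% deflection noise and a random baseline."""
    return simulate_curve(250.0, cantilever=soft_cantilever, indenter=indenter,
                          noise=NoiseModel(seed=7))
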