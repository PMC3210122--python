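"""Shared fixtures: converged cycles and measured PRCs at the reference points.

The expensive objects (limit cycles, direct-method PRCs, coupling
functions) are session-scoped: the near-onset oscillator A relaxes on a
1/mu timescale and the far-from-onset oscillator C needs a fine phase
grid, so they are computed once and reused by the unit and acceptance
tests alike.  Everything here is deterministic.
"""

import numpy as np
import pytest

from delayosc.model import default_param_sets
from delayosc.stability import find_hopf
from delayosc.ddesim import integrate, find_limit_cycle, DDESystem
from delayosc.phase import prc_direct, gamma_convolution
from delayosc import cmr


@pytest.fixture(scope="session")
def sets():
    return default_param_sets()


@pytest.fixture(scope="session")
def pA(sets):
    return sets["A"].params


@pytest.fixture(scope="session")
def pB(sets):
    return sets["B"].params


@pytest.fixture(scope="session")
def pC(sets):
    return sets["C"].params


@pytest.fixture(scope="session")
def hopfA(pA):
    return find_hopf(pA)


@pytest.fixture(scope="session")
def cglA(pA):
    return cmr.cgl_reduce(cmr.amplitude_equation([pA]))


@pytest.fixture(scope="session")
def cycleA(pA, cglA):
    mu = cglA.mu[0]
    T = 2 * np.pi / cglA.oscillation_frequency()
    transient = 300.0 + 12.0 / mu
    traj = integrate(pA, None, 0.05, t_end=transient + 60 * T)
    return find_limit_cycle(traj, transient=transient)


@pytest.fixture(scope="session")
def prcA(pA, cycleA):
    system = DDESystem(pA)
    return prc_direct(system, cycleA, n_phase=64, relax_periods=70)


@pytest.fixture(scope="session")
def gammaA_u(prcA, cycleA):
    return gamma_convolution(prcA, cycleA, "u")


@pytest.fixture(scope="session")
def gammaA_v(prcA, cycleA):
    return gamma_convolution(prcA, cycleA, "v")


@pytest.fixture(scope="session")
def cycleC(pC):
    traj = integrate(pC, None, 0.01, t_end=600.0, steps_per_delay=80)
    return find_limit_cycle(traj, transient=450.0)


@pytest.fixture(scope="session")
def prcC(pC, cycleC):
    system = DDESystem(pC, steps_per_delay=80)
    return prc_direct(system, cycleC, n_phase=128, relax_periods=25)


@pytest.fixture(scope="session")
def gammaC_u(prcC, cycleC):
    return gamma_convolution(prcC, cycleC, "u")


def nrmse(x, ref):
    x = np.asarray(x)
    ref = np.asarray(ref)
    return float(np.sqrt(np.mean((x - ref) ** 2)) / np.sqrt(np.mean(ref ** 2)))
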