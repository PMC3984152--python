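from fractions import Fraction

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from attractor_degree import case_study
from attractor_degree.automata import network_graph
from attractor_degree.network import basal_ganglia_network


@pytest.fixture(scope="session")
def calibration():
    """The calibrated basal-ganglia model (computed once per session)."""
    return case_study.calibrate()


@pytest.fixture(scope="session")
def case_net(calibration):
    return calibration.network()


@pytest.fixture(scope="session")
def case_graph(case_net):
    """Transition graph restricted to the reachable strongly connected component."""
    return network_graph(case_net, reachable_only=True)


@pytest.fixture(scope="session")
def case_degree_result(calibration):
    return case_study.case_degree(calibration)
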