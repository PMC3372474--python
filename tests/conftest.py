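"""Session-scoped simulation fixtures shared across test modules.

Flow solves dominate the suite's runtime, so each configuration is solved
once per session and reused: the steady cases feed the irradiance-sweep,
flow-comparison and conservation tests; the transients feed the
time-constant tests.  Test grids are the smallest the mesher accepts
(tissue shell and eight-cells-across-the-diameter constraints), one notch
below the package defaults; the solver tolerance is relaxed to 2e-5, which
moves surface warming by under ~3%.
"""

import pytest
from hypothesis import settings

from coraltherm import experiments as E
from coraltherm.solver import SolverConfig

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

#: reduced test resolutions (package presets are one notch finer)
TEST_RES = {
    "P. lobata": (50, 26, 26),
    "Favia sp.": (50, 26, 26),
    "S. pistillata": (50, 32, 30),
    "C. serailia": (56, 30, 30),
    "S. hystrix": (60, 42, 42),
}


def fast_config(**kw):
    kw.setdefault("tol", 2e-5)
    return SolverConfig(**kw)


class SteadyCase:
    """A solved steady case plus its per-unit-flux surface warming."""

    def __init__(self, species, u_inlet):
        self.species = species
        self.case = E.build_case(
            E.get_preset(species), u_inlet=u_inlet,
            resolution=TEST_RES[species], config=fast_config(),
        )
        self.unit_mean, self.unit_max, self.energy = E._unit_warming(self.case)

    def warming(self, alpha, irradiance, statistic="max"):
        unit = self.unit_max if statistic == "max" else self.unit_mean
        return alpha * irradiance * unit


@pytest.fixture(scope="session")
def lobata_low():
    return SteadyCase("P. lobata", E.LOW_FLOW)


@pytest.fixture(scope="session")
def lobata_high():
    return SteadyCase("P. lobata", E.HIGH_FLOW)


@pytest.fixture(scope="session")
def pistillata_low():
    return SteadyCase("S. pistillata", E.LOW_FLOW)


@pytest.fixture(scope="session")
def pistillata_high():
    return SteadyCase("S. pistillata", E.HIGH_FLOW)


@pytest.fixture(scope="session")
def favia_low():
    return SteadyCase("Favia sp.", E.LOW_FLOW)


@pytest.fixture(scope="session")
def favia_high():
    return SteadyCase("Favia sp.", E.HIGH_FLOW)


@pytest.fixture(scope="session")
def serailia_transient():
    cfg = fast_config(end_time=1600.0, min_after_on=400.0)
    series, tau, dT_ss = E.run_dark_light(
        "C. serailia", resolution=TEST_RES["C. serailia"], config=cfg
    )
    return {"series": series, "tau": tau, "dT_ss": dT_ss}


@pytest.fixture(scope="session")
def hystrix_transient():
    cfg = fast_config(end_time=1600.0, min_after_on=400.0)
    series, tau, dT_ss = E.run_dark_light(
        "S. hystrix", resolution=TEST_RES["S. hystrix"], config=cfg
    )
    return {"series": series, "tau": tau, "dT_ss": dT_ss}


@pytest.fixture(scope="session")
def sensitivity_tables():
    """Skeletal bulk-volume sensitivity trajectories for both growth forms."""
    out = {}
    cfg = dict(end_time=180.0, min_after_on=180.0)
    for label, species in (("hemisphere", "P. lobata"), ("branch", "S. pistillata")):
        out[label] = E.run_sensitivity(
            species, resolution=TEST_RES[species],
            config=fast_config(**cfg),
        )
    return out
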