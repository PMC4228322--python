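"""Shared fixtures.

The expensive objects — the stem-cell equilibrium and the benchmark scenario
runs — are session-scoped and shared between the unit tests and the
acceptance tests.
"""

from __future__ import annotations

import logging

import pytest

from myelosim.ode_model import OdeModel
from myelosim.scenarios import ScenarioRunner
from myelosim.stem_cells import ScModel

logging.getLogger("myelosim").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sc_model() -> ScModel:
    return ScModel()


@pytest.fixture(scope="session")
def sc_eq(sc_model):
    return sc_model.equilibrium()


@pytest.fixture(scope="session")
def ode_model() -> OdeModel:
    return OdeModel()


@pytest.fixture(scope="session")
def runner() -> ScenarioRunner:
    return ScenarioRunner()


@pytest.fixture(scope="session")
def bmt_ode(runner):
    """ODE transplantation: marrow at 1%, GRA at 50%, 8 days of G-CSF."""
    return runner.bmt("ode", t_end_days=110.0)


@pytest.fixture(scope="session")
def bmt_hybrid_omega(runner):
    """Hybrid transplantation with only growth environment Ω reduced."""
    return runner.bmt("hybrid-omega", t_end_days=60.0)


@pytest.fixture(scope="session")
def chop21_ode(runner):
    return runner.regimen("CHOP-21", engine="ode")


@pytest.fixture(scope="session")
def chop21_hybrid(runner):
    return runner.regimen("CHOP-21", engine="hybrid")
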