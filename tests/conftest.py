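import numpy as np
import pytest

import ventsplit as v
from ventsplit import reference as ref


@pytest.fixture(scope="session")
def gas():
    return v.GasProperties()


@pytest.fixture(scope="session")
def laws():
    """CFD-fitted quadratic laws keyed by nominal diameter (None = bare port)."""
    return ref.RESTRICTOR_LAWS


@pytest.fixture(scope="session")
def power_model():
    return ref.POWER_LAW


@pytest.fixture
def compliant_patient():
    return v.PatientParams(compliance=0.2)


@pytest.fixture
def circuit():
    return v.CircuitParams()


@pytest.fixture
def default_scenario():
    return v.default_scenario()


@pytest.fixture
def step_waveform():
    """Step to PIP=30 over a 1.25 s window, PEEP baseline 5 (driving 25)."""
    return v.build_waveform(v.VentilatorSettings(), dt=1e-3)


def make_branch(label, compliance, law=None):
    return v.BranchConfig(
        label=label,
        patient=v.PatientParams(compliance=compliance),
        circuit=v.CircuitParams(),
        restrictor=law or v.RestrictorLaw.identity())


@pytest.fixture(scope="session")
def bench_flows():
    return np.linspace(1.0, 60.0, 20)
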