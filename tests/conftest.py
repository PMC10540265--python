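import pytest

from fuelcircuits import (
    CalibrationModel,
    CircuitOptions,
    default_true_constants,
    make_exoiii_circuit,
    make_nickase_circuit,
    reference_conditions,
)


@pytest.fixture(scope="session")
def nickase():
    return make_nickase_circuit()


@pytest.fixture(scope="session")
def nickase_lumped():
    return make_nickase_circuit(CircuitOptions(assembly="lumped"))


@pytest.fixture(scope="session")
def exoiii():
    return make_exoiii_circuit()


@pytest.fixture(scope="session")
def nickase_constants():
    return default_true_constants("nickase")


@pytest.fixture(scope="session")
def exoiii_constants():
    return default_true_constants("exoiii")


@pytest.fixture(scope="session")
def nickase_conditions():
    return {c.label: c for c in reference_conditions("nickase")}


@pytest.fixture(scope="session")
def exoiii_conditions():
    return {c.label: c for c in reference_conditions("exoiii")}


@pytest.fixture(scope="session")
def calibration():
    return CalibrationModel(slope=150.0, background=10.0)
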