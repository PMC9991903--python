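"""Shared fixtures: packaged-scenario runs reused across the suite."""

import pytest

import pamvent
from pamvent import AnalysisParams, analyze_record


@pytest.fixture(scope="session")
def subject_a():
    return pamvent.load_scenario("subject-A")


@pytest.fixture(scope="session")
def subject_a_off(subject_a):
    """Subject-A with the assist off: unassisted spontaneous breathing."""
    record, triggers, gas = subject_a.with_controller(mode="off").run(75.0)
    return record, triggers, gas


@pytest.fixture(scope="session")
def subject_a_sync(subject_a):
    """Subject-A with synchronized actuation at the nominal 20 psi."""
    record, triggers, gas = subject_a.run(75.0)
    return record, triggers, gas


@pytest.fixture(scope="session")
def mech_vent_run():
    record, triggers, gas = pamvent.load_scenario("mech-vent").run(45.0)
    return record, triggers, gas


@pytest.fixture(scope="session")
def subject_a_off_summary(subject_a_off):
    record, _, _ = subject_a_off
    return analyze_record(record, AnalysisParams())


@pytest.fixture(scope="session")
def subject_a_sync_summary(subject_a_sync):
    record, _, _ = subject_a_sync
    return analyze_record(record, AnalysisParams())


@pytest.fixture(scope="session")
def mech_vent_summary(mech_vent_run):
    record, _, _ = mech_vent_run
    return analyze_record(record, AnalysisParams())
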