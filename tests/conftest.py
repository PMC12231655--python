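"""Shared fixtures: session-scoped cohort runs and small reusable inputs."""

import numpy as np
import pytest

from setms.pipeline import RunConfig, run_eeg_study, run_mep_study
from setms.preprocess import EEGEpochs
from setms.scheduling import StimulusPlan


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def eeg_cohort_report(default_config):
    """Full 27-participant synthetic EEG study at the default calibration."""
    return run_eeg_study(default_config)


@pytest.fixture(scope="session")
def mep_cohort_report(default_config):
    """Full 19-participant synthetic MEP study at the default calibration."""
    return run_mep_study(default_config)


@pytest.fixture(scope="session")
def sine_epochs() -> EEGEpochs:
    """20 identical epochs of a 10 Hz sinusoid (perfect phase locking)."""
    fs = 1000.0
    time_ms = np.arange(-800, 801)
    trial = 10.0 * np.sin(2 * np.pi * 10.0 * time_ms / 1000.0)
    data = np.tile(trial[None, :, None], (1, 1, 20))
    return EEGEpochs(data, fs, time_ms, ["C3"])


@pytest.fixture()
def pulse_plan() -> StimulusPlan:
    """Minimal pulse plan hosting 100 trials (ISIs all 4 s)."""
    times = np.arange(100) * 4.0
    return StimulusPlan("setms", times, -200.0, np.diff(times))
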