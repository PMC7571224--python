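import numpy as np
import pytest

from gaitload import (
    Anthropometry,
    CyclePolicy,
    GaitSimParams,
    detect_events,
    generate_design,
    generate_trial,
    table3_preset,
)
from gaitload.preprocess import butterworth, FilterSpec


DEFAULT_ANTHRO = Anthropometry("P01", 1.76, 0.94, 0.43, 0.43)


@pytest.fixture(scope="session")
def anthro():
    return DEFAULT_ANTHRO


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free, drift-free, jitter-free 10-cycle trial."""
    params = GaitSimParams(noise_sd_dps=0.0, drift_dps=0.0, cycle_sd_s=0.0, n_cycles=10)
    return generate_trial(params, 42)


@pytest.fixture(scope="session")
def noisy_trial():
    """Trial at default noise/drift, fixed seed."""
    params = GaitSimParams(n_cycles=10)
    return generate_trial(params, 7)


@pytest.fixture(scope="session")
def small_design():
    """Reduced two-participant study with the standard effect preset."""
    return generate_design("expt1", effects=table3_preset(), master_seed=3,
                           n_participants=2)


@pytest.fixture(scope="session")
def expt1_policy():
    return CyclePolicy(skip_first=1, keep=5)


def detect_from_record(record):
    """Run detection the way the pipeline does (2 Hz coarse + refined minima)."""
    shank = record.streams["shank_R"]
    raw = shank.axis("sagittal")
    filt = butterworth(raw, shank.fs, FilterSpec("lowpass", 2, 2.0, True))
    return detect_events(filt, shank.fs, raw=raw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
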