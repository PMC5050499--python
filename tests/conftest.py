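import warnings

import numpy as np
import pytest

from ryrblock import fixtures, synth


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def emd4_scheme():
    return fixtures.emd4()


@pytest.fixture(scope="session")
def emd4_record_10k():
    """Simulated class-level dwell record of the EMD scheme (shared)."""
    return synth.simulate_class_events(fixtures.emd4(), 10_000, seed=101)


@pytest.fixture(scope="session")
def three_level_noiseless_trace():
    """Noiseless unfiltered 3-level trace whose events all span many
    samples (durations bounded away from the sample interval)."""
    rng = np.random.default_rng(7)
    n = 300
    classes = []
    prev = None
    while len(classes) < n:
        c = ("CLOSED", "BLOCKED", "OPEN")[rng.integers(0, 3)]
        if c != prev:
            classes.append(c)
            prev = c
    classes = np.array(classes, dtype=object)
    levels = {"CLOSED": 0.0, "BLOCKED": 6.0, "OPEN": 30.0}
    rec = synth.IdealizedRecord(
        classes=classes,
        durations_ms=rng.integers(20, 200, size=classes.size) * 0.05,
        amplitudes_pA=np.array([levels[c] for c in classes]),
    )
    amps = synth.AmplitudeModel(open_amplitude=30.0, class_levels=levels)
    trace = synth.render_trace(rec, amps, 20_000.0, noise_sd=0.0, filter_cutoff=None, seed=1)
    return trace, rec
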