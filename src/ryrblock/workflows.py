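"""Reproduction workflows: simulate -> render -> idealize -> fit chains.

These functions wire the package's stages into the round-trip recovery
experiments used for validation: a synthetic recording is generated from a
preset scheme whose analytic dwell components sit at the published values,
pushed through SKM idealization and the 0.12 ms dead time, and the dwell
mixtures / amplitude ratios are re-estimated from the synthetic data
alone.  The reported numbers are therefore measurements, not inputs.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import dwell_fit, fixtures, idealize, synth

DEAD_TIME_MS = 0.12
SAMPLING_HZ = 20_000.0
FILTER_HZ = 5_000.0
OPEN_PA = 30.0
NOISE_PA = 3.0  # SNR ~ 10 at the open level
BASELINE_NOISE_PA = 1.5


def _idealize(trace, labels):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = idealize.auto_idealize(trace, len(labels), labels)
        return idealize.impose_dead_time(rec, DEAD_TIME_MS)


def emd4_recovery(seed: int, n_class_events: int = 20_000) -> dict:
    """EMD-activated recording round trip.

    Simulates ``n_class_events`` dwells of the four-state EMD scheme,
    renders at 20 kHz / 5 kHz / SNR 10, idealizes, imposes the dead time
    and fits two-component truncated mixtures (with the missed-event
    lifetime correction) to the closed and open dwells.  Returns the fitted
    components and event counts.
    """
    rng = np.random.default_rng(seed)
    scheme = fixtures.emd4()
    truth = synth.simulate_class_events(scheme, n_class_events, rng)
    amps = synth.AmplitudeModel.for_scheme(
        scheme, OPEN_PA, baseline_noise_sd=BASELINE_NOISE_PA, open_noise_sd=NOISE_PA
    )
    trace = synth.render_trace(
        truth, amps, SAMPLING_HZ, noise_sd=NOISE_PA, filter_cutoff=FILTER_HZ, seed=rng
    )
    rec = _idealize(trace, ("CLOSED", "OPEN"))
    fits = dwell_fit.fit_record_classes(rec, {"CLOSED": 2, "OPEN": 2})
    return {
        "closed": fits["CLOSED"],
        "open": fits["OPEN"],
        "record": rec,
        "truth": truth,
        "n_events": rec.n_events,
    }


def blocker_recovery(preset: str, seed: int, duration_s: float) -> dict:
    """Blocker-preset round trip ('TBA' or 'TPeA').

    Simulates and renders the five-state block preset, idealizes with three
    amplitude classes, imposes the dead time, fits blocked and closed dwell
    mixtures (k=2 each; one open component) and estimates the fractional
    conductance of the blocked level from the idealized amplitudes.  The
    closed-dwell fit uses the artifact screen: closings in these records
    are bounded by the low-contrast blocked level, whose noise dips add a
    false-event population near the resolution limit.
    """
    trace, truth = synth.make_block_recording(preset, duration_s, seed=seed)
    rec = _idealize(trace, ("CLOSED", "BLOCKED", "OPEN"))
    fits = dwell_fit.fit_record_classes(
        rec,
        {"CLOSED": 2, "BLOCKED": 2, "OPEN": 1},
        artifact_screen={"CLOSED"},
    )
    # false closings split the blocked dwells they interrupt; undo that
    # with the false-event rate implied by the screened artifact component
    n_art = fits["CLOSED"].standard_errors.get("artifact_n_observed", 0.0)
    blocked_time_s = rec.durations_of("BLOCKED").sum() * 1e-3
    if n_art > 0 and blocked_time_s > 0:
        fits["BLOCKED"] = dwell_fit.correct_false_event_splitting(
            fits["BLOCKED"], n_art / blocked_time_s
        )
    amp = rec.meta["class_amplitude_pA"]
    return {
        "closed": fits["CLOSED"],
        "blocked": fits["BLOCKED"],
        "fractional_conductance": amp["BLOCKED"] / amp["OPEN"],
        "record": rec,
        "truth": truth,
        "n_events": rec.n_events,
    }
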