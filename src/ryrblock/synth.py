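"""Synthetic single-channel recordings.

Two stages mirror a bilayer experiment: exact stochastic simulation of the
gating scheme (a continuous-time Markov chain sampled by the Gillespie
algorithm, giving the ground-truth event sequence) and rendering of that
event sequence as a sampled current trace -- class amplitude levels, additive
Gaussian noise and a digital approximation of the 8-pole Bessel anti-alias
filter, digitised on a uniform sample grid.  Defaults follow the recording
conditions the analysis is built for: 20 kHz digitisation after 5 kHz
low-pass filtering, ~30 pA full openings (roughly 750 pS at +40 mV in
symmetric 610 mM K+), and noise giving SNR ~ 10 at the open level.

Traces store opening deflections as positive regardless of holding
potential; the physical sign convention is retained in the metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from . import fixtures
from .schemes import GatingScheme, SchemeValidationError, equilibrium_occupancy, generator_matrix

MS_PER_S = 1e3

__all__ = [
    "DwellEvent",
    "IdealizedRecord",
    "Trace",
    "AmplitudeModel",
    "simulate_dwells",
    "simulate_class_events",
    "render_trace",
    "make_block_recording",
]


@dataclass(frozen=True)
class DwellEvent:
    state: str | None
    class_label: str
    duration_ms: float
    amplitude_pA: float


@dataclass
class IdealizedRecord:
    """Ordered dwell sequence -- the currency between idealization, dwell
    fitting and interval-likelihood fitting.

    ``classes`` and ``durations_ms`` are parallel arrays; ``states`` is kept
    for simulated records (None entries for data-derived records) and
    ``amplitudes_pA`` carries per-event mean amplitudes.  ``dead_time_ms`` is
    0 until a dead time has been imposed.
    """

    classes: np.ndarray  # array of str
    durations_ms: np.ndarray  # float, > 0
    amplitudes_pA: np.ndarray  # float
    states: np.ndarray | None = None
    dead_time_ms: float = 0.0
    sampling_rate: float | None = None
    holding_potential_mV: float | None = None
    source: str = "simulated"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=object)
        self.durations_ms = np.asarray(self.durations_ms, dtype=float)
        self.amplitudes_pA = np.asarray(self.amplitudes_pA, dtype=float)
        if self.states is not None:
            self.states = np.asarray(self.states, dtype=object)
        if np.any(self.durations_ms <= 0):
            raise ValueError("all dwell durations must be positive")

    @property
    def n_events(self) -> int:
        return int(self.durations_ms.size)

    @property
    def total_duration_ms(self) -> float:
        return float(self.durations_ms.sum())

    def durations_of(self, class_label: str) -> np.ndarray:
        return self.durations_ms[self.classes == class_label]

    def merge_to_classes(self) -> "IdealizedRecord":
        """Merge adjacent same-class sojourns into class-level events.

        Amplitudes are duration-weighted means; state identity is dropped
        for merged runs.
        """
        if self.n_events == 0:
            return self
        cls = self.classes
        change = np.empty(cls.size, dtype=bool)
        change[0] = True
        change[1:] = cls[1:] != cls[:-1]
        run_id = np.cumsum(change) - 1
        n_runs = run_id[-1] + 1
        dur = np.zeros(n_runs)
        np.add.at(dur, run_id, self.durations_ms)
        amp_w = np.zeros(n_runs)
        np.add.at(amp_w, run_id, self.durations_ms * self.amplitudes_pA)
        return IdealizedRecord(
            classes=cls[change],
            durations_ms=dur,
            amplitudes_pA=amp_w / dur,
            states=None,
            dead_time_ms=self.dead_time_ms,
            sampling_rate=self.sampling_rate,
            holding_potential_mV=self.holding_potential_mV,
            source=self.source,
            meta=dict(self.meta),
        )

    def events(self) -> list[DwellEvent]:
        states = self.states if self.states is not None else [None] * self.n_events
        return [
            DwellEvent(s, c, float(d), float(a))
            for s, c, d, a in zip(states, self.classes, self.durations_ms, self.amplitudes_pA)
        ]


@dataclass
class Trace:
    """Uniformly sampled current trace, opening deflections positive."""

    samples: np.ndarray  # pA
    sampling_rate: float  # Hz
    filter_cutoff: float | None = None  # Hz
    noise_sd: float = 0.0  # pA, post-filter RMS
    holding_potential_mV: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.filter_cutoff and self.sampling_rate <= 2.0 * self.filter_cutoff:
            raise ValueError("sampling_rate must exceed twice the filter cutoff")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class AmplitudeModel:
    """Class current levels and per-class noise.

    Closed sits at 0 pA (baseline subtracted), open at ``open_amplitude``,
    blocked at the scheme's conductance fraction of it.  ``noise_sd`` may be
    a dict of per-class RMS noise (open-channel noise exceeds baseline noise
    in real recordings); a scalar or empty dict means uniform noise set at
    render time.
    """

    open_amplitude: float = 30.0  # pA
    class_levels: dict[str, float] = field(default_factory=dict)
    noise_sd: dict[str, float] | float = 0.0

    @classmethod
    def for_scheme(
        cls,
        scheme: GatingScheme,
        open_amplitude: float = 30.0,
        baseline_noise_sd: float | None = None,
        open_noise_sd: float | None = None,
    ) -> "AmplitudeModel":
        """Levels from the scheme's conductance fractions.

        When both noise arguments are given, per-class noise interpolates
        between the baseline and open values with the conductance fraction
        (residual flux through a blocked pore carries some excess noise).
        """
        fracs = {lbl: scheme.conductance_fraction(lbl) for lbl in scheme.class_labels}
        levels = {lbl: f * open_amplitude for lbl, f in fracs.items()}
        noise: dict[str, float] | float = 0.0
        if baseline_noise_sd is not None and open_noise_sd is not None:
            noise = {
                lbl: baseline_noise_sd + (open_noise_sd - baseline_noise_sd) * f
                for lbl, f in fracs.items()
            }
        return cls(open_amplitude=open_amplitude, class_levels=levels, noise_sd=noise)

    def level(self, class_label: str) -> float:
        return self.class_levels[class_label]

    def noise_of(self, class_label: str, default: float) -> float:
        if isinstance(self.noise_sd, dict) and self.noise_sd:
            return self.noise_sd.get(class_label, default)
        return default


def simulate_dwells(
    scheme: GatingScheme,
    n_events: int,
    seed: int | np.random.Generator,
    initial: str | None = None,
) -> IdealizedRecord:
    """Exact CTMC sample of ``n_events`` state sojourns.

    Sojourn in state i is Exponential with mean 1/|q_ii|; the successor is
    drawn proportional to the outgoing rates.  ``initial`` names a start
    state; by default the start is drawn from the equilibrium occupancy.
    Adjacent same-class sojourns are retained at state level (use
    :meth:`IdealizedRecord.merge_to_classes` for class-level events).
    Amplitudes are the noiseless class conductance fractions (unit open
    amplitude); scale through an :class:`AmplitudeModel` when rendering.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    n_states = scheme.n_states
    Q = generator_matrix(scheme)
    exit_rates = -np.diag(Q)
    if np.any(exit_rates <= 0):
        raise SchemeValidationError("absorbing state in scheme")
    P = Q / exit_rates[:, None]
    np.fill_diagonal(P, 0.0)
    cumP = np.cumsum(P, axis=1)

    if initial is None:
        pi = equilibrium_occupancy(Q)
        state = int(rng.choice(n_states, p=pi))
    else:
        state = scheme.index(initial)

    states = np.empty(n_events, dtype=np.int64)
    if n_events:
        u = rng.random(n_events - 1) if n_events > 1 else np.empty(0)
        for k in range(n_events):
            states[k] = state
            if k < n_events - 1:
                state = int(np.searchsorted(cumP[state], u[k], side="right"))
        durations_s = rng.exponential(scale=1.0 / exit_rates[states])
    else:
        durations_s = np.empty(0)

    labels = np.array([scheme.class_of(s) for s in scheme.state_names], dtype=object)
    fracs = np.array(
        [scheme.state_class[s].conductance_fraction for s in scheme.state_names]
    )
    return IdealizedRecord(
        classes=labels[states] if n_events else np.empty(0, dtype=object),
        durations_ms=durations_s * MS_PER_S,
        amplitudes_pA=fracs[states] if n_events else np.empty(0),
        states=np.array(scheme.state_names, dtype=object)[states] if n_events else None,
        source="simulated",
        meta={"scheme": scheme.name},
    )


def simulate_class_events(
    scheme: GatingScheme,
    n_class_events: int,
    seed: int | np.random.Generator,
    initial: str | None = None,
) -> IdealizedRecord:
    """Simulate until at least ``n_class_events`` class-level events exist,
    returning the class-merged record (trimmed to exactly that many)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # states-per-class-event ratio estimated cheaply from a pilot chunk
    chunk = max(4 * n_class_events, 1000)
    parts = simulate_dwells(scheme, chunk, rng, initial=initial)
    merged = parts.merge_to_classes()
    while merged.n_events < n_class_events:
        more = simulate_dwells(scheme, chunk, rng, initial=str(parts.states[-1]))
        # drop the duplicated initial sojourn start: just concatenate raw events
        parts = IdealizedRecord(
            classes=np.concatenate([parts.classes, more.classes]),
            durations_ms=np.concatenate([parts.durations_ms, more.durations_ms]),
            amplitudes_pA=np.concatenate([parts.amplitudes_pA, more.amplitudes_pA]),
            states=np.concatenate([parts.states, more.states]),
            source="simulated",
            meta=parts.meta,
        )
        merged = parts.merge_to_classes()
    return IdealizedRecord(
        classes=merged.classes[:n_class_events],
        durations_ms=merged.durations_ms[:n_class_events],
        amplitudes_pA=merged.amplitudes_pA[:n_class_events],
        states=None,
        source="simulated",
        meta=dict(merged.meta),
    )


def _bessel_sos(filter_cutoff: float, sampling_rate: float):
    """Digital 8-pole Bessel approximation, -3 dB at the cutoff."""
    return sps.bessel(8, filter_cutoff, fs=sampling_rate, norm="mag", output="sos")


def _filter_delay_samples(sos) -> int:
    """Integer group delay of the filter at low frequency."""
    delay = 0.0
    for section in sos:
        b, a = section[:3], section[3:]
        _, gd = sps.group_delay((b, a), w=[1e-4])
        delay += float(gd[0])
    return int(round(delay))


def _noise_power_gain(sos) -> float:
    """White-noise variance gain of the filter (sum of squared impulse response)."""
    impulse = np.zeros(4096)
    impulse[0] = 1.0
    h = sps.sosfilt(sos, impulse)
    return float(np.sum(h * h))


def render_trace(
    record: IdealizedRecord,
    amps: AmplitudeModel,
    sampling_rate: float = 20_000.0,
    noise_sd: float = 3.0,
    filter_cutoff: float | None = 5_000.0,
    seed: int | np.random.Generator = 0,
) -> Trace:
    """Render an event sequence as a sampled, filtered, noisy current trace.

    The noiseless level signal is integrated over each sample interval, so
    events shorter than one sample contribute their area to the overlapping
    sample (as an analog anti-alias filter would).  Gaussian noise is added
    before the filter and pre-scaled so that the post-filter RMS noise on
    the trace equals ``noise_sd`` -- or, when the amplitude model carries
    per-class noise, the class's own RMS at each point of the trace.  The
    filter's constant group delay is compensated so that rendered levels
    stay aligned with the event clock.
    """
    if record.n_events == 0:
        raise ValueError("record is empty; nothing to render")
    if filter_cutoff and sampling_rate <= 2.0 * filter_cutoff:
        raise ValueError("sampling_rate must exceed twice the filter cutoff (Nyquist)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    levels = np.array([amps.level(c) for c in record.classes])
    dur_s = record.durations_ms / MS_PER_S
    bounds = np.concatenate([[0.0], np.cumsum(dur_s)])
    cum_area = np.concatenate([[0.0], np.cumsum(levels * dur_s)])
    n = int(np.floor(bounds[-1] * sampling_rate))
    if n == 0:
        raise ValueError("record shorter than one sample at this sampling rate")
    edges = np.arange(n + 1) / sampling_rate
    area_at_edges = np.interp(edges, bounds, cum_area)
    clean = np.diff(area_at_edges) * sampling_rate

    # per-sample noise SD: uniform, or the class of the event under each sample
    if isinstance(amps.noise_sd, dict) and amps.noise_sd:
        sd_by_event = np.array([amps.noise_of(c, noise_sd) for c in record.classes])
        centers = (np.arange(n) + 0.5) / sampling_rate
        ev = np.clip(np.searchsorted(bounds, centers, side="right") - 1, 0, len(sd_by_event) - 1)
        sample_sd = sd_by_event[ev]
    else:
        sample_sd = np.full(n, float(noise_sd))

    if filter_cutoff:
        sos = _bessel_sos(filter_cutoff, sampling_rate)
        gain = _noise_power_gain(sos)
        x = clean + rng.normal(0.0, 1.0, size=n) * (sample_sd / np.sqrt(gain))
        delay = _filter_delay_samples(sos)
        pad = max(8 * delay, 64)
        padded = np.concatenate([np.full(pad, x[0]), x, np.full(delay, x[-1])])
        y = sps.sosfilt(sos, padded)
        out = y[pad + delay : pad + delay + n]
    else:
        out = clean + rng.normal(0.0, 1.0, size=n) * sample_sd

    return Trace(
        samples=out,
        sampling_rate=sampling_rate,
        filter_cutoff=filter_cutoff,
        noise_sd=noise_sd,
        holding_potential_mV=record.holding_potential_mV,
        meta={"source": "render_trace", **record.meta},
    )


def _retune_po(scheme: GatingScheme, po_target: float) -> GatingScheme:
    """Scale the blocked->closed branching to move equilibrium Po toward a
    target; used by the block presets to emulate channels at different
    activation levels."""
    from scipy.optimize import brentq

    from .schemes import analytic_open_probability

    base = scheme.rates.copy()
    closed_idx = scheme.class_indices("CLOSED")

    def po_of(log_f: float) -> float:
        f = np.exp(log_f)
        rates = base.copy()
        rates[:, closed_idx] *= f  # entries into closed states
        rates[closed_idx, :] /= f  # exits from closed states
        return analytic_open_probability(scheme.with_rates(rates))

    lo, hi = -4.0, 4.0
    target = np.clip(po_target, 1e-3, 0.999)
    f_lo, f_hi = po_of(lo) - target, po_of(hi) - target
    if f_lo * f_hi > 0:
        warnings.warn("po_target unreachable by closed-branch scaling; using preset rates")
        return scheme
    log_f = brentq(lambda lf: po_of(lf) - target, lo, hi, xtol=1e-6)
    f = np.exp(log_f)
    rates = base.copy()
    rates[:, closed_idx] *= f
    rates[closed_idx, :] /= f
    return scheme.with_rates(rates)


def make_block_recording(
    preset: str,
    duration_s: float,
    seed: int | np.random.Generator,
    po_target: float | None = None,
    sampling_rate: float = 20_000.0,
    filter_cutoff: float | None = 5_000.0,
    noise_sd: float | None = None,
    baseline_noise_sd: float = 1.5,
    open_amplitude: float = 30.0,
) -> tuple[Trace, IdealizedRecord]:
    """Simulated blocker recording from the 'TBA' or 'TPeA' preset.

    Returns the rendered trace together with the ground-truth event record
    (for recovery tests).  The blocked level sits at 20% (TBA) or 14% (TPeA)
    of the open amplitude; metadata records the nominal blocker
    concentration and the +40 mV holding potential.  ``noise_sd`` is the
    open-level RMS noise and defaults to SNR ~ 10 there;
    ``baseline_noise_sd`` is the quieter closed-level RMS (open-channel
    noise exceeds baseline noise), with blocked levels interpolated by
    conductance.  ``duration_s`` of zero yields an empty trace and record.
    """
    if preset not in fixtures.BLOCK_PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(fixtures.BLOCK_PRESETS)}")
    cfg = fixtures.BLOCK_PRESETS[preset]
    scheme: GatingScheme = cfg["scheme"]()
    if po_target is not None:
        scheme = _retune_po(scheme, po_target)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_sd is None:
        noise_sd = open_amplitude / 10.0

    meta = {
        "blocker": preset,
        "concentration_molar": cfg["concentration_molar"],
        "scheme": scheme.name,
    }
    if duration_s <= 0:
        empty = IdealizedRecord(
            classes=np.empty(0, dtype=object),
            durations_ms=np.empty(0),
            amplitudes_pA=np.empty(0),
            holding_potential_mV=cfg["holding_potential_mV"],
            meta=meta,
        )
        trace = Trace(
            samples=np.empty(0),
            sampling_rate=sampling_rate,
            filter_cutoff=filter_cutoff,
            noise_sd=noise_sd,
            holding_potential_mV=cfg["holding_potential_mV"],
            meta=meta,
        )
        return trace, empty

    # simulate in chunks until the requested duration is covered
    target_ms = duration_s * MS_PER_S
    mean_event_ms = None
    record = simulate_dwells(scheme, 2000, rng)
    while record.total_duration_ms < target_ms:
        mean_event_ms = record.total_duration_ms / record.n_events
        need = int(1.2 * (target_ms - record.total_duration_ms) / mean_event_ms) + 100
        more = simulate_dwells(scheme, need, rng, initial=str(record.states[-1]))
        record = IdealizedRecord(
            classes=np.concatenate([record.classes, more.classes]),
            durations_ms=np.concatenate([record.durations_ms, more.durations_ms]),
            amplitudes_pA=np.concatenate([record.amplitudes_pA, more.amplitudes_pA]),
            states=np.concatenate([record.states, more.states]),
            meta=meta,
        )
    # trim to the requested duration
    cum = np.cumsum(record.durations_ms)
    keep = int(np.searchsorted(cum, target_ms, side="right") + 1)
    keep = min(keep, record.n_events)
    truth = IdealizedRecord(
        classes=record.classes[:keep],
        durations_ms=record.durations_ms[:keep],
        amplitudes_pA=record.amplitudes_pA[:keep] * open_amplitude,
        states=record.states[:keep],
        sampling_rate=sampling_rate,
        holding_potential_mV=cfg["holding_potential_mV"],
        meta=meta,
    ).merge_to_classes()

    if noise_sd > 0:
        amps = AmplitudeModel.for_scheme(
            scheme,
            open_amplitude=open_amplitude,
            baseline_noise_sd=baseline_noise_sd,
            open_noise_sd=noise_sd,
        )
    else:  # noiseless request: no per-class noise either
        amps = AmplitudeModel.for_scheme(scheme, open_amplitude=open_amplitude)
    trace = render_trace(
        truth,
        amps,
        sampling_rate=sampling_rate,
        noise_sd=noise_sd,
        filter_cutoff=filter_cutoff,
        seed=rng,
    )
    trace.holding_potential_mV = cfg["holding_potential_mV"]
    trace.meta.update(meta)
    return trace, truth
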