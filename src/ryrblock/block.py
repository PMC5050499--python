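"""Blocker statistics: block kinetics, fractional conductance, and the
Pb-versus-Po regression.

Open-channel block by a quaternary ammonium cation at concentration [B] is
treated as pseudo-first-order: the blocking rate from the open state is
k_on [B] and the dissociation rate k_off is the reciprocal mean blocked
dwell.  The probability of block Pb measured at positive potentials is
regressed on the open probability Po of the same channel at the mirrored
negative potential (where no block occurs); a linear fit whose extrapolated
y-intercept is credibly positive indicates that a closed conformation of
the channel can still be blocked -- evidence for a second gate distal to
the blocker site.

The module also provides labelled *synthetic mechanism fixtures* for that
argument: a two-gate scheme in which the blocker can bind while the
ligand-operated gate is open but the distal (selectivity-filter) gate is
closed, and a pure open-block control.  Their rates are illustrative
constructions, not experimental estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from . import dwell_fit
from .schemes import GatingScheme, analytic_open_probability, build_scheme
from .synth import IdealizedRecord, simulate_class_events

MS = 1e-3

__all__ = [
    "BlockKinetics",
    "PbPoRegression",
    "estimate_block_kinetics",
    "fractional_conductance",
    "pb_po_regression",
    "two_gate_scheme",
    "open_block_scheme",
    "simulate_pb_po_points",
]


class BlockAnalysisError(ValueError):
    pass


@dataclass
class BlockKinetics:
    """Pseudo-first-order block kinetics from an idealized record."""

    k_off_per_s: float
    k_on_per_M_s: float | None
    K_D_molar: float | None
    tau_blocked_ms: dict[str, float]  # per blocked component, e.g. {"B1": .., "B2": ..}
    blocker_concentration_molar: float | None
    fractional_conductance: float
    n_blocked_events: int

    def __post_init__(self) -> None:
        if self.k_off_per_s <= 0:
            raise BlockAnalysisError("k_off must be positive")


@dataclass
class PbPoRegression:
    points: list[tuple[float, float, float]]  # (Po at -V, Pb at +V, holding mV)
    slope: float
    intercept: float
    intercept_ci: tuple[float, float]
    r_squared: float
    closed_state_block_indicated: bool
    n_bootstrap: int


def fractional_conductance(
    record_or_pairs: IdealizedRecord | tuple[float, float],
) -> tuple[float, float]:
    """Blocked/open mean-amplitude ratio with a standard error.

    Accepts an idealized record (uses the edge-trimmed class amplitudes
    estimated during idealization when available, else duration-weighted
    event amplitudes) or an explicit ``(blocked_amplitude, open_amplitude)``
    pair (SE zero).
    """
    if isinstance(record_or_pairs, tuple):
        b, o = record_or_pairs
        if o == 0:
            raise BlockAnalysisError("open amplitude is zero")
        return b / o, 0.0
    record = record_or_pairs
    amp_meta = record.meta.get("class_amplitude_pA", {})
    if "BLOCKED" in amp_meta and "OPEN" in amp_meta and np.isfinite(amp_meta["BLOCKED"]):
        b, o = float(amp_meta["BLOCKED"]), float(amp_meta["OPEN"])
        ns = record.meta.get("class_amplitude_n_samples", {})
        sds = record.meta.get("skm_class_sd_pA")
        if sds is not None and ns.get("BLOCKED") and ns.get("OPEN"):
            se_b = max(sds) / np.sqrt(ns["BLOCKED"])
            se_o = max(sds) / np.sqrt(ns["OPEN"])
            se = abs(b / o) * np.sqrt((se_b / b) ** 2 + (se_o / o) ** 2)
        else:
            se = float("nan")
        return b / o, se
    for lbl in ("BLOCKED", "OPEN"):
        if not (record.classes == lbl).any():
            raise BlockAnalysisError(f"record has no {lbl} events")
    vals = {}
    ses = {}
    for lbl in ("BLOCKED", "OPEN"):
        sel = record.classes == lbl
        w = record.durations_ms[sel]
        a = record.amplitudes_pA[sel]
        m = float(np.sum(a * w) / w.sum())
        vals[lbl] = m
        ses[lbl] = float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0
    f = vals["BLOCKED"] / vals["OPEN"]
    se = abs(f) * np.sqrt(
        (ses["BLOCKED"] / vals["BLOCKED"]) ** 2 + (ses["OPEN"] / vals["OPEN"]) ** 2
    )
    return f, se


def estimate_block_kinetics(
    record: IdealizedRecord,
    concentration_molar: float | None = None,
    split_blocked_states: bool = True,
) -> BlockKinetics:
    """Block kinetics from an idealized record.

    k_off is the reciprocal mean blocked dwell (per second); when the
    blocked dwell distribution supports two components and
    ``split_blocked_states`` is set, per-state lifetimes are reported from
    a two-component truncated mixture fit (B1 = brief, B2 = long).  k_on is
    the open-to-blocked transition rate divided by the blocker
    concentration; without a concentration only k_off is reported.
    """
    blocked = record.durations_of("BLOCKED")
    if blocked.size == 0:
        raise BlockAnalysisError("record has no blocked events")
    mean_blocked_s = blocked.mean() * MS
    k_off = 1.0 / mean_blocked_s

    taus: dict[str, float] = {}
    if split_blocked_states and blocked.size >= 50:
        try:
            fit = dwell_fit.fit_mixture(
                blocked, 2, dead_time_ms=record.dead_time_ms, starts=4
            )
            taus = {"B1": fit.components[0][0], "B2": fit.components[1][0]}
        except dwell_fit.DwellFitError:
            taus = {}
    if not taus:
        taus = {"B": blocked.mean()}

    cls = record.classes
    open_time_s = record.durations_of("OPEN").sum() * MS
    n_ob = int(np.sum((cls[:-1] == "OPEN") & (cls[1:] == "BLOCKED")))
    k_on = None
    kd = None
    if concentration_molar is not None and open_time_s > 0:
        if concentration_molar <= 0:
            raise BlockAnalysisError("concentration must be positive")
        blocking_rate = n_ob / open_time_s  # s^-1 from the open state
        k_on = blocking_rate / concentration_molar
        kd = k_off / k_on if k_on > 0 else None

    try:
        frac, _ = fractional_conductance(record)
    except BlockAnalysisError:
        frac = float("nan")

    return BlockKinetics(
        k_off_per_s=k_off,
        k_on_per_M_s=k_on,
        K_D_molar=kd,
        tau_blocked_ms=taus,
        blocker_concentration_molar=concentration_molar,
        fractional_conductance=frac,
        n_blocked_events=int(blocked.size),
    )


def pb_po_regression(
    points: list[tuple[float, float, float]],
    n_bootstrap: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PbPoRegression:
    """Ordinary least squares of Pb (at +V) on Po (at the mirrored -V).

    ``points`` are ``(Po, Pb, holding_potential_mV)`` triples from paired
    recordings of the same channel.  The intercept confidence interval is a
    seeded bootstrap over points (percentile, ``1 - alpha``); the
    closed-state-block flag is raised when the whole interval lies above
    zero -- the operational signature that block persists as open access
    vanishes.
    """
    if len(points) < 3:
        raise BlockAnalysisError("need at least 3 (Po, Pb) points")
    po = np.array([p[0] for p in points], dtype=float)
    pb = np.array([p[1] for p in points], dtype=float)
    if np.any((po < 0) | (po > 1) | (pb < 0) | (pb > 1)):
        raise BlockAnalysisError("Po and Pb must lie in [0, 1]")
    if np.ptp(po) < 1e-12:
        raise BlockAnalysisError("degenerate regression: Po has no variance")

    X = sm.add_constant(po)
    fit = sm.OLS(pb, X).fit()
    intercept, slope = fit.params

    rng = np.random.default_rng(seed)
    n = po.size
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        if np.ptp(po[idx]) < 1e-12:
            boot[b] = np.nan
            continue
        Xb = sm.add_constant(po[idx])
        boot[b] = sm.OLS(pb[idx], Xb).fit().params[0]
    boot = boot[np.isfinite(boot)]
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])

    return PbPoRegression(
        points=list(points),
        slope=float(slope),
        intercept=float(intercept),
        intercept_ci=(float(lo), float(hi)),
        r_squared=float(fit.rsquared),
        closed_state_block_indicated=bool(lo > 0.0),
        n_bootstrap=int(len(boot)),
    )


# --------------------------------------------------------------------------
# synthetic mechanism fixtures (illustrative constructions, not data)
# --------------------------------------------------------------------------

_GATING = dict(k_ac=100.0, k_ao=2857.0, k_oa=500.0)


def _gating_states():
    return [
        {"name": "C", "class": "CLOSED"},  # ligand gate (IHBx) shut
        {"name": "A", "class": "CLOSED"},  # ligand gate open, distal (SF) gate shut
        {"name": "O", "class": "OPEN"},
    ]


def _gating_rates(activation: float):
    g = _GATING
    return [
        {"from": "C", "to": "A", "rate": activation},
        {"from": "A", "to": "C", "rate": g["k_ac"]},
        {"from": "A", "to": "O", "rate": g["k_ao"]},
        {"from": "O", "to": "A", "rate": g["k_oa"]},
    ]


def unblocked_gating_scheme(activation: float) -> GatingScheme:
    """Three-state two-gate scheme without blocker (negative-potential
    control): ligand gate C <-> A driven by ``activation``, distal gate
    A <-> O flickering fast."""
    return build_scheme(
        {"name": "two_gate_unblocked", "states": _gating_states(),
         "rates": _gating_rates(activation)}
    )


def two_gate_scheme(activation: float) -> GatingScheme:
    """SYNTHETIC six-state two-gate block mechanism.

    The blocker binds from the cytosolic side whenever the ligand gate is
    open: from the open state (O -> BO) and -- crucially -- from the
    distal-gate-closed state (A -> BA, weaker access).  BT is a trapped
    configuration: the ligand gate has shut on the bound blocker (at its
    usual closing rate) and releases it only when the gate reopens (at the
    activation rate).  Trapping makes the blocked occupancy persist as the
    ligand-driven open access is extrapolated away, so Pb retains a
    positive floor at Po -> 0.
    """
    states = _gating_states() + [
        {"name": "BO", "class": "BLOCKED", "conductance": 0.14},
        {"name": "BA", "class": "BLOCKED", "conductance": 0.14},
        {"name": "BT", "class": "BLOCKED", "conductance": 0.14},
    ]
    g = _GATING
    rates = _gating_rates(activation) + [
        {"from": "O", "to": "BO", "rate": 300.0},
        {"from": "BO", "to": "O", "rate": 500.0},
        {"from": "A", "to": "BA", "rate": 40.0},
        {"from": "BA", "to": "A", "rate": 500.0},
        {"from": "BO", "to": "BA", "rate": g["k_oa"]},
        {"from": "BA", "to": "BO", "rate": g["k_ao"]},
        {"from": "BA", "to": "BT", "rate": g["k_ac"]},
        {"from": "BT", "to": "BA", "rate": activation},
    ]
    return build_scheme({"name": "two_gate_block", "states": states, "rates": rates})


def open_block_scheme(activation: float) -> GatingScheme:
    """SYNTHETIC pure open-block control: binding only from the open state,
    in the weak-binding (linear pseudo-first-order) regime, so Pb is
    proportional to open access and the extrapolated intercept is zero."""
    states = _gating_states() + [
        {"name": "BO", "class": "BLOCKED", "conductance": 0.14},
    ]
    rates = _gating_rates(activation) + [
        {"from": "O", "to": "BO", "rate": 40.0},
        {"from": "BO", "to": "O", "rate": 1500.0},
    ]
    return build_scheme({"name": "open_block", "states": states, "rates": rates})


def simulate_pb_po_points(
    mechanism: str,
    seed: int,
    activations: tuple[float, ...] = (
        3.0, 4.0, 5.0, 8.0, 12.0, 20.0, 30.0, 50.0, 80.0, 150.0, 300.0, 800.0,
    ),
    n_events: int = 10_000,
    holding_mV: float = 40.0,
) -> list[tuple[float, float, float]]:
    """Paired (Po, Pb) points over a range of ligand activation.

    For each activation level, Po is measured from a simulated recording of
    the unblocked scheme (negative potential) and Pb from the corresponding
    blocked mechanism ('two-gate' or 'open-block') at the mirrored positive
    potential, both as time fractions of ``n_events``-event records.
    """
    builders = {"two-gate": two_gate_scheme, "open-block": open_block_scheme}
    if mechanism not in builders:
        raise BlockAnalysisError(f"unknown mechanism {mechanism!r}")
    rng = np.random.default_rng(seed)
    points = []
    for act in activations:
        rec_u = simulate_class_events(unblocked_gating_scheme(act), n_events, rng)
        rec_b = simulate_class_events(builders[mechanism](act), n_events, rng)
        po = rec_u.durations_of("OPEN").sum() / rec_u.total_duration_ms
        pb = rec_b.durations_of("BLOCKED").sum() / rec_b.total_duration_ms
        points.append((float(po), float(pb), holding_mV))
    return points
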