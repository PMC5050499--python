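"""Aggregated Markov gating schemes and their analytic kinetic properties.

A single ion channel is modelled as a continuous-time Markov chain whose
states are grouped into conductance classes -- CLOSED (zero current), OPEN
(full current) and BLOCKED (a subconductance level produced by a bound pore
blocker).  Only the class of the occupied state is observable in a current
recording, which makes the chain an *aggregated* Markov model: many schemes
with different internal topology can produce the same marginal behaviour,
and dwell times within a class follow phase-type (mixture-of-exponential)
distributions determined by the within-class generator submatrix.

This module holds the scheme container, its generator matrix, equilibrium
occupancies, the open/blocked probability, and the analytic decomposition of
class dwell densities into exponential components (tau, area) -- the ground
truth that dwell-time histogram fitting estimates from data.

Units: rate constants are stored in s^-1; dwell time constants are reported
in ms (the conventional reporting unit of single-channel work).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

CLOSED = "CLOSED"
OPEN = "OPEN"
BLOCKED = "BLOCKED"
_CLASS_LABELS = (CLOSED, OPEN, BLOCKED)

MS_PER_S = 1e3


class SchemeValidationError(ValueError):
    """Raised when a gating-scheme definition violates its invariants."""


@dataclass(frozen=True)
class StateClass:
    """Conductance class of a state.

    ``conductance_fraction`` is the fraction of the fully open single-channel
    amplitude carried in this class: 0 for CLOSED, 1 for OPEN and strictly
    between 0 and 1 for BLOCKED (a partially occluded pore still passes a
    residual current, e.g. ~0.20 for TBA and ~0.14 for TPeA block of RyR2).
    """

    label: str
    conductance_fraction: float

    def __post_init__(self) -> None:
        if self.label not in _CLASS_LABELS:
            raise SchemeValidationError(f"unknown class label {self.label!r}")
        f = float(self.conductance_fraction)
        if self.label == CLOSED and f != 0.0:
            raise SchemeValidationError("CLOSED states must have conductance_fraction 0")
        if self.label == OPEN and f != 1.0:
            raise SchemeValidationError("OPEN states must have conductance_fraction 1")
        if self.label == BLOCKED and not 0.0 < f < 1.0:
            raise SchemeValidationError(
                "BLOCKED states need a conductance_fraction strictly between 0 and 1"
            )


@dataclass(frozen=True)
class DwellComponents:
    """Exponential components of a class dwell-time density.

    ``components`` is a list of ``(tau_ms, area)`` pairs sorted by tau; areas
    are event fractions and sum to one.  This mirrors the tau/Amp inset
    tables of published dwell-time fits.
    """

    components: tuple[tuple[float, float], ...]
    class_label: str

    @property
    def taus_ms(self) -> np.ndarray:
        return np.array([t for t, _ in self.components])

    @property
    def areas(self) -> np.ndarray:
        return np.array([a for _, a in self.components])

    @property
    def mean_ms(self) -> float:
        """Mean class dwell, sum(area * tau)."""
        return float(np.sum(self.taus_ms * self.areas))

    def density(self, t_ms: np.ndarray) -> np.ndarray:
        """Mixture pdf evaluated at ``t_ms`` (per ms)."""
        t = np.asarray(t_ms, dtype=float)[..., None]
        tau = self.taus_ms
        return np.sum(self.areas / tau * np.exp(-t / tau), axis=-1)


@dataclass
class GatingScheme:
    """A validated aggregated Markov gating scheme.

    ``rates`` holds k_ij in s^-1 for the transition i -> j, zero exactly off
    the connectivity set.  The scheme must contain at least one CLOSED and
    one OPEN state and be irreducible (every state reachable from every
    other through allowed transitions).
    """

    name: str
    state_names: tuple[str, ...]
    state_class: dict[str, StateClass]
    rates: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def index(self, state: str) -> int:
        return self.state_names.index(state)

    def class_of(self, state: str) -> str:
        return self.state_class[state].label

    @property
    def class_labels(self) -> tuple[str, ...]:
        """Class labels present, in canonical CLOSED, OPEN, BLOCKED order."""
        present = {sc.label for sc in self.state_class.values()}
        return tuple(lbl for lbl in _CLASS_LABELS if lbl in present)

    def states_in_class(self, class_label: str) -> list[str]:
        return [s for s in self.state_names if self.class_of(s) == class_label]

    def class_indices(self, class_label: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.state_names) if self.class_of(s) == class_label],
            dtype=int,
        )

    def conductance_fraction(self, class_label: str) -> float:
        for sc in self.state_class.values():
            if sc.label == class_label:
                return sc.conductance_fraction
        raise KeyError(class_label)

    @property
    def connectivity(self) -> set[tuple[str, str]]:
        edges = set()
        for i, si in enumerate(self.state_names):
            for j, sj in enumerate(self.state_names):
                if i != j and self.rates[i, j] > 0:
                    edges.add((si, sj))
        return edges

    def with_rates(self, rates: np.ndarray, name: str | None = None) -> "GatingScheme":
        """Copy of this scheme with new rate values on the same states."""
        return build_scheme(
            {
                "name": name or self.name,
                "states": [
                    {
                        "name": s,
                        "class": self.state_class[s].label,
                        "conductance": self.state_class[s].conductance_fraction,
                    }
                    for s in self.state_names
                ],
                "rates": [
                    {"from": si, "to": sj, "rate": float(rates[i, j])}
                    for i, si in enumerate(self.state_names)
                    for j, sj in enumerate(self.state_names)
                    if i != j and rates[i, j] > 0
                ],
            }
        )

    def to_definition(self) -> dict:
        """Structured definition that round-trips through build_scheme."""
        return {
            "name": self.name,
            "states": [
                {
                    "name": s,
                    "class": self.state_class[s].label,
                    "conductance": self.state_class[s].conductance_fraction,
                }
                for s in self.state_names
            ],
            "rates": [
                {"from": si, "to": sj, "rate": float(self.rates[i, j])}
                for i, si in enumerate(self.state_names)
                for j, sj in enumerate(self.state_names)
                if i != j and self.rates[i, j] > 0
            ],
        }


def build_scheme(definition: dict) -> GatingScheme:
    """Build and validate a GatingScheme from a structured definition.

    ``definition`` is a mapping with keys

    - ``states``: list of ``{"name", "class", "conductance"(optional)}``
    - ``rates``: list of ``{"from", "to", "rate"}`` with rate in s^-1
    - ``name`` (optional)

    Conductance defaults to 0 for CLOSED and 1 for OPEN; BLOCKED states must
    state theirs.  Raises :class:`SchemeValidationError` for negative rates,
    references to undefined states, missing CLOSED/OPEN representation, or a
    disconnected state graph (the error names an unreachable state).
    """
    states = definition.get("states", [])
    if len(states) < 1:
        raise SchemeValidationError("definition must name at least one state")
    names: list[str] = []
    classes: dict[str, StateClass] = {}
    for s in states:
        nm = str(s["name"])
        if nm in classes:
            raise SchemeValidationError(f"duplicate state name {nm!r}")
        label = str(s["class"]).upper()
        default = {CLOSED: 0.0, OPEN: 1.0}.get(label)
        cond = s.get("conductance", default)
        if cond is None:
            raise SchemeValidationError(f"BLOCKED state {nm!r} must state its conductance")
        classes[nm] = StateClass(label, float(cond))
        names.append(nm)

    n = len(names)
    rates = np.zeros((n, n))
    idx = {nm: i for i, nm in enumerate(names)}
    for r in definition.get("rates", []):
        a, b = str(r["from"]), str(r["to"])
        for nm in (a, b):
            if nm not in idx:
                raise SchemeValidationError(f"rate references undefined state {nm!r}")
        if a == b:
            raise SchemeValidationError(f"self-transition {a!r} is not allowed")
        k = float(r["rate"])
        if k < 0:
            raise SchemeValidationError(f"negative rate {a}->{b}: {k}")
        rates[idx[a], idx[b]] = k

    labels = {sc.label for sc in classes.values()}
    if n >= 2 and (CLOSED not in labels or OPEN not in labels):
        raise SchemeValidationError("scheme needs at least one CLOSED and one OPEN state")

    scheme = GatingScheme(
        name=str(definition.get("name", "scheme")),
        state_names=tuple(names),
        state_class=classes,
        rates=rates,
    )
    if n > 1:
        _check_irreducible(scheme)
    return scheme


def _check_irreducible(scheme: GatingScheme) -> None:
    """Every state must be reachable from every other along positive rates."""
    n = scheme.n_states
    adj = scheme.rates > 0
    # reachability by repeated squaring of the boolean adjacency
    reach = adj | np.eye(n, dtype=bool)
    for _ in range(int(np.ceil(np.log2(max(n, 2))))):
        reach = reach @ reach
    if not reach.all():
        bad = np.argwhere(~reach)[0]
        src, dst = scheme.state_names[bad[0]], scheme.state_names[bad[1]]
        raise SchemeValidationError(
            f"scheme is not irreducible: state {dst!r} unreachable from {src!r}"
        )


def generator_matrix(scheme: GatingScheme) -> np.ndarray:
    """Infinitesimal generator Q (s^-1): off-diagonals k_ij, rows sum to zero."""
    Q = scheme.rates.astype(float).copy()
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def equilibrium_occupancy(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi Q = 0 and sum(pi) = 1.

    Solved as the null space of Q^T with the normalisation appended; raises
    for a reducible generator (null space dimension != 1).
    """
    Q = np.asarray(Q, dtype=float)
    n = Q.shape[0]
    if n == 1:
        return np.array([1.0])
    # null space via SVD for robustness
    u, s, vt = np.linalg.svd(Q.T)
    tol = max(Q.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    null_dim = int(np.sum(s <= max(tol, 1e-12 * max(s[0], 1.0))))
    if null_dim != 1:
        raise SchemeValidationError(
            f"generator is reducible (null-space dimension {null_dim})"
        )
    pi = vt[-1, :]
    pi = pi / pi.sum()
    if np.any(pi <= 0):
        raise SchemeValidationError("stationary distribution has non-positive entries")
    return pi


def class_occupancies(scheme: GatingScheme) -> dict[str, float]:
    """Equilibrium time fraction spent in each conductance class."""
    pi = equilibrium_occupancy(generator_matrix(scheme))
    out: dict[str, float] = {}
    for lbl in scheme.class_labels:
        out[lbl] = float(pi[scheme.class_indices(lbl)].sum())
    return out


def analytic_open_probability(scheme: GatingScheme, per_class: bool = False):
    """Equilibrium open probability Po (and optionally P per class).

    Po is the summed stationary occupancy of OPEN states; with
    ``per_class=True`` returns the dict of class occupancies, which sums to
    one over the classes present.
    """
    occ = class_occupancies(scheme)
    if per_class:
        return occ
    return occ.get(OPEN, 0.0)


def _class_entry_vector(scheme: GatingScheme, class_label: str) -> np.ndarray:
    """Equilibrium entry distribution phi over the states of a class.

    phi_j is proportional to the total stationary probability flux entering
    state j of the class from outside the class -- the distribution of the
    state in which a class sojourn starts under stationary recording.
    """
    Q = generator_matrix(scheme)
    pi = equilibrium_occupancy(Q)
    a = scheme.class_indices(class_label)
    outside = np.array([i for i in range(scheme.n_states) if i not in a], dtype=int)
    if outside.size == 0:
        raise SchemeValidationError(
            f"class {class_label!r} covers the whole scheme; dwells are unbounded"
        )
    flux = pi[outside] @ Q[np.ix_(outside, a)]
    total = flux.sum()
    if total <= 0:
        raise SchemeValidationError(f"no probability flux enters class {class_label!r}")
    return flux / total


def class_dwell_components(scheme: GatingScheme, class_label: str) -> DwellComponents:
    """Analytic phase-type dwell components of a conductance class.

    The sojourn-time density in class A is f(t) = phi exp(Q_AA t)(-Q_AA) 1
    with Q_AA the within-class generator submatrix and phi the equilibrium
    entry distribution.  When Q_AA has real negative eigenvalues the density
    is a mixture of exponentials with tau_m = -1/lambda_m and areas from the
    spectral projection of phi; complex eigenvalues (possible for cyclic
    schemes violating detailed balance) trigger a warning and the areas are
    taken from the real part of the projections.
    """
    a = scheme.class_indices(class_label)
    if a.size == 0:
        raise SchemeValidationError(f"scheme has no state in class {class_label!r}")
    Q = generator_matrix(scheme)
    Qaa = Q[np.ix_(a, a)]
    phi = _class_entry_vector(scheme, class_label)
    exit_rates = -Qaa @ np.ones(a.size)  # rate of leaving the class from each state

    lam, V = np.linalg.eig(Qaa)
    if np.any(lam.real >= 0):
        raise SchemeValidationError(f"class {class_label!r} has a non-exiting mode")
    complex_modes = np.any(np.abs(lam.imag) > 1e-9 * np.abs(lam.real))
    if complex_modes:
        warnings.warn(
            f"class {class_label!r} dwell density has complex eigenmodes; "
            "reporting real parts -- use DwellComponents.density with care",
            RuntimeWarning,
            stacklevel=2,
        )
    Vinv = np.linalg.inv(V)
    # f(t) = sum_m  (phi v_m)(w_m e) e^{lam_m t}; area_m = -(phi v_m)(w_m e)/lam_m
    comps = []
    for m in range(a.size):
        coeff = (phi @ V[:, m]) * (Vinv[m, :] @ exit_rates)
        area = float((-coeff / lam[m]).real)
        tau_ms = float((-1.0 / lam[m]).real) * MS_PER_S
        comps.append((tau_ms, area))
    # merge numerically degenerate eigenvalues, drop zero-area modes
    comps.sort(key=lambda c: c[0])
    merged: list[list[float]] = []
    for tau, area in comps:
        if merged and abs(tau - merged[-1][0]) <= 1e-9 * max(tau, merged[-1][0]):
            merged[-1][1] += area
        else:
            merged.append([tau, area])
    merged = [[t, ar] for t, ar in merged if abs(ar) > 1e-12]
    total = sum(ar for _, ar in merged)
    if not np.isclose(total, 1.0, atol=1e-6):
        raise SchemeValidationError(
            f"dwell component areas for {class_label!r} sum to {total:.6g}, not 1"
        )
    merged = [(t, ar / total) for t, ar in merged]
    return DwellComponents(components=tuple(merged), class_label=class_label)


def mean_class_dwell_ms(scheme: GatingScheme, class_label: str) -> float:
    """Mean class sojourn -phi Q_AA^{-1} 1, in ms (independent of the
    eigendecomposition; used to cross-check the component decomposition)."""
    a = scheme.class_indices(class_label)
    Q = generator_matrix(scheme)
    Qaa = Q[np.ix_(a, a)]
    phi = _class_entry_vector(scheme, class_label)
    return float(-phi @ np.linalg.solve(Qaa, np.ones(a.size))) * MS_PER_S
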