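"""Dwell-time histograms and dead-time-truncated exponential mixture fits.

Class dwell-time distributions of an aggregated Markov channel are mixtures
of exponentials.  Following standard practice the mixtures are fitted on the
raw durations by maximum likelihood -- histograms are presentation only --
with the likelihood left-truncated at the dead time, so that the estimated
component weights refer to the untruncated distribution (the differential
loss of brief events below the dead time is accounted for by the model).

Two systematic effects of finite time resolution are handled:

* **Truncation.**  Durations below the dead time never appear; each
  observation contributes f(t|theta)/S(t_d|theta).
* **Apparent prolongation.**  A sojourn in another class shorter than the
  dead time is invisible, so the two dwells of the fitted class flanking it
  coalesce into one long apparent dwell.  The first-order retrospective
  correction of classic single-channel analysis is provided: with p the
  probability that a dwell of class A is followed by an unresolved
  excursion returning to A, apparent lifetimes are deflated as
  tau = (1 - p) tau_app - p * m_gap, where m_gap is the mean unresolved gap.
  p and m_gap are computed from the fitted mixtures of the other classes
  and the observed class-transition frequencies.

For durations measured on a sample grid, :func:`effective_dead_time` gives
the half-sample-corrected truncation point to use in place of the nominal
dead time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .synth import IdealizedRecord

__all__ = [
    "DwellHistogram",
    "ExpMixtureFit",
    "histogram",
    "fit_mixture",
    "select_components",
    "effective_dead_time",
    "correct_apparent_lifetimes",
    "fit_record_classes",
]


class DwellFitError(RuntimeError):
    pass


@dataclass
class DwellHistogram:
    class_label: str
    bin_edges_ms: np.ndarray  # logarithmically spaced
    counts: np.ndarray
    transform: str = "log-binned"  # none | log-binned | sqrt (Sigworth-Sine ordinate)

    @property
    def ordinate(self) -> np.ndarray:
        if self.transform == "sqrt":
            return np.sqrt(self.counts)
        return self.counts.astype(float)


@dataclass
class ExpMixtureFit:
    """Exponential mixture fit: components (tau_ms, area) sorted by tau,
    areas summing to one (untruncated weights), with the dead time used for
    truncation, the attained log-likelihood and delta-method standard
    errors (same ordering as the components)."""

    components: tuple[tuple[float, float], ...]
    dead_time_ms: float
    log_likelihood: float
    n_events: int
    standard_errors: dict = field(default_factory=dict)
    class_label: str | None = None
    converged: bool = True

    @property
    def taus_ms(self) -> np.ndarray:
        return np.array([t for t, _ in self.components])

    @property
    def areas(self) -> np.ndarray:
        return np.array([a for _, a in self.components])

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def n_parameters(self) -> int:
        return 2 * self.k - 1

    def bic(self) -> float:
        return self.n_parameters * np.log(self.n_events) - 2.0 * self.log_likelihood

    def prob_below(self, t_ms: float) -> float:
        """Untruncated probability that a dwell is shorter than ``t_ms``."""
        return float(np.sum(self.areas * (1.0 - np.exp(-t_ms / self.taus_ms))))

    def mean_below(self, t_ms: float) -> float:
        """Mean dwell conditional on being shorter than ``t_ms``."""
        tau, w = self.taus_ms, self.areas
        f = 1.0 - np.exp(-t_ms / tau)
        num = np.sum(w * (tau * f - t_ms * np.exp(-t_ms / tau)))
        den = np.sum(w * f)
        return float(num / den) if den > 0 else 0.0

    def mean_ms(self) -> float:
        return float(np.sum(self.areas * self.taus_ms))


def effective_dead_time(dead_time_ms: float, sampling_rate: float | None) -> float:
    """Truncation point for grid-quantized durations.

    Durations from idealization are integer multiples of the sample
    interval; the shortest retained duration is ceil(t_d / dt) samples and
    corresponds to true durations from about half a sample less.  Returns
    the nominal dead time when no sampling rate is given.
    """
    if not sampling_rate:
        return dead_time_ms
    dt = 1e3 / sampling_rate
    n = int(np.ceil(dead_time_ms / dt - 1e-9))
    return max(n * dt - 0.5 * dt, 0.0)


def histogram(
    record: IdealizedRecord,
    class_label: str,
    bins_per_decade: int = 10,
    transform: str = "log-binned",
) -> DwellHistogram:
    """Log-binned dwell histogram for one class, spanning the dead time (or
    the shortest dwell) to the longest dwell."""
    if bins_per_decade <= 0:
        raise ValueError("bins_per_decade must be positive")
    d = record.durations_of(class_label)
    if d.size == 0:
        raise DwellFitError(f"no events of class {class_label!r}")
    lo = record.dead_time_ms if record.dead_time_ms > 0 else float(d.min())
    lo = min(lo, float(d.min()))
    hi = float(d.max())
    if hi <= lo:
        hi = lo * 1.01
    n_bins = max(int(np.ceil(np.log10(hi / lo) * bins_per_decade)), 1)
    edges = np.geomspace(lo, hi, n_bins + 1)
    edges[-1] *= 1 + 1e-12  # include the max dwell
    counts, _ = np.histogram(d, bins=edges)
    return DwellHistogram(class_label, edges, counts, transform)


def _nll_and_weights(theta: np.ndarray, t: np.ndarray, k: int, td: float):
    log_tau = theta[:k]
    tau = np.exp(log_tau)
    if k > 1:
        z = np.concatenate([theta[k:], [0.0]])
        z = z - z.max()
        w = np.exp(z)
        w = w / w.sum()
    else:
        w = np.ones(1)
    # log mixture density, stabilised
    log_dens = -t[:, None] / tau - log_tau
    m = log_dens.max(axis=1)
    dens = np.exp(log_dens - m[:, None]) @ w
    ll = np.sum(m + np.log(dens))
    surv = np.sum(w * np.exp(-td / tau))
    ll -= t.size * np.log(surv)
    return -ll, tau, w


def fit_mixture(
    durations_ms: np.ndarray,
    k: int,
    dead_time_ms: float = 0.0,
    starts: int = 8,
    seed: int = 0,
    class_label: str | None = None,
) -> ExpMixtureFit:
    """Maximum-likelihood left-truncated exponential mixture fit.

    Parameters are log time constants and softmax weights, optimized by
    L-BFGS-B from ``starts`` deterministic-plus-seeded initial points; the
    best optimum is returned.  All durations must be at or above the dead
    time.  Standard errors are delta-method transforms of the observed
    information (numerical Hessian).
    """
    t = np.asarray(durations_ms, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if t.size < 2 * k + 1:
        raise DwellFitError(f"{t.size} events cannot support a {k}-component fit")
    if np.any(t < dead_time_ms - 1e-12):
        raise DwellFitError("durations below the dead time are present")
    td = float(dead_time_ms)

    rng = np.random.default_rng(seed)
    mean_excess = max(t.mean() - td, 1e-6)
    inits = []
    qs = np.quantile(t - td + 1e-9, np.linspace(0.15, 0.95, k)) if k > 1 else [mean_excess]
    inits.append(np.concatenate([np.log(np.maximum(qs, 1e-6)), np.zeros(max(k - 1, 0))]))
    if k > 1:
        spread = mean_excess * np.geomspace(0.1, 10.0, k)
        inits.append(np.concatenate([np.log(spread), np.zeros(k - 1)]))
    while len(inits) < starts:
        base = np.log(mean_excess) + rng.normal(0, 1.5, size=k)
        inits.append(np.concatenate([np.sort(base), rng.normal(0, 0.5, size=max(k - 1, 0))]))

    best = None
    for x0 in inits[:starts]:
        res = minimize(
            lambda th: _nll_and_weights(th, t, k, td)[0],
            x0,
            method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None:
        raise DwellFitError("all optimizer starts failed")

    nll, tau, w = _nll_and_weights(best.x, t, k, td)
    order = np.argsort(tau)
    tau, w = tau[order], w[order]

    se = _delta_standard_errors(best.x, t, k, td, order)
    return ExpMixtureFit(
        components=tuple((float(ti), float(wi)) for ti, wi in zip(tau, w)),
        dead_time_ms=td,
        log_likelihood=float(-nll),
        n_events=int(t.size),
        standard_errors=se,
        class_label=class_label,
        converged=bool(best.success),
    )


def _delta_standard_errors(theta, t, k, td, order):
    """SEs of (tau, area) from the numerical observed information."""
    n_par = theta.size
    eps = 1e-4

    def nll(th):
        return _nll_and_weights(th, t, k, td)[0]

    H = np.zeros((n_par, n_par))
    f0 = nll(theta)
    for i in range(n_par):
        for j in range(i, n_par):
            ei = np.zeros(n_par); ei[i] = eps
            ej = np.zeros(n_par); ej[j] = eps
            H[i, j] = H[j, i] = (
                nll(theta + ei + ej) - nll(theta + ei) - nll(theta + ej) + f0
            ) / (eps * eps)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return {"tau_ms": [np.nan] * k, "area": [np.nan] * k}
    # Jacobians: d tau/d theta = tau on the log-tau block; areas via softmax
    _, tau, w = _nll_and_weights(theta, t, k, td)
    se_tau = np.sqrt(np.maximum(np.diag(cov)[:k], 0.0)) * tau
    if k > 1:
        J = np.zeros((k, k - 1))
        for m in range(k):
            for j in range(k - 1):
                J[m, j] = w[m] * ((1.0 if m == j else 0.0) - w[j])
        cov_w = J @ cov[k:, k:] @ J.T
        se_w = np.sqrt(np.maximum(np.diag(cov_w), 0.0))
    else:
        se_w = np.zeros(1)
    return {
        "tau_ms": se_tau[order].tolist(),
        "area": se_w[order].tolist(),
    }


def select_components(
    durations_ms: np.ndarray,
    max_k: int,
    dead_time_ms: float = 0.0,
    criterion: str = "bic",
    lrt_alpha: float = 0.05,
    **fit_kw,
) -> tuple[int, dict[int, ExpMixtureFit]]:
    """Fit k = 1..max_k mixtures and pick the best component count.

    Default criterion is BIC; ``criterion='lrt'`` adds components while the
    likelihood-ratio test against the simpler fit is significant.  Component
    counts the data cannot support (fewer than 2k+1 events) are skipped.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    t = np.asarray(durations_ms, dtype=float)
    fits: dict[int, ExpMixtureFit] = {}
    for k in range(1, max_k + 1):
        if t.size < 2 * k + 1:
            break
        fits[k] = fit_mixture(t, k, dead_time_ms, **fit_kw)
    if not fits:
        raise DwellFitError("no supportable component count")
    if criterion == "bic":
        best_k = min(fits, key=lambda k: fits[k].bic())
    elif criterion == "lrt":
        from scipy.stats import chi2

        best_k = 1
        for k in range(2, max(fits) + 1):
            stat = 2.0 * (fits[k].log_likelihood - fits[best_k].log_likelihood)
            df = fits[k].n_parameters - fits[best_k].n_parameters
            if stat > chi2.ppf(1.0 - lrt_alpha, df):
                best_k = k
            else:
                break
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return best_k, fits


def fit_with_artifact_screen(
    durations_ms: np.ndarray,
    k: int,
    dead_time_ms: float = 0.0,
    artifact_tau_max_ms: float | None = None,
    starts: int = 8,
    seed: int = 0,
    class_label: str | None = None,
) -> ExpMixtureFit:
    """Mixture fit with one extra component screening detection artifacts.

    Dwells of a class bounded by a *low-contrast* neighbouring level (for
    instance closings interrupting a subconductance blocked level) carry a
    contamination population of false events -- correlated-noise dips that
    segmentation cannot distinguish from real transitions -- concentrated
    just above the resolution limit.  This fit adds one component to absorb
    them: it fits k+1 components and, when the extra component's time
    constant falls below ``artifact_tau_max_ms`` (default twice the dead
    time, the conventional shortest trustworthy time constant), drops it
    and renormalises the remaining areas.  If no component falls below the
    threshold the plain k-component fit is returned.
    """
    if artifact_tau_max_ms is None:
        artifact_tau_max_ms = 2.0 * dead_time_ms
    t = np.asarray(durations_ms, dtype=float)
    plain = fit_mixture(t, k, dead_time_ms, starts=starts, seed=seed, class_label=class_label)
    if artifact_tau_max_ms <= dead_time_ms or t.size < 2 * (k + 1) + 1:
        return plain
    try:
        ext = fit_mixture(t, k + 1, dead_time_ms, starts=starts, seed=seed)
    except DwellFitError:
        return plain
    keep = [(tau, a) for tau, a in ext.components if tau >= artifact_tau_max_ms]
    if len(keep) != k:
        return plain
    art = [(tau, a) for tau, a in ext.components if tau < artifact_tau_max_ms]
    dropped = sum(a for _, a in art)
    total = sum(a for _, a in keep)
    comps = tuple((tau, a / total) for tau, a in keep)
    # expected number of *observed* artifact events, for downstream
    # corrections (each false event also split a dwell of the level it
    # interrupted): untruncated weights scaled by survival past the cut
    surv = {tau: np.exp(-ext.dead_time_ms / tau) for tau, _ in ext.components}
    denom = sum(a * surv[tau] for tau, a in ext.components)
    n_art = ext.n_events * sum(a * surv[tau] for tau, a in art) / denom
    return ExpMixtureFit(
        components=comps,
        dead_time_ms=ext.dead_time_ms,
        log_likelihood=ext.log_likelihood,
        n_events=ext.n_events,
        standard_errors={
            **plain.standard_errors,
            "artifact_area": float(dropped),
            "artifact_n_observed": float(n_art),
        },
        class_label=class_label,
        converged=ext.converged,
    )


def correct_false_event_splitting(
    fit: ExpMixtureFit, false_event_rate_per_s: float
) -> ExpMixtureFit:
    """Correct dwell time constants of a level that false events split.

    A false event occurring at rate lambda_f (per second of time spent at
    the level) cuts a sojourn in two, adding lambda_f to every apparent
    exit rate: the inverse correction is 1/tau = 1/tau_app - lambda_f,
    which only matters for components whose lifetime approaches
    1/lambda_f.  Components the correction cannot invert (apparent rate
    below lambda_f) are left unchanged.
    """
    if false_event_rate_per_s <= 0:
        return fit
    lam_ms = false_event_rate_per_s * 1e-3  # per ms
    comps = []
    for tau, a in fit.components:
        inv = 1.0 / tau - lam_ms
        comps.append((1.0 / inv if inv > 0.1 / tau else tau, a))
    return ExpMixtureFit(
        components=tuple(comps),
        dead_time_ms=fit.dead_time_ms,
        log_likelihood=fit.log_likelihood,
        n_events=fit.n_events,
        standard_errors={**fit.standard_errors, "false_event_rate_per_s": false_event_rate_per_s},
        class_label=fit.class_label,
        converged=fit.converged,
    )


def _transition_stats(record: IdealizedRecord) -> dict[tuple[str, str], float]:
    """Observed class-transition probabilities T[a -> b]."""
    cls = record.classes
    pairs: dict[tuple[str, str], int] = {}
    totals: dict[str, int] = {}
    for a, b in zip(cls[:-1], cls[1:]):
        pairs[(a, b)] = pairs.get((a, b), 0) + 1
        totals[a] = totals.get(a, 0) + 1
    return {ab: n / totals[ab[0]] for ab, n in pairs.items()}


def correct_apparent_lifetimes(
    fits: dict[str, ExpMixtureFit],
    record: IdealizedRecord,
    dead_time_ms: float,
) -> dict[str, ExpMixtureFit]:
    """First-order missed-event correction of apparent time constants.

    For each class A, the probability that an A dwell is merged with the
    next A dwell is p_A = sum_x T[A->x] F_{x|A}(t_d) T[x->A | after A]:
    T are observed class-transition probabilities, and F_{x|A} is the
    fitted untruncated probability that an x dwell *entered from A* is
    shorter than the dead time.  Conditioning the gap distribution on the
    preceding class matters in multi-class schemes, where the sojourns of a
    class reached from different neighbours come from different internal
    states (in a Markov chain, exit direction is independent of sojourn
    duration, so the observed-event estimates are unbiased).  Each apparent
    time constant is corrected as tau = (1 - p_A) tau_app - p_A m_gap with
    m_gap the mean unresolved gap; areas keep their truncated-fit values.
    """
    cls = record.classes
    dur = record.durations_ms
    prev_cls = np.concatenate([["__start__"], cls[:-1]])
    next_cls = np.concatenate([cls[1:], ["__end__"]])
    T = _transition_stats(record)
    out: dict[str, ExpMixtureFit] = {}
    for a, fit in fits.items():
        p = 0.0
        m_gap = 0.0
        for x, fx in fits.items():
            if x == a:
                continue
            t_ax = T.get((a, x), 0.0)
            sel = (cls == x) & (prev_cls == a)
            n_ax = int(sel.sum())
            if n_ax == 0 or t_ax == 0.0:
                continue
            t_xa = float(np.mean(next_cls[sel] == a))
            cond_fit = fx
            if n_ax >= 20 * fx.k:
                try:
                    cond_fit = fit_mixture(
                        dur[sel], fx.k, dead_time_ms=dead_time_ms, starts=4
                    )
                except DwellFitError:
                    cond_fit = fx
            fx_td = cond_fit.prob_below(dead_time_ms)
            contrib = t_ax * fx_td * t_xa
            p += contrib
            m_gap += contrib * cond_fit.mean_below(dead_time_ms)
        m_gap = m_gap / p if p > 0 else 0.0
        comps = tuple(
            (max((1.0 - p) * tau - p * m_gap, 1e-6), area)
            for tau, area in fit.components
        )
        out[a] = ExpMixtureFit(
            components=comps,
            dead_time_ms=fit.dead_time_ms,
            log_likelihood=fit.log_likelihood,
            n_events=fit.n_events,
            standard_errors=fit.standard_errors,
            class_label=a,
            converged=fit.converged,
        )
        out[a].standard_errors = {**fit.standard_errors, "missed_event_p": p}
    return out


def fit_record_classes(
    record: IdealizedRecord,
    k_by_class: dict[str, int],
    dead_time_ms: float | None = None,
    correct_missed_events: bool = True,
    resolution_guard_samples: int = 1,
    artifact_screen: set[str] | frozenset[str] | None = None,
    **fit_kw,
) -> dict[str, ExpMixtureFit]:
    """Fit every requested class of a dead-time-imposed record.

    For idealized (grid-quantized) records the truncation point is the
    half-sample-corrected effective dead time plus a resolution guard of
    ``resolution_guard_samples``: events in the first retained sample bin
    sit at the edge of what Viterbi segmentation of filtered data resolves
    (the anti-alias filter's rise time is about one sample), so the record
    is conservatively re-merged at one sample above the imposed dead time
    and the likelihood truncated there.  Simulated records with exact
    durations use the nominal dead time unchanged.  With
    ``correct_missed_events`` the apparent-lifetime correction is applied
    across classes at the same resolution.  Classes named in
    ``artifact_screen`` (those bounded by a low-contrast level, where
    correlated-noise dips masquerade as brief events) are fitted through
    :func:`fit_with_artifact_screen`.
    """
    from .idealize import impose_dead_time  # local import avoids a cycle

    td_nominal = record.dead_time_ms if dead_time_ms is None else dead_time_ms
    rec = record
    if record.source == "idealized" and record.sampling_rate:
        dt = 1e3 / record.sampling_rate
        n0 = int(np.ceil(td_nominal / dt - 1e-9)) + resolution_guard_samples
        td = max(n0 * dt - 0.5 * dt, 0.0)
        if td > td_nominal:
            rec = impose_dead_time(record, td)
    else:
        td = td_nominal
    fits: dict[str, ExpMixtureFit] = {}
    for lbl, k in k_by_class.items():
        d = rec.durations_of(lbl)
        if artifact_screen and lbl in artifact_screen:
            fits[lbl] = fit_with_artifact_screen(
                d, k, dead_time_ms=td, class_label=lbl, **fit_kw
            )
        else:
            fits[lbl] = fit_mixture(d, k, dead_time_ms=td, class_label=lbl, **fit_kw)
    if correct_missed_events:
        fits = correct_apparent_lifetimes(fits, rec, td)
    return fits
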