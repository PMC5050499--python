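"""Segmental K-means (SKM) idealization and kinetic summaries.

A sampled current trace is converted into a discrete event sequence by the
segmental K-means algorithm: Viterbi segmentation under a Gaussian-emission
HMM whose hidden states are the conductance classes, alternated with
re-estimation of the class amplitudes, per-class noise SDs and the
per-sample transition matrix from the current segmentation, until the
segmentation log-likelihood stops improving.  A dead time (120 us in the
recordings this package emulates) is then imposed: events shorter than the
dead time are deleted and absorbed into the preceding event, after which
the summary statistics of single-channel work -- Po, Pb, median open and
closed durations, closing frequency, mean class amplitudes -- are computed.

Class mean amplitudes are reported from event-interior samples only (a few
samples at each event edge are excluded) so that filter-smeared transition
samples do not bias the level estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .synth import IdealizedRecord, Trace

MS_PER_S = 1e3

#: samples excluded at each event edge when estimating class amplitudes
EDGE_TRIM_SAMPLES = 2


class IdealizationError(ValueError):
    pass


@dataclass
class IdealizationModel:
    """Initial conditions and controls for SKM idealization.

    ``class_levels`` are initial amplitudes (pA) in ascending order and
    ``class_labels`` names each level's conductance class.  The per-sample
    transition matrix is re-estimated from the segmentation; its initial
    value only needs the right order of magnitude (events last many
    samples, so the self-transition probability is close to one).
    """

    class_levels: np.ndarray
    class_labels: tuple[str, ...]
    class_noise_sd: np.ndarray | float = 1.0
    transition_probabilities: np.ndarray | None = None
    max_iterations: int = 30
    convergence_tol: float = 1e-8

    def __post_init__(self) -> None:
        self.class_levels = np.asarray(self.class_levels, dtype=float)
        k = self.class_levels.size
        if k < 2:
            raise IdealizationError("idealization needs at least 2 classes")
        if len(self.class_labels) != k:
            raise IdealizationError("class_labels must match class_levels")
        if np.isscalar(self.class_noise_sd):
            self.class_noise_sd = np.full(k, float(self.class_noise_sd))
        else:
            self.class_noise_sd = np.asarray(self.class_noise_sd, dtype=float)
        if self.transition_probabilities is None:
            p_stay = 0.99
            T = np.full((k, k), (1 - p_stay) / (k - 1))
            np.fill_diagonal(T, p_stay)
            self.transition_probabilities = T
        T = np.asarray(self.transition_probabilities, dtype=float)
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
            raise IdealizationError("transition probabilities must be row-stochastic")
        self.transition_probabilities = T


@dataclass
class KineticSummary:
    """Summary kinetics of an idealized record.  Undefined statistics for an
    absent class are NaN, never silently zero."""

    Po: float
    Pb: float
    To_median_ms: float
    Tc_median_ms: float
    closing_frequency_hz: float
    mean_amplitude_pA: dict[str, float]
    event_count: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "Po": self.Po,
            "Pb": self.Pb,
            "To_median_ms": self.To_median_ms,
            "Tc_median_ms": self.Tc_median_ms,
            "closing_frequency_hz": self.closing_frequency_hz,
            **{f"amp_{k}_pA": v for k, v in self.mean_amplitude_pA.items()},
            **{f"n_{k}": v for k, v in self.event_count.items()},
        }


@njit(cache=False)
def _viterbi(x, means, sds, logT, logpi0):  # pragma: no cover - numba kernel
    n = x.size
    k = means.size
    log_norm = np.empty(k)
    inv2v = np.empty(k)
    for j in range(k):
        log_norm[j] = -0.5 * np.log(2.0 * np.pi * sds[j] * sds[j])
        inv2v[j] = 0.5 / (sds[j] * sds[j])
    delta = np.empty(k)
    prev = np.empty(k)
    bp = np.empty((n, k), dtype=np.uint8)
    for j in range(k):
        d = x[0] - means[j]
        delta[j] = logpi0[j] + log_norm[j] - inv2v[j] * d * d
    for t in range(1, n):
        for j in range(k):
            prev[j] = delta[j]
        for j in range(k):
            best = -1.0e308
            arg = 0
            for i in range(k):
                v = prev[i] + logT[i, j]
                if v > best:
                    best = v
                    arg = i
            d = x[t] - means[j]
            delta[j] = best + log_norm[j] - inv2v[j] * d * d
            bp[t, j] = arg
    best = -1.0e308
    arg = 0
    for j in range(k):
        if delta[j] > best:
            best = delta[j]
            arg = j
    path = np.empty(n, dtype=np.uint8)
    path[n - 1] = arg
    for t in range(n - 2, -1, -1):
        path[t] = bp[t + 1, path[t + 1]]
    return path, best


def kmeans_levels(samples: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic 1-D k-means for initial class amplitudes.

    Initialised at evenly spaced quantiles plus min/max-anchored variants;
    the best final inertia wins, ties broken by sorted level.
    """
    x = np.asarray(samples, dtype=float)
    if x.size > 200_000:
        x = x[:: x.size // 200_000 + 1]
    inits = [
        np.quantile(x, np.linspace(0.02, 0.98, k)),
        np.quantile(x, np.linspace(0.0, 1.0, k + 2)[1:-1]),
        np.linspace(x.min(), x.max(), k),
    ]
    best_c, best_inertia = None, np.inf
    for c0 in inits:
        c = np.sort(np.asarray(c0, dtype=float))
        for _ in range(max_iter):
            edges = (c[1:] + c[:-1]) / 2
            lab = np.searchsorted(edges, x)
            new_c = c.copy()
            for j in range(k):
                sel = lab == j
                if sel.any():
                    new_c[j] = x[sel].mean()
            new_c = np.sort(new_c)
            if np.allclose(new_c, c, atol=1e-12):
                c = new_c
                break
            c = new_c
        edges = (c[1:] + c[:-1]) / 2
        lab = np.searchsorted(edges, x)
        inertia = float(np.sum((x - c[lab]) ** 2))
        if inertia < best_inertia - 1e-9:
            best_inertia, best_c = inertia, c
    return best_c


def _histogram_peak_levels(x: np.ndarray, k: int) -> np.ndarray:
    """Initial levels from the most prominent peaks of the smoothed
    amplitude histogram, padded with quantiles when fewer than k distinct
    peaks exist (a level can hide as a shoulder under a dominant one)."""
    from scipy.signal import find_peaks

    hist, edges = np.histogram(x, bins=256)
    centers = (edges[1:] + edges[:-1]) / 2
    kern = np.exp(-0.5 * (np.arange(-8, 9) / 3.0) ** 2)
    h = np.convolve(hist.astype(float), kern / kern.sum(), mode="same")
    idx, props = find_peaks(h, prominence=0.02 * h.max())
    order = np.argsort(props["prominences"])[::-1]
    peaks = list(centers[idx[order[:k]]])
    if len(peaks) < k:
        span = float(x.max() - x.min())
        for q in np.quantile(x, np.linspace(0.02, 0.98, 2 * k)):
            if all(abs(q - p) > span / (4 * k) for p in peaks):
                peaks.append(float(q))
            if len(peaks) == k:
                break
        while len(peaks) < k:  # degenerate data; spread arbitrarily
            peaks.append(float(x.min()) + span * len(peaks) / k)
    return np.sort(np.array(peaks[:k]))


def gaussian_mixture_levels(samples: np.ndarray, k: int, max_iter: int = 300) -> np.ndarray:
    """Class levels from a 1-D Gaussian mixture fitted to the amplitude
    distribution of low-slope samples (the conventional all-points
    histogram read-out of a single-channel record, with filter-transition
    samples excluded so inter-level shoulders do not masquerade as levels).
    Deterministic: EM from histogram-peak, quantile, uniform and k-means
    initial configurations; best log-likelihood wins."""
    x = np.asarray(samples, dtype=float)
    if x.size > 6:
        dx = np.abs(x[2:] - x[:-2])
        med = np.median(dx)
        if med > 0:
            keep = dx < 2.0 * med
            if keep.sum() >= max(10 * k, 100):
                x = x[1:-1][keep]
    if x.size > 100_000:
        x = x[:: x.size // 100_000 + 1]
    n = x.size
    span = float(x.max() - x.min())
    sd0 = max(span / (6 * k), 1e-6)
    qs = [np.quantile(x, np.linspace(lo, 1 - lo, k)) for lo in (0.01, 0.05, 0.15)]
    inits = [_histogram_peak_levels(x, k)] + qs + [
        np.linspace(x.min(), x.max(), k),
        kmeans_levels(x, k),
    ]
    best_mu, best_ll = None, -np.inf
    for mu0 in inits:
        mu = np.sort(np.asarray(mu0, dtype=float))
        var = np.full(k, sd0 * sd0)
        w = np.full(k, 1.0 / k)
        ll_prev = -np.inf
        for _ in range(max_iter):
            logp = (
                np.log(w)
                - 0.5 * np.log(2 * np.pi * var)
                - 0.5 * (x[:, None] - mu) ** 2 / var
            )
            m = logp.max(axis=1, keepdims=True)
            p = np.exp(logp - m)
            tot = p.sum(axis=1, keepdims=True)
            ll = float(np.sum(m.ravel() + np.log(tot.ravel())))
            r = p / tot
            nk = r.sum(axis=0) + 1e-12
            w = nk / n
            mu = (r * x[:, None]).sum(axis=0) / nk
            var = np.maximum((r * (x[:, None] - mu) ** 2).sum(axis=0) / nk, 1e-9)
            if abs(ll - ll_prev) < 1e-7 * abs(ll):
                break
            ll_prev = ll
        if ll > best_ll:
            best_ll, best_mu = ll, np.sort(mu)
    return best_mu


def skm_idealize(trace: Trace, model: IdealizationModel) -> IdealizedRecord:
    """Idealize a trace by segmental K-means.

    Iterates Viterbi segmentation and parameter re-estimation until the
    Viterbi log-likelihood improves by less than ``convergence_tol`` (in
    relative terms) or ``max_iterations`` is reached; the final
    segmentation is returned as an event record with per-event mean
    amplitudes.  A class that loses all its samples is re-seeded at a
    quantile of the data (with a warning); non-convergence returns the best
    iterate flagged in ``meta['converged']``.
    """
    x = np.asarray(trace.samples, dtype=float)
    if x.size == 0:
        raise IdealizationError("trace is empty")
    k = model.class_levels.size
    means = model.class_levels.astype(float).copy()
    sds = np.maximum(model.class_noise_sd.astype(float).copy(), 1e-6)
    T = model.transition_probabilities.copy()
    logpi0 = np.full(k, -np.log(k))

    ll_prev = -np.inf
    converged = False
    path = None
    for _ in range(model.max_iterations):
        logT = np.log(np.maximum(T, 1e-300))
        path, ll = _viterbi(x, means, sds, logT, logpi0)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= model.convergence_tol * abs(ll_prev):
            converged = True
            break
        ll_prev = ll
        # re-estimate emission and transition parameters from the segmentation
        counts = np.zeros(k)
        for j in range(k):
            sel = path == j
            counts[j] = sel.sum()
            if counts[j] == 0:
                means[j] = float(np.quantile(x, (j + 0.5) / k))
                warnings.warn(
                    f"class {j} lost all samples; re-seeded its mean", RuntimeWarning
                )
                continue
            means[j] = x[sel].mean()
            sds[j] = max(x[sel].std(), 1e-6)
        trans = np.zeros((k, k))
        np.add.at(trans, (path[:-1].astype(int), path[1:].astype(int)), 1.0)
        trans += 0.5  # pseudocount keeps log finite
        T = trans / trans.sum(axis=1, keepdims=True)

    assert path is not None
    if not converged:
        warnings.warn("SKM did not converge; returning best iterate", RuntimeWarning)

    # runs of the final path -> events
    change = np.empty(path.size, dtype=bool)
    change[0] = True
    change[1:] = path[1:] != path[:-1]
    starts = np.flatnonzero(change)
    ends = np.append(starts[1:], path.size)
    cls_idx = path[starts].astype(int)
    dt_ms = MS_PER_S / trace.sampling_rate
    durations = (ends - starts) * dt_ms
    amp = np.array([x[s:e].mean() for s, e in zip(starts, ends)])
    labels = np.array(model.class_labels, dtype=object)

    # trimmed class amplitudes: event-interior samples only
    interior_mean: dict[str, float] = {}
    interior_n: dict[str, int] = {}
    tr = EDGE_TRIM_SAMPLES
    for j, lbl in enumerate(model.class_labels):
        tot, cnt = 0.0, 0
        for s, e, ci in zip(starts, ends, cls_idx):
            if ci != j or e - s <= 2 * tr:
                continue
            seg = x[s + tr : e - tr]
            tot += seg.sum()
            cnt += seg.size
        if cnt:
            interior_mean[lbl] = tot / cnt
            interior_n[lbl] = cnt
        else:
            interior_mean[lbl] = float("nan")
            interior_n[lbl] = 0

    return IdealizedRecord(
        classes=labels[cls_idx],
        durations_ms=durations,
        amplitudes_pA=amp,
        states=None,
        sampling_rate=trace.sampling_rate,
        holding_potential_mV=trace.holding_potential_mV,
        source="idealized",
        meta={
            "converged": converged,
            "skm_class_levels_pA": means.tolist(),
            "skm_class_sd_pA": sds.tolist(),
            "class_amplitude_pA": interior_mean,
            "class_amplitude_n_samples": interior_n,
            "viterbi_ll": float(ll_prev),
        },
    )


def auto_idealize(trace: Trace, n_classes: int, class_labels: tuple[str, ...],
                  init: str = "gmm", **model_kw) -> IdealizedRecord:
    """Convenience: data-driven initial levels (all-points Gaussian mixture
    by default, ``init='kmeans'`` for plain k-means), then SKM."""
    if init == "gmm":
        levels = gaussian_mixture_levels(trace.samples, n_classes)
    elif init == "kmeans":
        levels = kmeans_levels(trace.samples, n_classes)
    else:
        raise ValueError(f"unknown init {init!r}")
    sd0 = max(float(np.diff(levels).min()) / 4.0, 1e-3)
    model = IdealizationModel(
        class_levels=levels, class_labels=class_labels, class_noise_sd=sd0, **model_kw
    )
    return skm_idealize(trace, model)


def impose_dead_time(record: IdealizedRecord, dead_time_ms: float) -> IdealizedRecord:
    """Remove events shorter than the dead time, merging their duration into
    the preceding event (leading short events merge forward), then
    concatenate successive same-class events.  Total duration is conserved;
    the operation is idempotent.
    """
    if dead_time_ms < 0:
        raise ValueError("dead_time_ms must be >= 0")
    if dead_time_ms == 0 or record.n_events == 0:
        return record
    dur = record.durations_ms
    keep = dur >= dead_time_ms
    if not keep.any():
        raise IdealizationError("record unresolvable at this dead time")

    classes, durations, amps = [], [], []
    pending = 0.0  # duration of leading sub-dead-time events
    for c, d, a, k in zip(record.classes, dur, record.amplitudes_pA, keep):
        if not k:
            if durations:
                durations[-1] += d
            else:
                pending += d
            continue
        if durations and classes[-1] == c:
            w = durations[-1] + d
            amps[-1] = (amps[-1] * durations[-1] + a * d) / w
            durations[-1] = w
        else:
            classes.append(c)
            durations.append(d + pending)
            pending = 0.0
            amps.append(a)

    out = IdealizedRecord(
        classes=np.array(classes, dtype=object),
        durations_ms=np.array(durations),
        amplitudes_pA=np.array(amps),
        states=None,
        dead_time_ms=dead_time_ms,
        sampling_rate=record.sampling_rate,
        holding_potential_mV=record.holding_potential_mV,
        source=record.source,
        meta=dict(record.meta),
    )
    return out


def summarize(record: IdealizedRecord) -> KineticSummary:
    """Po, Pb, median open/closed durations, closing frequency, amplitudes.

    Po and Pb are time fractions over the whole record; the first and last
    events (censored dwells) are excluded from the duration statistics but
    contribute to the time fractions.  The closing frequency is the number
    of closed events per second of record.
    """
    if record.n_events == 0:
        raise ValueError("record is empty")
    total_ms = record.total_duration_ms
    cls = record.classes
    dur = record.durations_ms

    def time_frac(lbl: str) -> float:
        return float(dur[cls == lbl].sum() / total_ms)

    po, pb = time_frac("OPEN"), time_frac("BLOCKED")

    interior = slice(1, -1) if record.n_events > 2 else slice(0, 0)
    cls_i, dur_i = cls[interior], dur[interior]

    def med(lbl: str) -> float:
        d = dur_i[cls_i == lbl]
        return float(np.median(d)) if d.size else float("nan")

    counts = {lbl: int(np.sum(cls == lbl)) for lbl in ("CLOSED", "OPEN", "BLOCKED")}
    amp_meta = record.meta.get("class_amplitude_pA")
    if amp_meta:
        mean_amp = {lbl: float(amp_meta.get(lbl, np.nan)) for lbl in counts}
    else:
        mean_amp = {}
        for lbl in counts:
            sel = cls == lbl
            if sel.any():
                d = dur[sel]
                mean_amp[lbl] = float(np.sum(record.amplitudes_pA[sel] * d) / d.sum())
            else:
                mean_amp[lbl] = float("nan")

    return KineticSummary(
        Po=po,
        Pb=pb,
        To_median_ms=med("OPEN"),
        Tc_median_ms=med("CLOSED"),
        closing_frequency_hz=counts["CLOSED"] / (total_ms / MS_PER_S),
        mean_amplitude_pA=mean_amp,
        event_count=counts,
    )
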