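"""Truncated exponential-mixture fitting, histograms and component-count
selection, validated on known-truth simulations."""

import numpy as np
import pytest

from ryrblock import synth
from ryrblock.dwell_fit import (
    DwellFitError,
    effective_dead_time,
    fit_mixture,
    histogram,
    select_components,
)


def draw_mixture(rng, n, taus, areas, dead_time=0.0):
    comp = rng.choice(len(taus), size=3 * n, p=areas)
    t = rng.exponential(np.asarray(taus)[comp])
    t = t[t >= dead_time][:n]
    assert t.size == n
    return t


class TestHistogram:
    def _rec(self, durations):
        n = len(durations)
        return synth.IdealizedRecord(
            classes=np.array(["CLOSED"] * n, dtype=object),
            durations_ms=np.asarray(durations, dtype=float),
            amplitudes_pA=np.zeros(n),
        )

    def test_counts_land_in_expected_bins(self):
        h = histogram(self._rec([1.0, 1.0, 10.0]), "CLOSED", bins_per_decade=5)
        assert h.counts.sum() == 3
        centers = np.sqrt(h.bin_edges_ms[:-1] * h.bin_edges_ms[1:])
        assert h.counts[np.argmin(np.abs(centers - 1.0))] == 2
        assert h.counts[np.argmin(np.abs(centers - 10.0))] == 1

    def test_sqrt_mode_peaks_near_tau_on_log_axis(self):
        rng = np.random.default_rng(11)
        d = rng.exponential(1.0, size=100_000)
        h = histogram(self._rec(d), "CLOSED", bins_per_decade=10, transform="sqrt")
        centers = np.sqrt(h.bin_edges_ms[:-1] * h.bin_edges_ms[1:])
        # log-binned exponential peaks at t = tau
        peak = centers[np.argmax(h.ordinate)]
        assert 0.6 < peak < 1.6

    def test_zero_bins_per_decade_rejected(self):
        with pytest.raises(ValueError):
            histogram(self._rec([1.0]), "CLOSED", bins_per_decade=0)

    def test_empty_class_rejected(self):
        with pytest.raises(DwellFitError):
            histogram(self._rec([1.0]), "OPEN")


class TestFitMixture:
    def test_single_exponential_recovery(self):
        rng = np.random.default_rng(21)
        t = rng.exponential(1.0, size=50_000)
        fit = fit_mixture(t, 1, dead_time_ms=0.0)
        assert fit.components[0][0] == pytest.approx(1.0, rel=0.02)

    def test_two_component_closed_time_structure(self):
        # brief 0.35 ms at 54% area against a 10.7 ms component, truncated
        rng = np.random.default_rng(22)
        t = draw_mixture(rng, 20_000, [0.35, 10.7], [0.54, 0.46], dead_time=0.12)
        fit = fit_mixture(t, 2, dead_time_ms=0.12)
        (t1, a1), (t2, a2) = fit.components
        assert t1 == pytest.approx(0.35, rel=0.10)
        assert t2 == pytest.approx(10.7, rel=0.10)
        assert a1 == pytest.approx(0.54, abs=0.05)

    def test_durations_below_dead_time_rejected(self):
        with pytest.raises(DwellFitError):
            fit_mixture(np.array([0.05, 1.0, 2.0, 3.0, 4.0]), 1, dead_time_ms=0.12)

    def test_unsupportable_component_count_rejected(self):
        with pytest.raises(DwellFitError):
            fit_mixture(np.array([1.0, 2.0, 3.0, 4.0]), 2)

    def test_areas_sum_to_one_and_taus_sorted(self):
        rng = np.random.default_rng(23)
        t = draw_mixture(rng, 5_000, [0.5, 5.0], [0.5, 0.5])
        fit = fit_mixture(t, 2)
        assert fit.areas.sum() == pytest.approx(1.0, abs=1e-6)
        assert (np.diff(fit.taus_ms) > 0).all()

    def test_truncation_vanishes_as_dead_time_goes_to_zero(self):
        rng = np.random.default_rng(24)
        t = rng.exponential(2.0, size=20_000)
        f0 = fit_mixture(t, 1, dead_time_ms=0.0)
        f_eps = fit_mixture(t, 1, dead_time_ms=1e-9)
        assert f_eps.components[0][0] == pytest.approx(f0.components[0][0], rel=1e-6)
        assert f_eps.log_likelihood == pytest.approx(f0.log_likelihood, rel=1e-9)

    def test_estimator_consistency_over_n(self):
        taus, areas = [0.5, 8.0], [0.6, 0.4]
        errs = []
        for n in (1_000, 10_000, 100_000):
            per_seed = []
            for seed in (1, 2, 3):
                rng = np.random.default_rng(1000 * seed + n)
                t = draw_mixture(rng, n, taus, areas)
                fit = fit_mixture(t, 2, starts=4)
                per_seed.append(abs(fit.components[0][0] - 0.5) / 0.5)
            errs.append(np.median(per_seed))
        assert errs[2] < errs[0]

    def test_standard_errors_scale_with_n(self):
        rng = np.random.default_rng(25)
        small = fit_mixture(rng.exponential(1.0, size=500), 1)
        large = fit_mixture(rng.exponential(1.0, size=50_000), 1)
        assert large.standard_errors["tau_ms"][0] < small.standard_errors["tau_ms"][0]


class TestSelectComponents:
    def test_single_exponential_selects_one(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            t = rng.exponential(1.0, size=10_000)
            best_k, _ = select_components(t, max_k=3, starts=3)
            hits += best_k == 1
        assert hits >= 9

    def test_two_component_structure_selects_two(self):
        rng = np.random.default_rng(31)
        t = draw_mixture(rng, 10_000, [0.35, 10.7], [0.54, 0.46])
        best_k, fits = select_components(t, max_k=3, starts=3)
        assert best_k == 2
        assert set(fits) >= {1, 2}

    def test_unsupportable_ks_are_skipped(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        best_k, fits = select_components(t, max_k=3)
        assert max(fits) <= 2  # k=3 needs 7 events


class TestArtifactHandling:
    def test_screen_removes_sub_resolution_component(self):
        # two physical components plus a contamination population just
        # above the dead time, as false events from a low-contrast level
        rng = np.random.default_rng(41)
        phys = draw_mixture(rng, 8_000, [0.6, 10.0], [0.65, 0.35], dead_time=0.175)
        art = rng.exponential(0.22, size=2_000)
        art = art[art >= 0.175][:1200]
        t = np.concatenate([phys, art])
        from ryrblock.dwell_fit import fit_with_artifact_screen

        screened = fit_with_artifact_screen(t, 2, dead_time_ms=0.175)
        assert screened.k == 2
        assert screened.components[0][0] == pytest.approx(0.6, rel=0.12)
        assert screened.standard_errors["artifact_area"] > 0.05
        # plain fit is dragged down by the contamination
        plain = fit_mixture(t, 2, dead_time_ms=0.175)
        assert plain.components[0][0] < screened.components[0][0]

    def test_screen_is_noop_on_clean_data(self):
        rng = np.random.default_rng(42)
        t = draw_mixture(rng, 6_000, [0.6, 10.0], [0.6, 0.4], dead_time=0.175)
        from ryrblock.dwell_fit import fit_with_artifact_screen

        screened = fit_with_artifact_screen(t, 2, dead_time_ms=0.175)
        plain = fit_mixture(t, 2, dead_time_ms=0.175)
        assert screened.components[0][0] == pytest.approx(
            plain.components[0][0], rel=0.10
        )

    def test_splitting_correction_inverts_apparent_rate(self):
        from ryrblock.dwell_fit import ExpMixtureFit, correct_false_event_splitting

        fit = ExpMixtureFit(
            components=((1.0, 0.5), (10.0, 0.5)),
            dead_time_ms=0.12,
            log_likelihood=0.0,
            n_events=100,
        )
        out = correct_false_event_splitting(fit, 5.0)  # 5 false events / s
        assert out.components[0][0] == pytest.approx(1.0 / (1.0 - 0.005), rel=1e-9)
        assert out.components[1][0] == pytest.approx(1.0 / (0.1 - 0.005), rel=1e-9)
        assert correct_false_event_splitting(fit, 0.0) is fit


class TestEffectiveDeadTime:
    def test_grid_correction(self):
        # 0.12 ms at 20 kHz -> first retained bin is 3 samples (0.15 ms),
        # truncation point half a sample lower
        assert effective_dead_time(0.12, 20_000.0) == pytest.approx(0.125)
        assert effective_dead_time(0.12, None) == pytest.approx(0.12)
        assert effective_dead_time(0.0, 20_000.0) == pytest.approx(0.0)
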