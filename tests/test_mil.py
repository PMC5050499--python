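"""Interval likelihood, rate fitting and topology ranking, checked
against closed forms, a dense matrix-exponential oracle and
parameter-recovery simulations."""

import numpy as np
import pytest
from scipy.linalg import expm

from ryrblock import fixtures, synth
from ryrblock.mil import MILError, fit_rates, interval_likelihood, rank_models
from ryrblock.schemes import (
    _class_entry_vector,
    build_scheme,
    class_dwell_components,
    generator_matrix,
)


def series_expm(A, order=30):
    """Independent matrix exponential: high-order Taylor series with
    scaling and squaring (keeps the series norm well inside convergence)."""
    norm = np.linalg.norm(A, 1)
    s = max(int(np.ceil(np.log2(max(norm, 1e-16)))) + 1, 0)
    B = A / (2**s)
    out = np.eye(A.shape[0])
    term = np.eye(A.shape[0])
    for k in range(1, order + 1):
        term = term @ B / k
        out = out + term
    for _ in range(s):
        out = out @ out
    return out


def brute_force_ll(record, scheme, use_series=True):
    """Dense forward product with explicit matrix exponentials."""
    Q = generator_matrix(scheme)
    ci = {lbl: scheme.class_indices(lbl) for lbl in scheme.class_labels}
    rec = record.merge_to_classes()
    v = _class_entry_vector(scheme, rec.classes[0]).copy()
    ll = 0.0
    for k in range(rec.n_events):
        a = ci[rec.classes[k]]
        t = rec.durations_ms[k] * 1e-3
        E = series_expm(Q[np.ix_(a, a)] * t) if use_series else expm(Q[np.ix_(a, a)] * t)
        v = v @ E
        if k < rec.n_events - 1:
            v = v @ Q[np.ix_(a, ci[rec.classes[k + 1]])]
        s = np.abs(v).sum()
        v = v / s
        ll += np.log(s)
    return ll + np.log(v.sum())


class TestIntervalLikelihood:
    def test_two_state_closed_form(self):
        scheme = fixtures.two_state(100.0, 300.0)
        rec = synth.simulate_dwells(scheme, 40, seed=1)
        rates = {"CLOSED": 100.0, "OPEN": 300.0}
        r = np.array([rates[c] for c in rec.classes])
        t = rec.durations_ms * 1e-3
        manual = np.sum(np.log(r[:-1]) - r[:-1] * t[:-1]) - r[-1] * t[-1]
        assert interval_likelihood(rec, scheme, 0.0) == pytest.approx(manual, abs=1e-9)

    def test_matches_series_expm_oracle_on_ten_events(self, emd4_scheme):
        rec = synth.simulate_dwells(emd4_scheme, 120, seed=2).merge_to_classes()
        small = synth.IdealizedRecord(
            classes=rec.classes[:10],
            durations_ms=rec.durations_ms[:10],
            amplitudes_pA=rec.amplitudes_pA[:10],
        )
        ll = interval_likelihood(small, emd4_scheme, 0.0)
        assert ll == pytest.approx(brute_force_ll(small, emd4_scheme), abs=1e-8)

    def test_generating_rates_beat_perturbed_rates(self, emd4_scheme):
        wins = 0
        for seed in range(20):
            rec = synth.simulate_class_events(emd4_scheme, 2_000, seed=500 + seed)
            ll_true = interval_likelihood(rec, emd4_scheme, 0.0)
            ll_pert = interval_likelihood(
                rec, emd4_scheme.with_rates(emd4_scheme.rates * 2.0), 0.0
            )
            wins += ll_true > ll_pert
        assert wins >= 19

    def test_dead_time_zero_limit(self, emd4_scheme, emd4_record_10k):
        from ryrblock.idealize import impose_dead_time

        rec = impose_dead_time(emd4_record_10k, 1e-6)
        ll0 = interval_likelihood(rec, emd4_scheme, 0.0)
        ll_eps = interval_likelihood(rec, emd4_scheme, 1e-7)
        assert ll_eps == pytest.approx(ll0, rel=1e-6)

    def test_invariant_to_state_relabelling_within_class(self, emd4_scheme):
        rec = synth.simulate_class_events(emd4_scheme, 500, seed=3)
        d = emd4_scheme.to_definition()
        swap = {"C1": "C2", "C2": "C1"}
        for s in d["states"]:
            s["name"] = swap.get(s["name"], s["name"])
        for r in d["rates"]:
            r["from"] = swap.get(r["from"], r["from"])
            r["to"] = swap.get(r["to"], r["to"])
        relabelled = build_scheme(d)
        assert interval_likelihood(rec, relabelled, 0.0) == pytest.approx(
            interval_likelihood(rec, emd4_scheme, 0.0), rel=1e-9
        )

    def test_unknown_class_rejected(self, emd4_scheme):
        rec = synth.simulate_class_events(fixtures.tba5(), 50, seed=4)
        with pytest.raises(MILError):
            interval_likelihood(rec, emd4_scheme, 0.0)


class TestFitRates:
    def test_stationary_at_generating_rates(self, emd4_scheme):
        # initialized at the truth on a large record, the optimizer should
        # stay in its neighbourhood and not lose likelihood
        rec = synth.simulate_class_events(emd4_scheme, 8_000, seed=11)
        res = fit_rates(
            rec, emd4_scheme, 0.0, starts=1, compute_se=False, init_scheme=emd4_scheme
        )
        assert res.log_likelihood >= interval_likelihood(rec, emd4_scheme, 0.0) - 1e-6
        ratio = res.scheme.rates[emd4_scheme.rates > 0] / emd4_scheme.rates[
            emd4_scheme.rates > 0
        ]
        assert np.all((ratio > 0.5) & (ratio < 2.0))

    def test_parameter_recovery_up_to_class_permutation(self, emd4_scheme):
        rec = synth.simulate_class_events(emd4_scheme, 15_000, seed=12)
        res = fit_rates(rec, emd4_scheme, 0.0, starts=2, compute_se=False)
        # compare class dwell components (invariant to within-class relabelling)
        for lbl in ("CLOSED", "OPEN"):
            dc_true = class_dwell_components(emd4_scheme, lbl)
            dc_fit = class_dwell_components(res.scheme, lbl)
            assert np.allclose(dc_fit.taus_ms, dc_true.taus_ms, rtol=0.15)
            assert np.allclose(dc_fit.areas, dc_true.areas, atol=0.08)

    def test_dead_time_correction_reduces_flicker_bias(self):
        # 2-state scheme with 0.35 ms closings, observed above a 0.12 ms
        # dead time: the corrected fit should be less biased on the
        # closed exit rate than the uncorrected one
        scheme = fixtures.two_state(1.0 / 10.7e-3, 1.0 / 0.35e-3)  # open flickers
        from ryrblock.idealize import impose_dead_time

        bias_corr, bias_raw = [], []
        for seed in (1, 2, 3):
            rec = impose_dead_time(
                synth.simulate_class_events(scheme, 6_000, seed=600 + seed), 0.12
            )
            corr = fit_rates(rec, scheme, 0.12, starts=1, compute_se=False)
            raw = fit_rates(rec, scheme, 0.0, starts=1, compute_se=False)
            k_true = 1.0 / 0.35e-3
            bias_corr.append(abs(corr.rate("O", "C") - k_true))
            bias_raw.append(abs(raw.rate("O", "C") - k_true))
        assert np.median(bias_corr) < np.median(bias_raw)

    def test_recovery_error_shrinks_with_n(self, emd4_scheme):
        def med_err(n, seed):
            rec = synth.simulate_class_events(emd4_scheme, n, seed=seed)
            res = fit_rates(rec, emd4_scheme, 0.0, starts=1, compute_se=False)
            errs = []
            for lbl in ("CLOSED", "OPEN"):
                tt = class_dwell_components(emd4_scheme, lbl).taus_ms
                ft = class_dwell_components(res.scheme, lbl).taus_ms
                errs.extend(np.abs(ft - tt) / tt)
            return np.median(errs)

        small = np.median([med_err(1_000, s) for s in (71, 72, 73)])
        large = np.median([med_err(8_000, s) for s in (74, 75, 76)])
        assert large < small


class TestRankModels:
    def test_single_candidate_ranks_first(self, emd4_scheme):
        rec = synth.simulate_class_events(emd4_scheme, 1_000, seed=21)
        ranking = rank_models(rec, {"emd4": emd4_scheme}, 0.0, starts=1)
        assert ranking.best[0] == "emd4"
        assert ranking.deltas == [0.0]

    def test_tpea_topology_discriminated_from_tba_topology(self):
        """Data simulated with a direct B1<->B2 pathway should rank the
        topology containing that edge above the one without it in the
        majority of seeded replicates."""
        gen = fixtures.tpea5()
        wins = 0
        n_rep = 10
        for seed in range(n_rep):
            rec = synth.simulate_class_events(gen, 10_000, seed=800 + seed)
            ranking = rank_models(
                rec,
                {"with_b1b2": fixtures.tpea5(), "through_open": fixtures.tba5()},
                0.0,
                starts=2,
                seed=seed,
            )
            wins += ranking.best[0] == "with_b1b2"
        assert wins > n_rep // 2

    def test_spurious_closed_closed_edge_gains_little(self, emd4_scheme):
        """Adding the disallowed direct C1-C2 edge to the generating
        4-state scheme buys almost no likelihood (the edge is absent in
        the data-generating process)."""
        rec = synth.simulate_class_events(emd4_scheme, 10_000, seed=22)
        d = emd4_scheme.to_definition()
        d["name"] = "emd4_c1c2"
        d["rates"] += [
            {"from": "C1", "to": "C2", "rate": 10.0},
            {"from": "C2", "to": "C1", "rate": 10.0},
        ]
        augmented = build_scheme(d)
        base = fit_rates(rec, emd4_scheme, 0.0, starts=2, compute_se=False)
        extra = fit_rates(rec, augmented, 0.0, starts=2, compute_se=False)
        assert extra.log_likelihood - base.log_likelihood < 2.0

    def test_failed_topology_ranks_last_with_error(self, emd4_scheme):
        rec = synth.simulate_class_events(fixtures.tba5(), 300, seed=23)
        ranking = rank_models(
            rec, {"blocker": fixtures.tba5(), "no_blocked_class": emd4_scheme}, 0.0, starts=1
        )
        tids = [tid for tid, _ in ranking.entries]
        assert tids[-1] == "no_blocked_class"
        assert ranking.entries[-1][1].error is not None


class TestAggregationConsistency:
    def test_fitted_scheme_dwell_density_matches_components(self, emd4_scheme):
        rec = synth.simulate_class_events(emd4_scheme, 4_000, seed=31)
        res = fit_rates(rec, emd4_scheme, 0.0, starts=1, compute_se=False)
        Q = generator_matrix(res.scheme)
        for lbl in ("CLOSED", "OPEN"):
            dc = class_dwell_components(res.scheme, lbl)
            a = res.scheme.class_indices(lbl)
            phi = _class_entry_vector(res.scheme, lbl)
            ones = np.ones(a.size)
            for t_ms in (0.1, 1.0, 5.0, 20.0):
                numeric = (
                    phi @ expm(Q[np.ix_(a, a)] * t_ms * 1e-3) @ (-Q[np.ix_(a, a)]) @ ones
                ) * 1e-3
                assert dc.density(np.array([t_ms]))[0] == pytest.approx(numeric, rel=1e-6)
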