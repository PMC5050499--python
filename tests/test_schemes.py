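"""Gating-scheme construction, generator algebra and analytic dwell
components, checked against independent linear-algebra, quadrature and
simulation oracles."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm

from ryrblock import fixtures, synth
from ryrblock.schemes import (
    SchemeValidationError,
    analytic_open_probability,
    build_scheme,
    class_dwell_components,
    equilibrium_occupancy,
    generator_matrix,
    mean_class_dwell_ms,
)


def chain3(k12=50.0, k21=20.0, k23=400.0, k32=150.0):
    return build_scheme(
        {
            "states": [
                {"name": "C1", "class": "CLOSED"},
                {"name": "C2", "class": "CLOSED"},
                {"name": "O", "class": "OPEN"},
            ],
            "rates": [
                {"from": "C1", "to": "C2", "rate": k12},
                {"from": "C2", "to": "C1", "rate": k21},
                {"from": "C2", "to": "O", "rate": k23},
                {"from": "O", "to": "C2", "rate": k32},
            ],
        }
    )


class TestBuildScheme:
    def test_minimal_two_state(self):
        s = fixtures.two_state(100.0, 100.0)
        assert s.n_states == 2
        assert s.states_in_class("CLOSED") == ["C"]
        assert s.states_in_class("OPEN") == ["O"]

    def test_emd4_topology(self, emd4_scheme):
        # two closed + two open states, and no direct C1-C2 edge
        assert len(emd4_scheme.states_in_class("CLOSED")) == 2
        assert len(emd4_scheme.states_in_class("OPEN")) == 2
        assert ("C1", "C2") not in emd4_scheme.connectivity
        assert ("C2", "C1") not in emd4_scheme.connectivity

    def test_negative_rate_rejected(self):
        with pytest.raises(SchemeValidationError, match="negative"):
            build_scheme(
                {
                    "states": [
                        {"name": "C", "class": "CLOSED"},
                        {"name": "O", "class": "OPEN"},
                    ],
                    "rates": [
                        {"from": "C", "to": "O", "rate": -5.0},
                        {"from": "O", "to": "C", "rate": 10.0},
                    ],
                }
            )

    def test_disconnected_graph_names_state(self):
        with pytest.raises(SchemeValidationError, match="O2"):
            build_scheme(
                {
                    "states": [
                        {"name": "C", "class": "CLOSED"},
                        {"name": "O", "class": "OPEN"},
                        {"name": "O2", "class": "OPEN"},
                    ],
                    "rates": [
                        {"from": "C", "to": "O", "rate": 1.0},
                        {"from": "O", "to": "C", "rate": 1.0},
                    ],
                }
            )

    def test_blocked_needs_fraction_in_unit_interval(self):
        for bad in (0.0, 1.0, 1.4):
            with pytest.raises(SchemeValidationError):
                build_scheme(
                    {
                        "states": [
                            {"name": "C", "class": "CLOSED"},
                            {"name": "O", "class": "OPEN"},
                            {"name": "B", "class": "BLOCKED", "conductance": bad},
                        ],
                        "rates": [
                            {"from": "C", "to": "O", "rate": 1.0},
                            {"from": "O", "to": "C", "rate": 1.0},
                            {"from": "O", "to": "B", "rate": 1.0},
                            {"from": "B", "to": "O", "rate": 1.0},
                        ],
                    }
                )


class TestGeneratorMatrix:
    def test_two_state_example(self):
        s = fixtures.two_state(100.0, 300.0)
        Q = generator_matrix(s)
        assert np.allclose(Q, [[-100.0, 100.0], [300.0, -300.0]])

    @pytest.mark.parametrize("name", ["emd4", "tba5", "tpea5"])
    def test_fixture_rows_sum_to_zero(self, name):
        Q = generator_matrix(fixtures.preset(name))
        assert np.abs(Q.sum(axis=1)).max() < 1e-9

    def test_three_state_chain_matches_hand_assembly(self):
        s = chain3()
        Q = generator_matrix(s)
        expected = np.array(
            [[-50.0, 50.0, 0.0], [20.0, -420.0, 400.0], [0.0, 150.0, -150.0]]
        )
        assert np.allclose(Q, expected)


class TestEquilibrium:
    def test_symmetric_two_state(self):
        pi = equilibrium_occupancy(generator_matrix(fixtures.two_state(80.0, 80.0)))
        assert np.allclose(pi, [0.5, 0.5])

    def test_single_state_degenerate(self):
        assert np.allclose(equilibrium_occupancy(np.array([[0.0]])), [1.0])

    def test_chain_matches_dense_nullspace_oracle(self):
        Q = generator_matrix(chain3())
        pi = equilibrium_occupancy(Q)
        # independent oracle: solve the augmented linear system directly
        A = np.vstack([Q.T, np.ones(3)])
        b = np.array([0.0, 0.0, 0.0, 1.0])
        oracle, *_ = np.linalg.lstsq(A, b, rcond=None)
        assert np.allclose(pi, oracle, atol=1e-10)
        assert np.abs(pi @ Q).max() < 1e-9

    def test_invariant_to_state_reordering(self, emd4_scheme):
        d = emd4_scheme.to_definition()
        perm = [2, 0, 3, 1]
        d["states"] = [d["states"][i] for i in perm]
        reordered = build_scheme(d)
        pi1 = equilibrium_occupancy(generator_matrix(emd4_scheme))
        pi2 = equilibrium_occupancy(generator_matrix(reordered))
        for s in emd4_scheme.state_names:
            assert pi1[emd4_scheme.index(s)] == pytest.approx(pi2[reordered.index(s)], abs=1e-9)

    def test_reducible_generator_rejected(self):
        Q = np.array([[-1.0, 1.0, 0.0], [1.0, -1.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(SchemeValidationError):
            equilibrium_occupancy(Q)


class TestOpenProbability:
    def test_symmetric_two_state(self):
        assert analytic_open_probability(fixtures.two_state(50.0, 50.0)) == pytest.approx(0.5)

    def test_emd4_is_high_activity(self, emd4_scheme):
        # the modelling selection criterion was high-activity channels
        assert analytic_open_probability(emd4_scheme) >= 0.7

    def test_class_occupancies_sum_to_one(self):
        occ = analytic_open_probability(fixtures.tpea5(), per_class=True)
        assert sum(occ.values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_long_run_simulation(self, emd4_scheme):
        rec = synth.simulate_dwells(emd4_scheme, 200_000, seed=42)
        opn = rec.classes == "OPEN"
        po_sim = rec.durations_ms[opn].sum() / rec.total_duration_ms
        # batch-means Monte-Carlo SE of the time fraction
        nb = 50
        bounds = np.linspace(0, rec.n_events, nb + 1, dtype=int)
        fracs = np.array(
            [
                rec.durations_ms[a:b][opn[a:b]].sum() / max(rec.durations_ms[a:b].sum(), 1e-12)
                for a, b in zip(bounds[:-1], bounds[1:])
            ]
        )
        se = fracs.std(ddof=1) / np.sqrt(nb)
        assert abs(po_sim - analytic_open_probability(emd4_scheme)) < 3 * se + 1e-4


class TestDwellComponents:
    def test_single_flicker_state(self):
        # lone closed state with total exit rate 2857/s -> tau ~ 0.35 ms
        s = build_scheme(
            {
                "states": [
                    {"name": "C", "class": "CLOSED"},
                    {"name": "O", "class": "OPEN"},
                ],
                "rates": [
                    {"from": "C", "to": "O", "rate": 2857.0},
                    {"from": "O", "to": "C", "rate": 100.0},
                ],
            }
        )
        dc = class_dwell_components(s, "CLOSED")
        assert len(dc.components) == 1
        assert dc.components[0][0] == pytest.approx(0.35, rel=1e-3)
        assert dc.components[0][1] == pytest.approx(1.0)

    def test_unconnected_pair_matches_quadrature_oracle(self):
        s = fixtures.emd4()
        dc = class_dwell_components(s, "CLOSED")
        # oracle: numeric phase-type density phi expm(Qaa t) (-Qaa) 1
        Q = generator_matrix(s)
        a = s.class_indices("CLOSED")
        Qaa = Q[np.ix_(a, a)]
        from ryrblock.schemes import _class_entry_vector

        phi = _class_entry_vector(s, "CLOSED")
        ones = np.ones(a.size)

        def pt_density_ms(t_ms):
            t = t_ms * 1e-3
            return float(phi @ expm(Qaa * t) @ (-Qaa) @ ones) * 1e-3

        for t in (0.05, 0.35, 2.0, 10.0, 40.0):
            assert dc.density(np.array([t]))[0] == pytest.approx(pt_density_ms(t), rel=1e-8)
        total, _ = quad(lambda t: dc.density(np.array([t]))[0], 0, 500, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_whole_scheme_class_is_rejected(self):
        s = build_scheme(
            {
                "states": [
                    {"name": "C", "class": "CLOSED"},
                    {"name": "O", "class": "OPEN"},
                ],
                "rates": [
                    {"from": "C", "to": "O", "rate": 10.0},
                    {"from": "O", "to": "C", "rate": 10.0},
                ],
            }
        )
        with pytest.raises(SchemeValidationError):
            class_dwell_components(s, "MISSING")

    @pytest.mark.parametrize(
        "name,label,expected",
        [
            ("emd4", "CLOSED", [(0.35, 0.54), (10.7, 0.46)]),
            ("emd4", "OPEN", [(0.35, 0.14), (23.7, 0.86)]),
            ("tba5", "BLOCKED", [(0.25, None), (1.06, None)]),
            ("tba5", "CLOSED", [(4.0, None), (10.7, None)]),
            ("tpea5", "BLOCKED", [(1.0, None), (11.2, None)]),
            ("tpea5", "CLOSED", [(0.6, None), (10.7, None)]),
        ],
    )
    def test_fixture_components_match_their_calibration(self, name, label, expected):
        dc = class_dwell_components(fixtures.preset(name), label)
        assert len(dc.components) == len(expected)
        for (tau, area), (etau, earea) in zip(dc.components, expected):
            assert tau == pytest.approx(etau, rel=1e-6)
            if earea is not None:
                assert area == pytest.approx(earea, rel=1e-6)

    @pytest.mark.parametrize("name", ["emd4", "tba5", "tpea5"])
    def test_areas_sum_and_mean_identity(self, name):
        s = fixtures.preset(name)
        for label in s.class_labels:
            dc = class_dwell_components(s, label)
            assert dc.areas.sum() == pytest.approx(1.0, abs=1e-9)
            assert dc.mean_ms == pytest.approx(mean_class_dwell_ms(s, label), rel=1e-6)

    def test_empirical_dwells_follow_analytic_density(self, emd4_scheme, emd4_record_10k):
        from scipy.stats import kstest

        dc = class_dwell_components(emd4_scheme, "CLOSED")

        def cdf(t):
            t = np.asarray(t, dtype=float)[:, None]
            return np.sum(dc.areas * (1.0 - np.exp(-t / dc.taus_ms)), axis=1)

        d = emd4_record_10k.durations_of("CLOSED")
        assert kstest(d, cdf).pvalue > 0.01
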