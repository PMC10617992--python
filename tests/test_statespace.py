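"""Unit and property tests for the microscopic state-space model."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    brute_force_bound_fraction,
    brute_force_deprotonation_fraction,
    brute_force_probabilities,
    random_model,
)
from zincsite.statespace import (
    Condition,
    ConsistencyEdge,
    Microstate,
    ModelError,
    apparent_kd,
    bound_fraction,
    deprotonation_fraction_model,
    enumerate_microstates,
    fit_consistent_potentials,
    free_energy,
    microstate_pka,
    model_from_json,
    model_from_parameters,
    model_to_json,
    solve_potentials,
    state_probabilities,
)

LN10 = math.log(10.0)


@pytest.mark.parametrize(
    "n_residues,n_free,n_total",
    [(4, 16, 32), (3, 8, 16), (0, 1, 2), (2, 4, 8)],
)
def test_enumerate_state_counts(n_residues, n_free, n_total):
    states = enumerate_microstates(n_residues)
    assert len(states) == n_total
    assert sum(1 for s in states if not s.zinc_bound) == n_free


def test_enumerate_canonical_order_and_labels():
    states = enumerate_microstates(2)
    # metal-free block first, proton codes little-endian ascending
    assert [s.label for s in states] == [
        "S0", "S1", "S2", "S3", "S0:Zn", "S1:Zn", "S2:Zn", "S3:Zn"
    ]
    assert [s.index() for s in states] == list(range(8))
    s1 = states[1]
    assert s1.protons == (1, 0) and s1.n_protons == 1


def test_enumerate_rejects_negative():
    with pytest.raises(ValueError):
        enumerate_microstates(-1)


class TestModelFromParameters:
    def test_additive_model_keeps_intrinsic_pkas_in_every_context(self):
        model = model_from_parameters({"A": 4.0, "B": 7.0, "C": 9.5})
        for ctx in enumerate_microstates(3):
            for res, pka in (("A", 4.0), ("B", 7.0), ("C", 9.5)):
                bit = model.residue(res).bit_index
                if ctx.protons[bit]:
                    continue
                assert microstate_pka(model, res, ctx) == pytest.approx(pka, abs=1e-12)

    def test_pairwise_coupling_shifts_partner_context(self):
        model = model_from_parameters({"A": 6.0, "B": 6.0}, {("A", "B"): 1.0})
        free = Microstate((0, 0), False)
        assert microstate_pka(model, "A", free) == pytest.approx(6.0)
        b_prot = Microstate((0, 1), False)
        assert microstate_pka(model, "A", b_prot) == pytest.approx(5.0)

    def test_site_a_parameter_set_builds_32_states(self):
        model = model_from_parameters(
            {"D47": 3.84, "D51": 2.92, "H155": 7.97, "D159": 4.87}
        )
        assert model.n_states == 32
        assert model.g[0] == 0.0

    def test_missing_coupling_residue_is_configuration_error(self):
        with pytest.raises(ModelError):
            model_from_parameters({"A": 4.0}, {("A", "Z"): 1.0})


class TestFreeEnergy:
    def test_reference_state_is_zero_everywhere(self):
        model = model_from_parameters({"A": 5.0, "B": 8.0}, None, -3.0)
        ref = Microstate((0, 0), False)
        for ph, zn in [(0.0, 1e-9), (7.0, 1e-3), (14.0, 1.0)]:
            assert free_energy(model, ref, Condition(ph, zn)) == 0.0

    def test_protonation_edge_vanishes_at_ph_equal_pka(self):
        model = model_from_parameters({"A": 5.5})
        prot = Microstate((1,), False)
        assert free_energy(model, prot, Condition(5.5, 1e-12)) == pytest.approx(0.0, abs=1e-12)

    def test_binding_edge_vanishes_at_kd(self):
        kd = 3.7e-8
        model = model_from_parameters({"A": 5.0}, None, math.log(kd))
        bound = Microstate((0,), True)
        assert free_energy(model, bound, Condition(7.0, kd)) == pytest.approx(0.0, abs=1e-12)

    def test_bound_state_infinite_at_zero_metal(self):
        model = model_from_parameters({"A": 5.0}, None, -2.0)
        bound = Microstate((0,), True)
        assert free_energy(model, bound, Condition(7.0, 0.0)) == math.inf


class TestProbabilitiesAgainstOracle:
    def test_two_state_symmetry_at_pka(self):
        model = model_from_parameters({"A": 6.2}, None, 0.0)
        p = state_probabilities(model, Condition(6.2, 1e-30))
        assert p[0] == pytest.approx(0.5, abs=1e-10)
        assert p[1] == pytest.approx(0.5, abs=1e-10)

    @pytest.mark.parametrize("n_residues", [1, 2, 3, 4, 5])
    def test_matches_brute_force_enumeration(self, rng, n_residues):
        for _ in range(8):
            model = random_model(rng, n_residues)
            cond = Condition(rng.uniform(2, 12), 10.0 ** rng.uniform(-12, -3))
            p = state_probabilities(model, cond)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            oracle = brute_force_probabilities(model, cond)
            np.testing.assert_allclose(p, oracle, atol=1e-12)
            assert bound_fraction(model, cond) == pytest.approx(
                brute_force_bound_fraction(model, cond), abs=1e-12
            )
            assert deprotonation_fraction_model(model, "R0", cond) == pytest.approx(
                brute_force_deprotonation_fraction(model, "R0", cond), abs=1e-12
            )

    def test_extreme_pka_does_not_overflow(self):
        model = model_from_parameters({"A": 200.0}, None, 0.0)
        p = state_probabilities(model, Condition(1.0, 1e-9))
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)


class TestBoundFraction:
    def test_zero_metal_gives_zero(self):
        model = model_from_parameters({"A": 5.0}, None, -4.0)
        assert bound_fraction(model, Condition(7.0, 0.0)) == 0.0

    def test_zero_residue_model_half_occupied_at_kd(self):
        kd = 2e-7
        model = model_from_parameters({}, None, math.log(kd))
        assert bound_fraction(model, Condition(7.0, kd)) == pytest.approx(0.5, abs=1e-12)

    def test_single_residue_against_four_term_closed_form(self):
        # Zn binds any protonation state with the same energy
        pka, g0 = 6.0, math.log(5e-8)
        model = model_from_parameters({"A": pka}, None, g0)
        for ph, zn in [(5.0, 1e-8), (6.0, 5e-8), (7.5, 1e-6)]:
            x = zn / 1.0
            wp = 10.0 ** (pka - ph)
            zb = math.exp(-g0) * x
            expected = (zb + zb * wp) / (1 + wp + zb + zb * wp)
            assert bound_fraction(model, Condition(ph, zn)) == pytest.approx(
                expected, abs=1e-12
            )

    @given(st.floats(1e-10, 1e-4), st.floats(2.0, 4.0))
    @settings(max_examples=30, deadline=None)
    def test_strictly_increasing_in_metal(self, zn, factor):
        model = model_from_parameters({"A": 6.0, "B": 7.5}, None, math.log(1e-7))
        cond_lo = Condition(7.0, zn)
        cond_hi = Condition(7.0, zn * factor)
        assert bound_fraction(model, cond_hi) > bound_fraction(model, cond_lo)


class TestDeprotonationFraction:
    def test_henderson_hasselbalch_exact_for_single_residue(self):
        pka = 6.8
        model = model_from_parameters({"A": pka})
        for ph in np.linspace(2, 12, 21):
            expected = 1.0 / (1.0 + 10.0 ** (pka - ph))
            got = deprotonation_fraction_model(model, "A", Condition(ph, 1e-30))
            assert got == pytest.approx(expected, abs=1e-12)

    def test_high_ph_limit_is_one(self):
        model = model_from_parameters({"A": 4.0, "B": 9.0})
        assert deprotonation_fraction_model(
            model, "B", Condition(25.0, 1e-30)
        ) == pytest.approx(1.0, abs=1e-10)

    def test_unknown_residue_is_lookup_error(self):
        model = model_from_parameters({"A": 4.0})
        with pytest.raises(KeyError):
            deprotonation_fraction_model(model, "Z", Condition(7.0, 1e-9))


class TestApparentKd:
    def test_zero_residue_model_reproduces_kd_exactly(self):
        kd = 4.2e-9
        model = model_from_parameters({}, None, math.log(kd))
        assert apparent_kd(model, 7.0) == pytest.approx(kd, rel=1e-9)

    def test_competitive_single_residue_closed_form(self):
        # Zn binds only the deprotonated state: K_app = K_D (1 + 10^(pKa-pH))
        kd, pka = 1e-8, 6.5
        model = model_from_parameters({"A": pka}, None, {0: math.log(kd), 1: 40.0})
        for ph in [5.0, 6.5, 8.0]:
            expected = kd * (1 + 10.0 ** (pka - ph))
            assert apparent_kd(model, ph) == pytest.approx(expected, rel=1e-8)

    def test_monotone_decreasing_in_ph_for_competitive_binding(self):
        model = model_from_parameters(
            {"A": 6.0, "B": 7.0}, None,
            {0: math.log(1e-8), 1: 15.0 + math.log(1e-8),
             2: 15.0 + math.log(1e-8), 3: 30.0 + math.log(1e-8)},
        )
        grid = np.linspace(4.0, 9.0, 11)
        kds = [apparent_kd(model, ph) for ph in grid]
        assert all(np.isfinite(kds)) and all(k > 0 for k in kds)
        assert all(a > b for a, b in zip(kds, kds[1:]))


class TestMicrostatePka:
    def test_path_independence_two_orders(self, rng):
        for _ in range(20):
            model = random_model(rng, 3)
            # S0 -> R0 -> R0R1 must equal S0 -> R1 -> R0R1
            s0 = Microstate((0, 0, 0), False)
            a = microstate_pka(model, "R0", s0) + microstate_pka(
                model, "R1", s0.with_proton(0)
            )
            b = microstate_pka(model, "R1", s0) + microstate_pka(
                model, "R0", s0.with_proton(1)
            )
            assert a == pytest.approx(b, abs=1e-12)

    def test_protonated_context_is_argument_error(self):
        model = model_from_parameters({"A": 5.0})
        with pytest.raises(ModelError):
            microstate_pka(model, "A", Microstate((1,), False))


def test_thermodynamic_cycle_closure(rng):
    """Protonate-then-bind equals bind-then-protonate for any model."""
    for _ in range(10):
        model = random_model(rng, 4)
        cond = Condition(rng.uniform(3, 11), 10.0 ** rng.uniform(-10, -4))
        s_free = Microstate((0, 1, 0, 0), False)
        s_free_p = s_free.with_proton(0)
        s_bound = Microstate(s_free.protons, True)
        s_bound_p = Microstate(s_free_p.protons, True)
        def G(s):
            return free_energy(model, s, cond)
        path1 = (G(s_free_p) - G(s_free)) + (G(s_bound_p) - G(s_free_p))
        path2 = (G(s_bound) - G(s_free)) + (G(s_bound_p) - G(s_bound))
        assert path1 == pytest.approx(path2, abs=1e-12)


class TestConsistencySolver:
    def test_triangle_reproduces_hand_solved_potentials(self):
        edges = [("A", "B", 1.0, 1.0), ("B", "C", 1.0, 1.0), ("A", "C", 2.3, 1.0)]
        pot = solve_potentials(edges, "A")
        assert pot["B"] == pytest.approx(1.1, abs=1e-12)
        assert pot["C"] == pytest.approx(2.2, abs=1e-12)

    def test_spanning_tree_reproduced_exactly(self, rng):
        states = enumerate_microstates(2)
        by_label = {s.label: s for s in states}
        g_true = np.concatenate([[0.0], rng.uniform(-5, 5, 7)])
        # adjacent-edge spanning tree: protonation edges in the free block,
        # then one binding edge per protonation state
        pairs = [("S0", "S1"), ("S0", "S2"), ("S1", "S3"),
                 ("S0", "S0:Zn"), ("S1", "S1:Zn"), ("S2", "S2:Zn"), ("S3", "S3:Zn")]
        edges = []
        for la, lb in pairs:
            a, b = by_label[la], by_label[lb]
            edges.append(
                ConsistencyEdge(a, b, g_true[b.index()] - g_true[a.index()], 0.5)
            )
        model = fit_consistent_potentials(edges, 2)
        np.testing.assert_allclose(model.g, g_true, atol=1e-10)

    def test_non_adjacent_edge_rejected(self):
        states = enumerate_microstates(2)
        with pytest.raises(ModelError, match="differ by exactly one"):
            ConsistencyEdge(states[0], states[3], 1.0, 1.0)

    def test_duplicated_edges_do_not_change_solution(self):
        edges = [("A", "B", 1.0, 1.0), ("B", "C", 1.0, 1.0), ("A", "C", 2.3, 1.0)]
        pot1 = solve_potentials(edges, "A")
        pot2 = solve_potentials(edges + edges, "A")
        for k in pot1:
            assert pot1[k] == pytest.approx(pot2[k], abs=1e-12)

    def test_disconnected_graph_names_unreachable_states(self):
        states = enumerate_microstates(1)
        edges = [ConsistencyEdge(states[0], states[1], 1.0, 1.0)]
        with pytest.raises(ModelError, match="not connected"):
            fit_consistent_potentials(edges, 1)


def test_model_json_round_trip_preserves_doubles(rng):
    model = random_model(rng, 3)
    restored = model_from_json(model_to_json(model))
    np.testing.assert_array_equal(restored.g, model.g)
    assert [r.label for r in restored.residues] == [r.label for r in model.residues]
    table = json.loads(model_to_json(model))["state_labels"]
    assert table[0] == {"index": 0, "label": "S0", "protons": [0, 0, 0],
                        "zinc_bound": False}
    assert len(table) == 16
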