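"""The quadratic penalty, its interaction-graph projection, the
oversaturation correction, and the exact oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from threebop.burial import compute_burial_grid
from threebop.errors import ParameterError, UsageError
from threebop.fixtures import random_cluster_grid_pose, random_polar_cluster
from threebop.penalty import (PolarScheme, SCHEME_PRESETS, assign_corrected,
                              assign_naive, count_buried_unsat,
                              eval_penalty, extraneous_fraction, get_scheme,
                              oracle_components, oracle_total, table_total)
from threebop.rotamers import (Rotamer, RotamerSet, apply_assignment,
                               build_rotamer_set, native_rotamer_set)
from threebop.structure import mutate_to_polyleu

from conftest import make_deep_grid, synthetic_acceptor, synthetic_donor

# the five published example rows: label -> (coeffs, penalties at H=0..5)
TABLE1_ROWS = {
    "NH1": ((1, -1, 2), [1, 0, 1, 4, 9, 16]),
    "carbonyl_O": ((1, -1, 1), [1, 0, 0, 1, 3, 6]),
    "NH2": ((4, -3, 2), [4, 1, 0, 1, 4, 9]),
    "carboxylate_O": ((3, -2, 1), [3, 1, 0, 0, 1, 3]),
    "NH3": ((9, -5, 2), [9, 4, 1, 0, 1, 4]),
}
TABLE1_TARGETS = {
    "NH1": {1}, "carbonyl_O": {1, 2}, "NH2": {2},
    "carboxylate_O": {2, 3}, "NH3": {3},
}


class TestEvalPenalty:
    @pytest.mark.parametrize("label", sorted(TABLE1_ROWS))
    def test_published_rows_exact(self, label):
        coeffs, expected = TABLE1_ROWS[label]
        values = [eval_penalty(coeffs, h) for h in range(6)]
        assert values == expected

    @pytest.mark.parametrize("label", sorted(TABLE1_ROWS))
    def test_minimum_at_target_hbond_count(self, label):
        coeffs, expected = TABLE1_ROWS[label]
        minimum = min(expected)
        argmin = {h for h, v in enumerate(expected) if v == minimum}
        assert argmin == TABLE1_TARGETS[label]

    def test_zero_coefficients(self):
        assert all(eval_penalty((0, 0, 0), h) == 0 for h in range(6))

    def test_negative_h_raises(self):
        with pytest.raises(ParameterError):
            eval_penalty((1, -1, 1), -1)

    @settings(max_examples=50, derandomize=True)
    @given(beta=st.integers(-10, 10), sigma=st.integers(-10, 10),
           omega=st.integers(-10, 10), h=st.integers(1, 20))
    def test_second_difference_is_omega(self, beta, sigma, omega, h):
        params = (beta, sigma, omega)
        second = (eval_penalty(params, h + 1) - 2 * eval_penalty(params, h)
                  + eval_penalty(params, h - 1))
        assert second == omega

    def test_scheme_presets_match_published_coefficients(self):
        table1 = SCHEME_PRESETS["table1"]
        for label, (coeffs, _) in TABLE1_ROWS.items():
            assert table1.coeffs(label) == tuple(float(c) for c in coeffs)
        for label in SCHEME_PRESETS["uniform5"].coefficients:
            assert SCHEME_PRESETS["uniform5"].coeffs(label) == (5., -5., 5.)
            assert SCHEME_PRESETS["uniform5_noover"].coeffs(label) == \
                (5., -5., 0.)
            assert SCHEME_PRESETS["uniform10"].coeffs(label) == \
                (10., -10., 10.)
        assert SCHEME_PRESETS["uniform5_lysnz"].coeffs("NH3")[:2] == \
            (15., -10.)
        assert SCHEME_PRESETS["uniform10_lysnz"].coeffs("NH3")[:2] == \
            (30., -20.)

    def test_scheme_text_round_trip(self):
        scheme = SCHEME_PRESETS["table1"]
        back = PolarScheme.from_text(scheme.to_text())
        assert back.coefficients == scheme.coefficients

    def test_unknown_scheme_raises(self):
        with pytest.raises(ParameterError):
            get_scheme("not_a_scheme")


class TestAssignWorkedExample:
    def test_fig_like_network_entries(self, glu_two_ser_pose,
                                      glu_two_ser_grid, uniform1_scheme):
        rset = native_rotamer_set(glu_two_ser_pose, [1, 2, 3])
        table = assign_naive(rset, glu_two_ser_grid, uniform1_scheme, 0.37)
        assert table.one_body_terms["beta"] == {(1, 0): 1.0}
        assert table.two_body_terms["sigma"] == {
            ((1, 0), (2, 0)): -1.0, ((1, 0), (3, 0)): -1.0}
        assert table.two_body_terms["omega"] == {((2, 0), (3, 0)): 1.0}
        assert table.constant_offset == 0.0
        assignment = {1: 0, 2: 0, 3: 0}
        total = table_total(table, assignment)
        oracle, report = oracle_total(glu_two_ser_pose, glu_two_ser_grid,
                                      uniform1_scheme, 0.37)
        assert total == pytest.approx(0.0, abs=1e-12)
        assert oracle == pytest.approx(0.0, abs=1e-12)
        assert len(report) == 1
        atom, h, p = report[0]
        assert (atom.name, h, p) == ("OE1", 2, 0.0)

    def test_surface_fixture_gives_empty_table(self, surface_pose,
                                               surface_grid, uniform1_scheme):
        rset = native_rotamer_set(surface_pose, [1, 2, 3, 4])
        table = assign_naive(rset, surface_grid, uniform1_scheme, 0.37)
        assert not table.one_body_keys()
        assert not table.two_body_keys()
        assert table.constant_offset == 0.0


class TestAssignCombinatorics:
    def test_three_satisfiers_give_three_omega_edges(self, deep_grid):
        b = synthetic_acceptor(1, [0.0, 0.0, 0.0])
        donors = [synthetic_donor(2 + k, pos, [0.0, 0.0, 0.0])
                  for k, pos in enumerate(([2.8, 0, 0], [-2.8, 0, 0],
                                           [0, 2.8, 0]))]
        rset = RotamerSet(
            {1: [Rotamer(1, "ASN", (), [b], 0)],
             **{2 + k: [Rotamer(2 + k, "TRP", (), [d], 0)]
                for k, d in enumerate(donors)}}, [])
        scheme = PolarScheme("t", {"carbonyl_O": (1., -1., 1.),
                                   "indole": (0., 0., 0.)})
        table = assign_naive(rset, deep_grid, scheme, 0.1)
        sigma_edges = {k for k in table.two_body_terms["sigma"]}
        omega_edges = {k for k in table.two_body_terms["omega"]}
        assert len(sigma_edges) == 3
        assert len(omega_edges) == 3  # C(3, 2)
        assert table.stats["omega_pair_contributions"] >= 3

    def test_correction_unit_case(self, deep_grid):
        q1 = synthetic_donor(2, [2.8, 0, 0], [0, 0, 0])
        q2 = synthetic_donor(3, [-2.8, 0, 0], [0, 0, 0])
        b1 = synthetic_acceptor(1, [0.0, 0.0, 0.0])
        b2 = synthetic_acceptor(1, [0.0, 0.0, 0.3])
        rset = RotamerSet({1: [Rotamer(1, "ASN", (), [b1], 0),
                               Rotamer(1, "ASN", (), [b2], 1)],
                           2: [Rotamer(2, "TRP", (), [q1], 0)],
                           3: [Rotamer(3, "TRP", (), [q2], 0)]}, [])
        scheme = PolarScheme("t", {"carbonyl_O": (1., -1., 1.),
                                   "indole": (0., 0., 0.)})
        key = ((2, 0), (3, 0))
        naive = assign_naive(rset, deep_grid, scheme, 0.1)
        corrected = assign_corrected(rset, deep_grid, scheme, 0.1)
        assert naive.two_body_terms["omega"][key] == 2.0
        assert corrected.two_body_terms["omega"][key] == 1.0

    def test_single_rotamer_contributing_twice_beats_two_once(self,
                                                              deep_grid):
        # rotamer A holds two buried acceptors each saturated by the same
        # donor pair (accumulates 2 omega); rotamer B holds one
        q1 = synthetic_donor(2, [2.8, 0, 0], [0, 0, 0])
        q1.bound_hydrogens.append(
            q1.position + np.array([-0.93, 0.0, 0.36]))
        q2 = synthetic_donor(3, [-2.8, 0, 0], [0, 0, 0])
        q2.bound_hydrogens.append(
            q2.position + np.array([0.93, 0.0, 0.36]))
        rot_a = Rotamer(1, "ASP", (), [
            synthetic_acceptor(1, [0.0, 0.0, 0.0], res_name="ASP"),
            synthetic_acceptor(1, [0.0, 0.0, 1.0], name="OD2",
                               res_name="ASP")], 0)
        rot_b = Rotamer(1, "ASP", (), [
            synthetic_acceptor(1, [0.0, 0.0, 0.2], res_name="ASP")], 1)
        rset = RotamerSet({1: [rot_a, rot_b],
                           2: [Rotamer(2, "TRP", (), [q1], 0)],
                           3: [Rotamer(3, "TRP", (), [q2], 0)]}, [])
        scheme = PolarScheme("t", {"carboxylate_O": (1., -1., 1.),
                                   "indole": (0., 0., 0.)})
        key = ((2, 0), (3, 0))
        naive = assign_naive(rset, deep_grid, scheme, 0.05)
        corrected = assign_corrected(rset, deep_grid, scheme, 0.05)
        assert naive.two_body_terms["omega"][key] == 3.0
        assert corrected.two_body_terms["omega"][key] == 2.0

    def test_singleton_sets_corrected_equals_naive(self, glu_two_ser_pose,
                                                   glu_two_ser_grid,
                                                   uniform1_scheme):
        rset = native_rotamer_set(glu_two_ser_pose, [1, 2, 3])
        naive = assign_naive(rset, glu_two_ser_grid, uniform1_scheme, 0.37)
        corrected = assign_corrected(rset, glu_two_ser_grid, uniform1_scheme,
                                     0.37)
        assert naive.one_body_terms == corrected.one_body_terms
        assert naive.two_body_terms == corrected.two_body_terms
        assert naive.offset_terms == corrected.offset_terms

    def test_table_total_iteration_order_irrelevant(self, glu_two_ser_pose,
                                                    glu_two_ser_grid,
                                                    uniform1_scheme):
        rset = native_rotamer_set(glu_two_ser_pose, [1, 2, 3])
        table = assign_naive(rset, glu_two_ser_grid, uniform1_scheme, 0.37)
        a = table_total(table, {1: 0, 2: 0, 3: 0})
        b = table_total(table, {3: 0, 1: 0, 2: 0})
        assert a == b

    def test_table_total_missing_position(self, glu_two_ser_pose,
                                          glu_two_ser_grid, uniform1_scheme):
        rset = native_rotamer_set(glu_two_ser_pose, [1, 2, 3])
        table = assign_naive(rset, glu_two_ser_grid, uniform1_scheme, 0.37)
        with pytest.raises(UsageError):
            table_total(table, {1: 0})


class TestSingletonEquivalenceAndBounds:
    def test_singleton_table_matches_oracle(self, cluster_grid):
        for seed in range(30):
            pose = random_polar_cluster(seed)
            positions = [r.index for r in pose.residues[:6]]
            rset = native_rotamer_set(pose, positions)
            table = assign_corrected(rset, cluster_grid, "table1", 0.37)
            total = table_total(table, {p: 0 for p in positions})
            oracle, _ = oracle_total(pose, cluster_grid, "table1", 0.37)
            assert total == pytest.approx(oracle, abs=1e-9)

    def test_naive_corrected_oracle_ordering(self, cluster_grid):
        rng = np.random.default_rng(11)
        for seed in range(8):
            pose = random_polar_cluster(seed)
            positions = [r.index for r in pose.residues[:6]]
            types = {p: pose.residues[p - 1].name for p in positions}
            rset = build_rotamer_set(pose, types, include_native=True)
            naive = assign_naive(rset, cluster_grid, "uniform5", 0.37)
            corrected = assign_corrected(rset, cluster_grid, "uniform5",
                                         0.37)
            for _ in range(3):
                asg = {p: int(rng.integers(len(rset.rotamers[p])))
                       for p in positions}
                posed = apply_assignment(pose, rset, asg)
                oracle, _ = oracle_total(posed, cluster_grid, "uniform5",
                                         0.37)
                t_naive = table_total(naive, asg)
                t_corr = table_total(corrected, asg)
                assert t_naive >= t_corr - 1e-9
                assert t_corr >= oracle - 1e-9
                comps = oracle_components(posed, cluster_grid, "uniform5",
                                          0.37)
                assert table_total(corrected, asg, terms=("beta",)) == \
                    pytest.approx(comps["beta"], abs=1e-9)
                assert table_total(corrected, asg, terms=("sigma",)) == \
                    pytest.approx(comps["sigma"], abs=1e-9)


class TestOracle:
    def test_surface_fixture_is_zero(self, surface_pose, surface_grid):
        total, report = oracle_total(surface_pose, surface_grid, "uniform5",
                                     0.37)
        assert total == 0.0 and report == []
        assert count_buried_unsat(surface_pose, surface_grid, 0.37) == 0

    def test_no_satisfiers_gives_beta_per_buried_atom(self, triad_pose,
                                                      triad_grid):
        # a quality threshold above 1 removes every h-bond
        total, report = oracle_total(triad_pose, triad_grid, "uniform5",
                                     1.01)
        n_buried = len(report)
        assert n_buried >= 2
        assert total == pytest.approx(5.0 * n_buried)
        assert count_buried_unsat(triad_pose, triad_grid, 1.01) == n_buried

    def test_native_triad_fully_satisfied(self, triad_pose, triad_grid):
        assert count_buried_unsat(triad_pose, triad_grid, 0.37) == 0

    def test_h_never_exceeds_partner_count(self, cluster_grid):
        pose = random_polar_cluster(4)
        n_polar = sum(1 for a in pose.all_atoms()
                      if a.polar_class.value != "none")
        _, report = oracle_total(pose, cluster_grid, "table1", 0.0)
        for _, h, _ in report:
            assert 0 <= h < n_polar


class TestExtraneousFraction:
    def test_native_singletons_give_zero(self, glu_two_ser_pose,
                                         glu_two_ser_grid, uniform1_scheme):
        rset = native_rotamer_set(glu_two_ser_pose, [1, 2, 3])
        frac = extraneous_fraction({1: 0, 2: 0, 3: 0}, rset,
                                   glu_two_ser_grid, uniform1_scheme, 0.37)
        assert frac == 0.0

    def test_bridging_rotamer_creates_extraneous_edge(self,
                                                      bridge_scenario,
                                                      uniform1_scheme):
        rset, grid, native = bridge_scenario
        frac = extraneous_fraction(native, rset, grid, uniform1_scheme, 0.2)
        assert frac > 0.0

    def test_nonincreasing_in_quality_threshold(self, bridge_scenario,
                                                uniform1_scheme):
        rset, grid, native = bridge_scenario
        fracs = [extraneous_fraction(native, rset, grid, uniform1_scheme, thr)
                 for thr in (0.1, 0.2, 0.5, 0.9)]
        assert fracs == sorted(fracs, reverse=True)

    def test_missing_native_raises(self, bridge_scenario, uniform1_scheme):
        rset, grid, _ = bridge_scenario
        with pytest.raises(UsageError):
            extraneous_fraction({1: 0}, rset, grid, uniform1_scheme, 0.2)
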