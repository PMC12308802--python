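"""Energy table construction, lookups, pair scoring and environment sums."""

import itertools

import numpy as np
import pytest

from rapa import (
    build_energy_table,
    environment_energy,
    load_table,
    lookup_energy,
    make_structure,
    pair_energy,
    save_table,
)
from rapa import assign_polar_sites, build_neighbor_graph
from rapa.hbond_energetics import best_state_energies, residue_interactions
from rapa.rapa_protocol import initialize, prepare
from rapa.state_enumeration import enumerate_states


class TestEnergyTable:
    def test_grid_shape(self, table):
        assert table.energies.shape == (16, 901)
        assert table.distances[0] == pytest.approx(2.5)
        assert table.distances[-1] == pytest.approx(4.0)
        assert table.angles[0] == pytest.approx(90.0)
        assert table.angles[-1] == pytest.approx(180.0)

    def test_global_minimum_at_equilibrium(self, table):
        i, j = np.unravel_index(table.energies.argmin(), table.energies.shape)
        assert table.distances[i] == pytest.approx(2.8)
        assert table.angles[j] == pytest.approx(180.0)
        assert table.energies[i, j] == pytest.approx(-5.0)

    def test_angle_monotone_on_every_row(self, table):
        diffs = np.diff(table.energies, axis=1)
        assert np.all(diffs <= 1e-12)

    def test_corner_least_favorable(self, table):
        assert np.all(table.energies <= table.energies[-1, 0] + 1e-12)

    def test_all_energies_favorable_or_zero(self, table):
        assert np.all(table.energies <= 0)

    def test_clash_antisymmetry_everywhere(self, table):
        # a clash is scored as the negative of the h-bond at the same point
        assert np.max(np.abs((-table.energies) + table.energies)) == 0.0

    def test_tsv_round_trip_bit_exact(self, table, tmp_path):
        path = tmp_path / "table.tsv"
        save_table(table, str(path))
        t2 = load_table(str(path))
        assert np.array_equal(t2.energies, table.energies)
        assert np.array_equal(t2.distances, table.distances)


class TestLookup:
    def test_nearest_grid_rounding(self, table):
        assert lookup_energy(table, 3.95, 179.96) == pytest.approx(
            float(table.energies[-1, -1]))

    def test_out_of_range_distance_is_zero(self, table):
        assert lookup_energy(table, 5.0, 170.0) == 0.0

    def test_below_90_degrees_is_zero(self, table):
        assert lookup_energy(table, 3.0, 80.0) == 0.0

    def test_short_distance_clamps_to_first_row(self, table):
        assert lookup_energy(table, 2.1, 180.0) == pytest.approx(
            float(table.energies[0, -1]))

    def test_minimum_recovered_by_lookup(self, table):
        grid_min = min(
            lookup_energy(table, d, a)
            for d in np.arange(2.5, 4.05, 0.1)
            for a in np.arange(90.0, 180.5, 1.0)
        )
        assert lookup_energy(table, 2.8, 180.0) == pytest.approx(grid_min)
        assert grid_min == pytest.approx(float(table.energies.min()))


def _prepared(kind, **kw):
    s = make_structure(kind, **kw)
    ctx = prepare(s)
    config = initialize(ctx)
    return s, ctx, config


class TestPairEnergy:
    def test_donor_acceptor_hbond_scored_from_table(self, table):
        s, ctx, config = _prepared("asn_ser")
        g = ctx.graph
        od1 = next(i for i, x in enumerate(g.sites) if x.atom_name == "OD1")
        og = next(i for i, x in enumerate(g.sites) if x.atom_name == "OG")
        rec = pair_energy(table, g.sites[od1], g.sites[og], s, config.assignments)
        assert rec.kind == "hbond"
        assert rec.energy == pytest.approx(
            lookup_energy(table, rec.distance, rec.angle))
        assert rec.energy < 0

    def test_acceptor_acceptor_is_inverse_of_hbond(self, table):
        s, ctx, config = _prepared("asn_ser")
        g = ctx.graph
        og_site = next(x for x in g.sites if x.atom_name == "OG")
        od1_site = next(x for x in g.sites if x.atom_name == "OD1")
        ser_state = config.assignments[("B", 2, "")]
        ser_state.hydroxyl_role = "acceptor"  # force the clash branch
        rec = pair_energy(table, od1_site, og_site, s, config.assignments)
        assert rec.kind == "clash"
        assert rec.energy == pytest.approx(
            -lookup_energy(table, rec.distance, 180.0))
        assert rec.energy > 0

    def test_hydroxyl_free_role_picks_lower_energy(self, table):
        s, ctx, config = _prepared("asn_ser")
        g = ctx.graph
        og_site = next(x for x in g.sites if x.atom_name == "OG")
        od1_site = next(x for x in g.sites if x.atom_name == "OD1")
        free = pair_energy(table, od1_site, og_site, s, config.assignments)
        config.assignments[("B", 2, "")].hydroxyl_role = "acceptor"
        forced = pair_energy(table, od1_site, og_site, s, config.assignments)
        assert free.energy <= forced.energy

    def test_ser_donates_with_closest_candidate(self, table):
        # of the 9 hydroxyl hydrogens, the one nearest the acceptor is used
        s, ctx, config = _prepared("asn_ser")
        g = ctx.graph
        og_site = next(x for x in g.sites if x.atom_name == "OG")
        od1_site = next(x for x in g.sites if x.atom_name == "OD1")
        ser = s.residue(("B", 2, ""))
        state = config.assignments[("B", 2, "")]
        state.hydroxyl_role = "donor"
        rec = pair_energy(table, od1_site, og_site, s, config.assignments)
        cands = state.hydrogen_placements["OG"]
        h_best = min(cands, key=lambda h: np.linalg.norm(h - od1_site.position))
        from rapa.geometry import angle_deg
        assert rec.angle == pytest.approx(
            angle_deg(og_site.position, h_best, od1_site.position))


class TestEnvironmentEnergy:
    def test_no_neighbors_scores_zero(self, table):
        s, ctx, config = _prepared("isolated", resname="GLN")
        r = s.residues[0]
        state = config.assignments[r.key]
        assert environment_energy(table, r, state, config.assignments,
                                  s, ctx.graph) == 0.0

    def test_additive_over_disjoint_neighbor_sets(self, table):
        # two copies of the motif, far apart: the motif residue's energy in
        # the combined structure equals its energy in the single-copy one
        s1, ctx1, cfg1 = _prepared("asn_ser")
        s2, ctx2, cfg2 = _prepared("asn_ser", count=2)
        r1 = s1.residue(("A", 1, ""))
        r2 = s2.residue(("A", 1, ""))
        e1 = environment_energy(table, r1, cfg1.assignments[r1.key],
                                cfg1.assignments, s1, ctx1.graph)
        e2 = environment_energy(table, r2, cfg2.assignments[r2.key],
                                cfg2.assignments, s2, ctx2.graph)
        assert e1 == pytest.approx(e2, abs=1e-9)

    def test_fig2_style_net_negative(self, table):
        # one strong h-bond plus one weaker clash: total below zero
        s, ctx, config = _prepared("asn_ser")
        r = s.residue(("A", 1, ""))
        recs = residue_interactions(table, r, s, ctx.graph, config.assignments)
        kinds = {rec.kind for rec in recs}
        assert sum(rec.energy for rec in recs) < 0


class TestBestStateEnergies:
    def test_four_environments_for_amide_hydroxyl_motif(self, table):
        s, ctx, config = _prepared("asn_ser")
        r = s.residue(("A", 1, ""))
        ambiguous = {("B", 2, ""): ctx.states[("B", 2, "")]}
        scores = best_state_energies(
            table, r, ctx.states[r.key], s, ctx.graph,
            config.assignments, ambiguous)
        assert scores.n_environments == 4    # 2 self states x 2 hydroxyl roles
        assert len(scores.scores) == 2

    def test_agrees_with_brute_force_product(self, table):
        """Independent oracle: nested loops over every neighbor-state
        combination, no shared code path with best_state_energies."""
        from rapa.hbond_energetics import environment_variants

        s, ctx, config = _prepared("asn_asn")
        r = s.residue(("A", 1, ""))
        nb_key = ("B", 2, "")
        nb = s.residue(nb_key)
        nb_variants = environment_variants(nb, ctx.states[nb_key])
        scores = best_state_energies(
            table, r, ctx.states[r.key], s, ctx.graph,
            config.assignments, {nb_key: ctx.states[nb_key]})
        for state, got in zip(scores.states, scores.scores):
            expected = min(
                environment_energy(
                    table, r, state,
                    {**config.assignments, nb_key: v}, s, ctx.graph)
                for v in nb_variants
            )
            assert got == pytest.approx(expected, abs=1e-12)

    def test_symmetric_fixture_states_tie_exactly(self, table):
        s, ctx, config = _prepared("asn_asn")
        r = s.residue(("A", 1, ""))
        scores = best_state_energies(
            table, r, ctx.states[r.key], s, ctx.graph,
            config.assignments, {("B", 2, ""): ctx.states[("B", 2, "")]})
        assert abs(scores.scores[0] - scores.scores[1]) < 1e-9

    def test_product_bound_enforced(self, table):
        from rapa import ResourceLimitError

        s, ctx, config = _prepared("asn_asn")
        r = s.residue(("A", 1, ""))
        with pytest.raises(ResourceLimitError):
            best_state_energies(
                table, r, ctx.states[r.key], s, ctx.graph,
                config.assignments, {("B", 2, ""): ctx.states[("B", 2, "")]},
                product_bound=1)
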