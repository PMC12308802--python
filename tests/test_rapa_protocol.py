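"""The resolve-and-branch workflow: initialization, passes, branching,
termination, determinism and labeling."""

import itertools

import numpy as np
import pytest

from rapa import (
    build_energy_table,
    make_structure,
    run,
    write_configuration,
)
from rapa.hbond_energetics import StateScores, best_state_energies
from rapa.rapa_protocol import (
    _scores_for,
    detect_dyads,
    evaluation_pass,
    initialize,
    prepare,
    write_report,
    summary_json,
)
from rapa.state_enumeration import RPState


def _poly_ala(n=4):
    import rapa.fixtures as fx
    from rapa.structure_model import Atom, Residue, Structure

    names, elements, coords = fx._template("ALA")
    residues = []
    for i in range(n):
        shift = np.array([0.0, 0.0, 6.0 * i])
        residues.append(Residue(
            resname="ALA", chain="A", seqnum=i + 1,
            atoms=[Atom(nm, el, c + shift)
                   for nm, el, c in zip(names, elements, coords)]))
    return Structure(residues=residues)


class TestInitialize:
    def test_poly_ala_all_known(self):
        ctx = prepare(_poly_ala())
        config = initialize(ctx)
        assert config.ambiguous_keys() == []

    def test_single_his_is_the_only_ambiguous(self):
        s = make_structure("his_probe")
        ctx = prepare(s)
        config = initialize(ctx)
        assert config.ambiguous_keys() == [("A", 1, "")]

    def test_bridged_cys_pair_known(self):
        s = make_structure("cys_pair", distance=2.05)
        ctx = prepare(s)
        config = initialize(ctx)
        assert config.ambiguous_keys() == []
        assert all(r.disulfide_partner is not None for r in s)

    def test_unbridged_cys_known_and_protonated(self):
        s = make_structure("cys_pair", distance=3.0)
        ctx = prepare(s)
        config = initialize(ctx)
        assert config.ambiguous_keys() == []
        assert all(r.disulfide_partner is None for r in s)

    def test_lone_acids_fixed_deprotonated(self):
        s = make_structure("asp_dyad", distance=8.0)
        ctx = prepare(s)
        config = initialize(ctx)
        assert config.ambiguous_keys() == []

    def test_dyad_controller_ambiguous(self):
        s = make_structure("asp_dyad", distance=2.6)
        ctx = prepare(s)
        config = initialize(ctx)
        assert config.ambiguous_keys() == [("A", 1, "")]
        assert s.residue(("A", 1, "")).dyad_controller


class TestEvaluationPass:
    def test_large_gap_residue_fixed(self, table):
        # offset facing amides: rotamer gap well above the 1 kcal cutoff
        s = make_structure("asn_asn", offset=0.6)
        ctx = prepare(s, table)
        config = initialize(ctx)
        config, changed = evaluation_pass(ctx, config)
        assert changed
        assert config.statuses[("A", 1, "")] == "known"
        d = ctx.decisions[("A", 1, "")]
        assert d.runner_up_gap > ctx.cutoff

    def test_isolated_gln_fully_solvated(self, table):
        s = make_structure("isolated", resname="GLN")
        ctx = prepare(s, table)
        config = initialize(ctx)
        config, changed = evaluation_pass(ctx, config)
        assert changed
        assert config.statuses[("A", 1, "")] == "known"
        assert ctx.decisions[("A", 1, "")].fully_solvated

    def test_coupled_degenerate_amides_not_fixed(self, table):
        s = make_structure("asn_asn")
        ctx = prepare(s, table)
        config = initialize(ctx)
        config, changed = evaluation_pass(ctx, config)
        assert config.statuses[("A", 1, "")] == "ambiguous"
        assert config.statuses[("B", 2, "")] == "ambiguous"
        config, changed = evaluation_pass(ctx, config)
        assert not changed


class TestBranchArithmetic:
    def test_states_within_cutoff_selection(self):
        # {A: -5.0, B: -4.4, C: -2.0} at cutoff 1.0 -> A and B survive
        states = [RPState(("A", 1, ""), rotamer_id=i) for i in range(3)]
        scores = StateScores(states=states, scores=[-5.0, -4.4, -2.0],
                             n_environments=3)
        within = scores.within_cutoff(1.0)
        assert [i for i, _, _ in within] == [0, 1]

    def test_exact_tie_included(self):
        states = [RPState(("A", 1, ""), rotamer_id=i) for i in range(2)]
        scores = StateScores(states=states, scores=[-5.0, -4.0],
                             n_environments=2)
        assert len(scores.within_cutoff(1.0)) == 2


class TestRun:
    def test_no_ambiguity_single_configuration(self, table):
        res = run(_poly_ala(), table)
        assert res.n_configurations == 1
        assert res.configurations[0].lineage == []

    def test_facing_amides_branch_into_two(self, table):
        res = run(make_structure("asn_asn"), table)
        assert res.n_configurations == 2
        # each branch resolved its partner: lineage has exactly one decision
        assert all(len(c.lineage) == 1 for c in res.configurations)
        idents = {
            tuple(c.assignments[k].rotamer_id for k in (("A", 1, ""), ("B", 2, "")))
            for c in res.configurations
        }
        assert idents == {(0, 0), (1, 1)}  # flips are correlated, not mixed

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_independent_pairs_multiply(self, table, k):
        res = run(make_structure("multi_pair", count=k), table)
        assert res.n_configurations == 2 ** k

    def test_oracle_cartesian_product(self, table):
        """Brute-force oracle: with no two ambiguous residues mutually
        proximal across units, the output equals the Cartesian product of
        per-residue within-cutoff state sets."""
        k = 3
        s = make_structure("multi_pair", count=k)
        res = run(s, table)
        # recompute each amide's within-cutoff set independently, against
        # its (resolved) hydroxyl partner
        ctx = prepare(make_structure("multi_pair", count=k), table)
        config = initialize(ctx)
        config, _ = evaluation_pass(ctx, config)  # resolves the hydroxyls
        per_residue = []
        amide_keys = [key for key in config.ambiguous_keys()]
        for key in amide_keys:
            r = ctx.structure.residue(key)
            scores = _scores_for(ctx, config, r)
            per_residue.append([
                st.identity for _, st, _ in scores.within_cutoff(ctx.cutoff)])
        expected = {
            combo for combo in itertools.product(*per_residue)
        }
        got = {
            tuple(c.assignments[k_].identity for k_ in amide_keys)
            for c in res.configurations
        }
        assert got == expected
        assert len(got) == 2 ** k

    def test_cutoff_monotonicity(self, table):
        for kind, kw in [("asn_ser", {}), ("asn_asn", {}),
                         ("asn_asn", {"offset": 0.4}), ("his_probe", {})]:
            s1 = make_structure(kind, **kw)
            s2 = make_structure(kind, **kw)
            n1 = run(s1, table, cutoff=1.0).n_configurations
            n2 = run(s2, table, cutoff=2.0).n_configurations
            assert n2 >= n1

    def test_output_bound(self, table):
        s = make_structure("asn_asn")
        res = run(s, table)
        assert res.n_configurations <= 2 * 2

    def test_determinism_byte_identical(self, table):
        outs = []
        for _ in range(2):
            s = make_structure("multi_pair", count=2)
            res = run(s, table)
            outs.append("".join(
                write_configuration(c, s) for c in res.configurations))
        assert outs[0] == outs[1]

    def test_branch_cap_enforced(self, table):
        from rapa import ResourceLimitError

        s = make_structure("multi_pair", count=3)
        with pytest.raises(ResourceLimitError):
            run(s, table, branch_cap=4)

    def test_his_double_probe_resolves_uniquely(self, table):
        s = make_structure("his_probe", donor=True)
        res = run(s, table)
        assert res.n_configurations == 1
        state = res.configurations[0].assignments[("A", 1, "")]
        assert state.protonation == "HID"
        assert state.rotamer_id == 0


class TestLabels:
    def test_isolated_asn_fully_solvated(self, table):
        res = run(make_structure("isolated", resname="ASN"), table)
        assert res.labels[("A", 1, "")] == "fully_solvated"

    def test_resolved_his_fixed(self, table):
        res = run(make_structure("his_probe", donor=True), table)
        assert res.labels[("A", 1, "")] == "fixed"

    def test_branched_amides_degenerate(self, table):
        res = run(make_structure("asn_asn"), table)
        assert res.labels[("A", 1, "")] == "degenerate"
        assert res.labels[("B", 2, "")] == "degenerate"

    def test_every_amide_and_his_labeled(self, table):
        s = make_structure("multi_pair", count=2)
        res = run(s, table)
        for r in s:
            if r.resname in ("ASN", "GLN", "HIS"):
                assert res.labels[r.key] in (
                    "fully_solvated", "fixed", "degenerate")


class TestWriteOutputs:
    def test_ambiguous_configuration_rejected(self, table):
        from rapa import ContractError

        s = make_structure("asn_asn")
        ctx = prepare(s, table)
        config = initialize(ctx)
        with pytest.raises(ContractError):
            write_configuration(config, s)

    def test_flipped_amide_written_with_swapped_heavy_atoms(self, table):
        s = make_structure("asn_asn")
        res = run(s, table)
        c0, c1 = res.configurations
        st0 = c0.assignments[("A", 1, "")]
        st1 = c1.assignments[("A", 1, "")]
        assert {st0.rotamer_id, st1.rotamer_id} == {0, 1}
        flipped = st0 if st0.rotamer_id == 1 else st1
        r = s.residue(("A", 1, ""))
        # the flipped OD1 equals the input OD1 rotated 180 deg about CB-CG
        from rapa.geometry import rotate_about_axis
        cb, cg = r.atom("CB").position, r.atom("CG").position
        expected = rotate_about_axis(r.atom("OD1").position, cb, cg - cb, 180.0)
        np.testing.assert_allclose(
            flipped.coord_overrides["OD1"], expected, atol=1e-9)

    def test_his_tautomer_resname_and_hydrogens(self, table):
        from rapa import read_structure

        s = make_structure("his_probe", donor=True)
        res = run(s, table)
        text = write_configuration(res.configurations[0], s)
        assert " HID " in text
        lines = [ln for ln in text.splitlines() if " HID " in ln]
        hnames = {ln[12:16].strip() for ln in lines if ln[76:78].strip() == "H"}
        assert "HD1" in hnames and "HE2" not in hnames
        # plain naming keeps HIS
        text2 = write_configuration(res.configurations[0], s, "plain")
        assert " HIS " in text2 and " HID " not in text2

    def test_report_and_summary(self, table):
        s = make_structure("asn_asn")
        res = run(s, table)
        report = write_report(res)
        assert "degenerate" in report
        assert report.startswith("chain\tseqnum\tresname")
        import json
        summary = json.loads(summary_json(res))
        assert summary["n_configurations"] == 2
        assert summary["cutoff"] == 1.0
        assert len(summary["branch_tree"]) == 2
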