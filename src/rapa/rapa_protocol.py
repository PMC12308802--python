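"""The recursive resolve-and-branch workflow.

Starting from a parsed structure the protocol (1) fixes everything
unambiguous (nonpolar residues, TRP/LYS/ARG, cysteines with or without a
disulfide bridge, lone ASP/GLU as charged carboxylates), (2) repeatedly
sweeps the remaining ambiguous residues in sequence order, fixing any
residue whose best RP state beats all alternatives by more than the
degeneracy cutoff, (3) when a sweep makes no progress, *branches*: the
first still-ambiguous residue is copied once per degenerate state, and
each branch is processed recursively, and (4) terminates when every
branch is fully assigned. Unique configurations are returned depth-first
with lower-energy children explored first, and every ASN/GLN/HIS residue
receives one of three labels: *fully_solvated* (no protein h-bond),
*fixed* (one clearly preferred state) or *degenerate* (several states
within the cutoff).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, IncompleteSideChainError, RapaError, ResourceLimitError
from .hbond_energetics import (
    EnergyTable,
    StateScores,
    best_state_energies,
    build_energy_table,
    residue_interactions,
)
from .state_enumeration import RPState, base_state, enumerate_states
from .structure_model import (
    CARBOXYLATE_ATOMS,
    NeighborGraph,
    Residue,
    ResidueKey,
    Structure,
    assign_polar_sites,
    build_neighbor_graph,
    detect_disulfides,
)

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 1.0          # kcal/mol degeneracy window
DEFAULT_PROXIMAL = 3.8        # A
DEFAULT_SS_THRESHOLD = 2.3    # A
DEFAULT_BRANCH_CAP = 4096


# ---------------------------------------------------------------------------
# configuration bookkeeping

@dataclass
class Configuration:
    """One branch of the search: per-residue status plus the states
    assigned so far. ``lineage`` records the branch decisions and uniquely
    identifies the branch."""

    assignments: dict[ResidueKey, RPState]
    statuses: dict[ResidueKey, str]
    lineage: list[tuple[ResidueKey, tuple]] = field(default_factory=list)

    def copy(self) -> "Configuration":
        return Configuration(dict(self.assignments), dict(self.statuses),
                             list(self.lineage))

    def ambiguous_keys(self) -> list[ResidueKey]:
        return [k for k, st in sorted(self.statuses.items()) if st == "ambiguous"]

    def assignment_identity(self) -> tuple:
        return tuple(
            (k, self.assignments[k].identity)
            for k in sorted(self.assignments)
        )


@dataclass
class ResidueDecision:
    key: ResidueKey
    resname: str
    n_states: int
    n_within_cutoff: int
    best_energy: float
    runner_up_gap: float | None
    fully_solvated: bool = False
    branched: bool = False


@dataclass
class RAPAResult:
    configurations: list[Configuration]
    labels: dict[ResidueKey, str]
    cutoff: float
    decisions: dict[ResidueKey, ResidueDecision]
    structure: Structure
    n_branch_events: int = 0

    @property
    def n_configurations(self) -> int:
        return len(self.configurations)


@dataclass
class ProtocolContext:
    structure: Structure
    table: EnergyTable
    graph: NeighborGraph
    cutoff: float
    states: dict[ResidueKey, list[RPState]]   # candidate states per ambiguous residue
    branch_cap: int = DEFAULT_BRANCH_CAP
    product_bound: int = 10 ** 6
    decisions: dict[ResidueKey, ResidueDecision] = field(default_factory=dict)
    n_branch_events: int = 0
    branched_on: set[ResidueKey] = field(default_factory=set)


# ---------------------------------------------------------------------------
# dyad detection

def detect_dyads(s: Structure, proximal: float = DEFAULT_PROXIMAL
                 ) -> list[tuple[ResidueKey, ResidueKey]]:
    """Pair ASP/GLU residues whose carboxylate oxygens come within the
    proximal threshold into acid dyads (closest pair first, each residue
    in at most one dyad). The first residue in sequence order controls
    the pair's protonation states."""
    acids = [r for r in s if r.resname in CARBOXYLATE_ATOMS]
    for r in acids:
        r.dyad_partner = None
        r.dyad_controller = False
    cand = []
    for i in range(len(acids)):
        a = acids[i]
        oa = [n for n in CARBOXYLATE_ATOMS[a.resname][1:] if a.has(n)]
        if len(oa) != 2:
            continue
        for j in range(i + 1, len(acids)):
            b = acids[j]
            ob = [n for n in CARBOXYLATE_ATOMS[b.resname][1:] if b.has(n)]
            if len(ob) != 2:
                continue
            d = min(float(np.linalg.norm(a.atom(x).position - b.atom(y).position))
                    for x in oa for y in ob)
            if d <= proximal:
                cand.append((d, a, b))
    cand.sort(key=lambda t: (t[0], t[1].key, t[2].key))
    pairs = []
    used: set[ResidueKey] = set()
    for d, a, b in cand:
        if a.key in used or b.key in used:
            continue
        first, second = sorted((a, b), key=lambda r: r.key)
        first.dyad_partner = second.key
        second.dyad_partner = first.key
        first.dyad_controller = True
        used.update((a.key, b.key))
        pairs.append((first.key, second.key))
    return pairs


# ---------------------------------------------------------------------------
# steps

def prepare(
    s: Structure,
    table: EnergyTable | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    proximal: float = DEFAULT_PROXIMAL,
    ss_threshold: float = DEFAULT_SS_THRESHOLD,
    branch_cap: int = DEFAULT_BRANCH_CAP,
    protonatable_acids: bool = False,
) -> ProtocolContext:
    """Type sites, detect disulfides and acid dyads, build the proximity
    graph and enumerate candidate states for every ambiguous residue."""
    if cutoff < 0 or proximal <= 0 or ss_threshold <= 0:
        raise ContractError("thresholds must be positive and cutoff >= 0")
    detect_disulfides(s, ss_threshold)
    detect_dyads(s, proximal)
    sites = assign_polar_sites(s)
    graph = build_neighbor_graph(sites, proximal, flip_aware=True)
    table = table if table is not None else build_energy_table()

    states: dict[ResidueKey, list[RPState]] = {}
    for r in s:
        if _is_ambiguous_type(r, protonatable_acids):
            r.set_ambiguous()
            try:
                states[r.key] = enumerate_states(r, s)
            except IncompleteSideChainError as exc:
                logger.warning("%s; residue forced known", exc)
                r.set_known()
    return ProtocolContext(structure=s, table=table, graph=graph,
                           cutoff=cutoff, states=states, branch_cap=branch_cap)


def _is_ambiguous_type(r: Residue, protonatable_acids: bool) -> bool:
    if r.resname in ("HIS", "ASN", "GLN", "SER", "THR", "TYR"):
        return True
    if r.resname in ("ASP", "GLU"):
        if r.dyad_partner is not None:
            return r.dyad_controller
        return protonatable_acids
    return False


def initialize(ctx: ProtocolContext) -> Configuration:
    """Step 1: every residue gets its input-equivalent base state; residues
    with rotamer or protonation ambiguity are marked ambiguous, everything
    else (nonpolar residues, TRP/LYS/ARG, cysteines, lone acids, dyad
    followers) is known from the start."""
    assignments = {}
    statuses = {}
    for r in ctx.structure:
        assignments[r.key] = base_state(ctx.structure, r)
        statuses[r.key] = r.status if r.key in ctx.states else "known"
    return Configuration(assignments=assignments, statuses=statuses)


def _scores_for(ctx: ProtocolContext, config: Configuration,
                r: Residue) -> StateScores:
    ambiguous = {
        k: ctx.states[k]
        for k in config.ambiguous_keys()
        if k != r.key
    }
    return best_state_energies(
        ctx.table, r, ctx.states[r.key], ctx.structure, ctx.graph,
        config.assignments, ambiguous, ctx.product_bound)


def _has_neighbors(ctx: ProtocolContext, r: Residue) -> bool:
    keys = [r.key] + ([r.dyad_partner] if r.dyad_controller else [])
    return any(ctx.graph.incident_edges(k, sidechain_only=True) for k in keys if k)


def evaluation_pass(ctx: ProtocolContext,
                    config: Configuration) -> tuple[Configuration, bool]:
    """Step 3: visit ambiguous residues in sequence order; fix each one
    whose best state beats every alternative by more than the cutoff.
    Residues fixed mid-pass are visible to later residues in the same
    pass. Residues with no proximal neighbors keep their input state and
    become known (fully solvated)."""
    changed = False
    for key in config.ambiguous_keys():
        r = ctx.structure.residue(key)
        if not _has_neighbors(ctx, r):
            config.assignments[key] = base_state(ctx.structure, r)
            config.statuses[key] = "known"
            ctx.decisions[key] = ResidueDecision(
                key, r.resname, len(ctx.states[key]), 1,
                0.0, None, fully_solvated=True)
            changed = True
            logger.debug("%s %s: fully solvated, input state kept", r.resname, key)
            continue
        scores = _scores_for(ctx, config, r)
        within = scores.within_cutoff(ctx.cutoff)
        best_i, best_state_, best_e = min(
            ((i, st, e) for i, st, e in within), key=lambda t: t[2])
        others = sorted(e for i, e in enumerate(scores.scores) if i != best_i)
        gap = (others[0] - best_e) if others else None
        ctx.decisions[key] = ResidueDecision(
            key, r.resname, len(scores.states), len(within), best_e, gap)
        logger.debug("%s %s: scores=%s within_cutoff=%d", r.resname, key,
                     [round(e, 3) for e in scores.scores], len(within))
        if len(within) == 1:
            config.assignments[key] = best_state_
            config.statuses[key] = "known"
            changed = True
    return config, changed


def branch(ctx: ProtocolContext,
           config: Configuration) -> list[Configuration]:
    """Step 5: copy the configuration once per degenerate state of the
    first ambiguous residue in sequence order (states above the cutoff
    are discarded), lowest-energy child first."""
    for key in config.ambiguous_keys():
        r = ctx.structure.residue(key)
        scores = _scores_for(ctx, config, r)
        within = scores.within_cutoff(ctx.cutoff)
        if len(within) < 2:
            raise RapaError(
                f"internal error: branch reached but {r.resname} {key} "
                "is not degenerate")
        within.sort(key=lambda t: (t[2], t[0]))
        children = []
        for i, st, e in within:
            child = config.copy()
            child.assignments[key] = st
            child.statuses[key] = "known"
            child.lineage.append((key, st.identity))
            children.append(child)
        ctx.n_branch_events += 1
        ctx.branched_on.add(key)
        d = ctx.decisions.get(key)
        if d is not None:
            d.branched = True
        logger.debug("branching %s %s into %d children", r.resname, key, len(within))
        return children
    raise RapaError("branch called with no ambiguous residues")


def run(
    s: Structure,
    table: EnergyTable | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    proximal: float = DEFAULT_PROXIMAL,
    ss_threshold: float = DEFAULT_SS_THRESHOLD,
    branch_cap: int = DEFAULT_BRANCH_CAP,
    protonatable_acids: bool = False,
) -> RAPAResult:
    """Execute the full workflow and return the unique, fully-assigned
    configurations (depth-first, lower-energy branches first) together
    with per-residue labels. Deterministic: identical input yields an
    identical configuration list."""
    ctx = prepare(s, table, cutoff, proximal, ss_threshold, branch_cap,
                  protonatable_acids)
    root = initialize(ctx)
    done: list[Configuration] = []

    def process(config: Configuration) -> None:
        while True:
            if not config.ambiguous_keys():
                done.append(config)
                if len(done) > ctx.branch_cap:
                    raise ResourceLimitError(
                        f"more than {ctx.branch_cap} configurations; "
                        f"branched residues: {sorted(ctx.branched_on)}")
                return
            config, changed = evaluation_pass(ctx, config)
            if not changed:
                break
        for child in branch(ctx, config):
            process(child)

    process(root)

    unique: list[Configuration] = []
    seen: set[tuple] = set()
    for c in done:
        ident = c.assignment_identity()
        if ident not in seen:
            seen.add(ident)
            unique.append(c)

    labels = label_residues(ctx, unique)
    for r in ctx.structure:
        if r.key in labels:
            r.label = labels[r.key]
    return RAPAResult(configurations=unique, labels=labels, cutoff=cutoff,
                      decisions=ctx.decisions, structure=s,
                      n_branch_events=ctx.n_branch_events)


def label_residues(ctx: ProtocolContext,
                   configurations: list[Configuration]) -> dict[ResidueKey, str]:
    """Label each ASN/GLN/HIS residue: *fully_solvated* if it makes no
    h-bond with the protein, *degenerate* if several of its RP states were
    within the cutoff (it was branched on, or its assignment differs
    across the output configurations), otherwise *fixed*."""
    labels: dict[ResidueKey, str] = {}
    ref = configurations[0] if configurations else None
    for r in ctx.structure:
        if r.resname not in ("ASN", "GLN", "HIS"):
            continue
        d = ctx.decisions.get(r.key)
        if d is not None and d.fully_solvated:
            labels[r.key] = "fully_solvated"
            continue
        if ref is not None and not _makes_hbond(ctx, r, ref):
            labels[r.key] = "fully_solvated"
            continue
        differs = len({
            c.assignments[r.key].identity for c in configurations
        }) > 1 if configurations else False
        if r.key in ctx.branched_on or differs:
            labels[r.key] = "degenerate"
        else:
            labels[r.key] = "fixed"
    return labels


def _makes_hbond(ctx: ProtocolContext, r: Residue, config: Configuration) -> bool:
    if not _has_neighbors(ctx, r):
        return False
    recs = residue_interactions(ctx.table, r, ctx.structure, ctx.graph,
                                config.assignments)
    return any(rec.kind == "hbond" and rec.energy < 0.0 for rec in recs)


# ---------------------------------------------------------------------------
# reporting

def write_report(result: RAPAResult) -> str:
    """TSV label report: one row per ASN/GLN/HIS or dyad-member residue."""
    rows = ["chain\tseqnum\tresname\tlabel\tn_states_within_cutoff\t"
            "best_energy\trunner_up_gap"]
    for r in result.structure:
        is_dyad = r.dyad_partner is not None
        if r.resname not in ("ASN", "GLN", "HIS") and not is_dyad:
            continue
        d = result.decisions.get(r.key)
        label = result.labels.get(r.key, "dyad" if is_dyad else "unset")
        n_within = d.n_within_cutoff if d else ""
        best = f"{d.best_energy:.4f}" if d else ""
        gap = (f"{d.runner_up_gap:.4f}"
               if d and d.runner_up_gap is not None else "")
        rows.append(f"{r.chain}\t{r.seqnum}\t{r.resname}\t{label}\t"
                    f"{n_within}\t{best}\t{gap}")
    return "\n".join(rows) + "\n"


def summary_json(result: RAPAResult) -> str:
    """JSON run summary: configuration count, cutoff and the branch tree
    (one lineage per output configuration)."""
    payload = {
        "n_configurations": result.n_configurations,
        "cutoff": result.cutoff,
        "n_branch_events": result.n_branch_events,
        "branch_tree": [
            [
                {"residue": list(key), "state": _identity_json(ident)}
                for key, ident in c.lineage
            ]
            for c in result.configurations
        ],
        "labels": {
            "{}{}{}".format(k[0], k[1], k[2]): v
            for k, v in sorted(result.labels.items())
        },
    }
    return json.dumps(payload, indent=2)


def _identity_json(ident: tuple):
    return [list(x) if isinstance(x, tuple) else x for x in ident]
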