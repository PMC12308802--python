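"""Hydrogen-bond / clash energetics on a tabulated distance-angle surface.

The energy table covers heavy-atom--heavy-atom distances 2.5-4.0 A in
0.1 A steps and donor (hv-H-hv) angles 90-180 deg in 0.1 deg steps, the
geometry proxy used for scoring all local polar interactions. The table
is generated from an analytic water-dimer-like model

    E(d, theta) = W * [1 - (1 - exp(-a (d - d0)))^2] * cos^2(180 - theta)

with well depth W = -5.0 kcal/mol at the equilibrium distance
d0 = 2.8 A and radial steepness a = 1.8 1/A: a Morse-like radial well
multiplied by an angular factor that vanishes smoothly at 90 degrees.
Users may substitute their own quantum-chemistry-derived table via the
TSV format handled by :func:`save_table` / :func:`load_table`.

An electrostatic clash (donor facing donor, or acceptor facing acceptor)
is scored as the *negative* of the h-bond energy at the same geometry.
Lookups are nearest-grid-point (no interpolation); at the grid resolution
the discretization error is negligible relative to the 1 kcal/mol
degeneracy cutoff.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, ResourceLimitError
from .state_enumeration import RPState
from .structure_model import (
    NeighborGraph,
    PolarSite,
    Residue,
    ResidueKey,
    Structure,
)

DEFAULT_WELL_DEPTH = -5.0   # kcal/mol at (2.8 A, 180 deg)
DEFAULT_EQ_DISTANCE = 2.8   # A
DEFAULT_STEEPNESS = 1.8     # 1/A


# ---------------------------------------------------------------------------
# energy table

@dataclass
class EnergyTable:
    distances: np.ndarray       # (16,)  2.5..4.0 step 0.1
    angles: np.ndarray          # (901,) 90..180 step 0.1
    energies: np.ndarray        # (16, 901) kcal/mol, favorable negative
    params: dict = field(default_factory=dict)

    @property
    def d_step(self) -> float:
        return float(self.distances[1] - self.distances[0])

    @property
    def a_step(self) -> float:
        return float(self.angles[1] - self.angles[0])


def build_energy_table(
    well_depth: float = DEFAULT_WELL_DEPTH,
    eq_distance: float = DEFAULT_EQ_DISTANCE,
    steepness: float = DEFAULT_STEEPNESS,
) -> EnergyTable:
    """Tabulate the analytic h-bond surface on the standard grid."""
    distances = np.round(np.arange(2.5, 4.0 + 1e-9, 0.1), 10)
    angles = np.round(np.arange(90.0, 180.0 + 1e-9, 0.1), 10)
    radial = 1.0 - (1.0 - np.exp(-steepness * (distances - eq_distance))) ** 2
    angular = np.cos(np.radians(180.0 - angles)) ** 2
    energies = well_depth * np.outer(radial, angular)
    return EnergyTable(
        distances=distances, angles=angles, energies=energies,
        params={"well_depth": well_depth, "eq_distance": eq_distance,
                "steepness": steepness},
    )


def lookup_energy(t: EnergyTable, d: float, theta: float) -> float:
    """Nearest-grid-point energy lookup.

    Distances beyond the table (d > 4.0 A) and angles below 90 deg score
    zero (no interaction); distances below 2.5 A clamp to the closest row,
    angles above 180 deg clamp to the 180 column.
    """
    dmax = float(t.distances[-1])
    if d > dmax + 0.5 * t.d_step or theta < float(t.angles[0]) - 0.5 * t.a_step:
        return 0.0
    # half-up rounding (plus a float-noise guard) so midpoints go to the
    # farther grid line
    i = int(np.clip(np.floor((d - t.distances[0]) / t.d_step + 0.5 + 1e-9),
                    0, len(t.distances) - 1))
    j = int(np.clip(np.floor((theta - t.angles[0]) / t.a_step + 0.5 + 1e-9),
                    0, len(t.angles) - 1))
    return float(t.energies[i, j])


def save_table(t: EnergyTable, path: str) -> None:
    """Write the table as TSV: a header comment with the grid definition
    and well depth, then one row of energies per distance."""
    with open(path, "w") as fh:
        fh.write("# dmin dmax dstep amin amax astep well_depth\n")
        fh.write("# {:g} {:g} {:g} {:g} {:g} {:g} {:g}\n".format(
            t.distances[0], t.distances[-1], t.d_step,
            t.angles[0], t.angles[-1], t.a_step,
            t.params.get("well_depth", float(t.energies.min()))))
        for row in t.energies:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def load_table(path: str) -> EnergyTable:
    with open(path) as fh:
        lines = fh.read().splitlines()
    grid = [float(x) for x in lines[1].lstrip("# ").split()]
    dmin, dmax, dstep, amin, amax, astep, well = grid
    distances = np.round(np.arange(dmin, dmax + 1e-9, dstep), 10)
    angles = np.round(np.arange(amin, amax + 1e-9, astep), 10)
    rows = [np.array([float(v) for v in ln.split("\t")])
            for ln in lines[2:] if ln.strip()]
    energies = np.vstack(rows)
    if energies.shape != (len(distances), len(angles)):
        raise ContractError(
            f"table shape {energies.shape} does not match its header grid")
    return EnergyTable(distances=distances, angles=angles, energies=energies,
                       params={"well_depth": well})


# ---------------------------------------------------------------------------
# role resolution

@dataclass
class InteractionRecord:
    site_a: PolarSite
    site_b: PolarSite
    kind: str        # hbond | clash | none
    distance: float
    angle: float
    energy: float


def _controller_state(r: Residue, s: Structure,
                      states: dict[ResidueKey, RPState]) -> RPState | None:
    key = r.key if r.dyad_controller else r.dyad_partner
    return states.get(key)


def site_roles(site: PolarSite, s: Structure,
               states: dict[ResidueKey, RPState]) -> list[str]:
    """Effective role(s) of a polar site given the assigned states."""
    r = s.residue(site.residue_key)
    state = states.get(site.residue_key)
    if r.resname == "HIS" and site.atom_name in ("ND1", "NE2"):
        prot = state.protonation if state is not None and state.protonation else "HIE"
        if site.atom_name == "ND1":
            return ["donor"] if prot in ("HID", "HIP") else ["acceptor"]
        return ["donor"] if prot in ("HIE", "HIP") else ["acceptor"]
    if r.resname in ("ASP", "GLU") and site.atom_name[0] == "O" and not site.is_backbone:
        if r.dyad_partner is not None:
            cs = _controller_state(r, s, states)
            if (cs is not None and cs.dyad_proton is not None
                    and cs.dyad_proton == (r.key, site.atom_name)):
                return ["donor"]
        return ["acceptor"]
    if site.role == "donor_or_acceptor":
        if state is not None and state.hydroxyl_role is not None:
            return [state.hydroxyl_role]
        return ["donor", "acceptor"]
    return [site.role]


def _donor_candidates(site: PolarSite, r: Residue, s: Structure,
                      states: dict[ResidueKey, RPState]) -> list[np.ndarray]:
    state = states.get(site.residue_key)
    if r.resname in ("ASP", "GLU") and r.dyad_partner is not None:
        cs = _controller_state(r, s, states)
        if (cs is not None and cs.dyad_proton == (r.key, site.atom_name)
                and cs.dyad_hydrogen is not None):
            return [cs.dyad_hydrogen]
    if state is not None:
        cands = state.hydrogen_placements.get(site.atom_name)
        if cands:
            return cands
    from .state_enumeration import donor_hydrogen_candidates
    return donor_hydrogen_candidates(s, r, site.atom_name,
                                     state.coord_overrides if state else None)


def _site_position(site: PolarSite, r: Residue,
                   states: dict[ResidueKey, RPState]) -> np.ndarray:
    state = states.get(site.residue_key)
    if state is not None and site.atom_name in state.coord_overrides:
        return state.coord_overrides[site.atom_name]
    return site.position


# ---------------------------------------------------------------------------
# pairwise scoring

def _angle_at(h: np.ndarray, pa: np.ndarray, pb: np.ndarray) -> float:
    from .geometry import angle_deg
    return angle_deg(pa, h, pb)


def pair_energy(
    t: EnergyTable,
    site_a: PolarSite,
    site_b: PolarSite,
    s: Structure,
    states: dict[ResidueKey, RPState],
) -> InteractionRecord:
    """Score one proximal site pair under the given state assignment.

    donor/acceptor -> h-bond using the donor hydrogen candidate closest to
    the acceptor (shortest H...acceptor distance), angle measured
    donor-heavy - H - acceptor-heavy. donor/donor -> clash: each donor
    aims its best hydrogen at the other; the more unfavorable of the two
    inverted energies is kept. acceptor/acceptor -> clash at the
    heavy-atom distance with the angle fixed at 180 deg (no carrier
    hydrogen exists, so the maximally penalizing angle is used).
    Dual-role sites are tried in every allowed role and the lowest-energy
    outcome is kept.
    """
    ra = s.residue(site_a.residue_key)
    rb = s.residue(site_b.residue_key)
    pa = _site_position(site_a, ra, states)
    pb = _site_position(site_b, rb, states)
    d = float(np.linalg.norm(pa - pb))

    roles_a = site_roles(site_a, s, states)
    roles_b = site_roles(site_b, s, states)

    best: InteractionRecord | None = None
    for role_a in roles_a:
        for role_b in roles_b:
            rec = _score_pair(t, site_a, site_b, ra, rb, pa, pb, d,
                              role_a, role_b, s, states)
            if rec is None:
                continue
            if best is None or rec.energy < best.energy:
                best = rec
    if best is None:
        best = InteractionRecord(site_a, site_b, "none", d, 0.0, 0.0)
    if best.energy == 0.0:
        best = InteractionRecord(site_a, site_b, "none", d, best.angle, 0.0)
    return best


def _score_pair(t, site_a, site_b, ra, rb, pa, pb, d, role_a, role_b,
                s, states) -> InteractionRecord | None:
    if role_a == "donor" and role_b == "acceptor":
        return _hbond(t, site_a, site_b, ra, pa, pb, d, s, states, donor_first=True)
    if role_a == "acceptor" and role_b == "donor":
        return _hbond(t, site_b, site_a, rb, pb, pa, d, s, states, donor_first=False)
    if role_a == "donor" and role_b == "donor":
        recs = []
        for dsite, dres, dpos, apos in ((site_a, ra, pa, pb), (site_b, rb, pb, pa)):
            cands = _donor_candidates(dsite, dres, s, states)
            if not cands:
                continue
            h = min(cands, key=lambda x: float(np.linalg.norm(x - apos)))
            theta = _angle_at(h, dpos, apos)
            recs.append((theta, -lookup_energy(t, d, theta)))
        if not recs:
            return None
        theta, energy = max(recs, key=lambda x: x[1])
        return InteractionRecord(site_a, site_b, "clash", d, theta, energy)
    if role_a == "acceptor" and role_b == "acceptor":
        energy = -lookup_energy(t, d, 180.0)
        return InteractionRecord(site_a, site_b, "clash", d, 180.0, energy)
    return None


def _hbond(t, donor_site, acceptor_site, donor_res, dpos, apos, d,
           s, states, donor_first) -> InteractionRecord | None:
    cands = _donor_candidates(donor_site, donor_res, s, states)
    if not cands:
        return None
    h = min(cands, key=lambda x: float(np.linalg.norm(x - apos)))
    theta = _angle_at(h, dpos, apos)
    energy = lookup_energy(t, d, theta)
    a, b = (donor_site, acceptor_site) if donor_first else (acceptor_site, donor_site)
    return InteractionRecord(a, b, "hbond", d, theta, energy)


# ---------------------------------------------------------------------------
# environment scoring

def _scope_keys(r: Residue) -> list[ResidueKey]:
    """Residues whose side-chain sites are controlled by r's state: r
    itself, plus the dyad partner when r controls an acid dyad."""
    keys = [r.key]
    if r.dyad_controller and r.dyad_partner is not None:
        keys.append(r.dyad_partner)
    return keys


def residue_interactions(
    t: EnergyTable,
    r: Residue,
    s: Structure,
    graph: NeighborGraph,
    states: dict[ResidueKey, RPState],
) -> list[InteractionRecord]:
    """All scored interactions incident to r's side-chain polar sites
    (and its dyad partner's, when r controls a dyad)."""
    records = []
    seen: set[tuple[int, int]] = set()
    for key in _scope_keys(r):
        for i, j, _ in graph.incident_edges(key, sidechain_only=True):
            if (i, j) in seen:
                continue
            seen.add((i, j))
            a, b = graph.sites[i], graph.sites[j]
            other = b.residue_key if a.residue_key in _scope_keys(r) else a.residue_key
            if other not in states:
                raise ContractError(
                    f"no state assigned for proximal residue {other}")
            records.append(pair_energy(t, a, b, s, states))
    return records


def environment_energy(
    t: EnergyTable,
    r: Residue,
    state: RPState,
    neighbor_assignment: dict[ResidueKey, RPState],
    s: Structure,
    graph: NeighborGraph,
) -> float:
    """Total local energy of residue r in the given state: the sum of all
    pairwise interactions over proximal-graph edges incident to its
    side-chain polar sites, with neighbors in their assigned states."""
    states = dict(neighbor_assignment)
    states[r.key] = state
    return sum(rec.energy
               for rec in residue_interactions(t, r, s, graph, states))


def environment_variants(residue: Residue, states: list[RPState]) -> list[RPState]:
    """Expand a neighbor's state list into the variants it presents to an
    environment: hydroxyl/thiol residues offer their single geometric state
    in each of the two roles (donor / acceptor); everything else offers its
    RP states unchanged."""
    if residue.resname in ("SER", "THR", "TYR", "CYS"):
        out = []
        for st in states:
            for role in ("donor", "acceptor"):
                v = RPState(
                    residue_key=st.residue_key, rotamer_id=st.rotamer_id,
                    protonation=st.protonation,
                    coord_overrides=st.coord_overrides,
                    hydrogen_placements=st.hydrogen_placements,
                    hydroxyl_role=role,
                )
                out.append(v)
        return out
    return states


@dataclass
class StateScores:
    """Per-state best environment energies of one residue."""
    states: list[RPState]
    scores: list[float]
    n_environments: int

    def best(self) -> tuple[RPState, float]:
        i = int(np.argmin(self.scores))
        return self.states[i], self.scores[i]

    def within_cutoff(self, cutoff: float) -> list[tuple[int, RPState, float]]:
        emin = min(self.scores)
        return [(i, st, e) for i, (st, e) in enumerate(zip(self.states, self.scores))
                if e <= emin + cutoff]


def best_state_energies(
    t: EnergyTable,
    r: Residue,
    self_states: list[RPState],
    s: Structure,
    graph: NeighborGraph,
    assignment: dict[ResidueKey, RPState],
    ambiguous_neighbor_states: dict[ResidueKey, list[RPState]],
    product_bound: int = 10 ** 6,
) -> StateScores:
    """Score each candidate state of r against every combination of its
    proximal ambiguous neighbors' states (known neighbors contribute their
    fixed assignment): score(s) = min over the neighbor-state product of
    the environment energy. The full map is returned for degeneracy
    analysis."""
    nb_keys = sorted(
        set(
            k
            for key in _scope_keys(r)
            for k in graph.residue_neighbors(key)
            if k not in _scope_keys(r)
        )
    )
    variant_lists: list[list[RPState]] = []
    variant_keys: list[ResidueKey] = []
    for k in nb_keys:
        if k in ambiguous_neighbor_states:
            nbres = s.residue(k)
            variant_keys.append(k)
            variant_lists.append(
                environment_variants(nbres, ambiguous_neighbor_states[k]))
        elif k not in assignment:
            raise ContractError(f"proximal residue {k} has no assignment")
        else:
            # a fixed hydroxyl/thiol whose proton direction is still free
            # presents both roles, exactly as it did while ambiguous, so
            # scores are stable across passes
            nbres = s.residue(k)
            fixed = assignment[k]
            if (nbres.resname in ("SER", "THR", "TYR", "CYS")
                    and fixed.hydroxyl_role is None
                    and nbres.disulfide_partner is None):
                variant_keys.append(k)
                variant_lists.append(environment_variants(nbres, [fixed]))
        # dyad followers among neighbors: their roles resolve through the
        # controller, which appears in assignment or the ambiguous lists.
    n_product = int(np.prod([len(v) for v in variant_lists])) if variant_lists else 1
    if n_product * max(len(self_states), 1) > product_bound:
        raise ResourceLimitError(
            f"environment product {n_product} x {len(self_states)} states for "
            f"{r.resname} {r.key} exceeds the bound {product_bound}")

    scores: list[float] = []
    n_env = 0
    for st in self_states:
        best = np.inf
        for combo in itertools.product(*variant_lists) if variant_lists else [()]:
            env = dict(assignment)
            for k, v in zip(variant_keys, combo):
                env[k] = v
            e = environment_energy(t, r, st, env, s, graph)
            n_env += 1
            if e < best:
                best = e
        scores.append(float(best))
    return StateScores(states=list(self_states), scores=scores,
                       n_environments=n_env)
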