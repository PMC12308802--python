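"""Enumeration of rotamer/protonation (RP) states for ambiguous residues.

Ambiguity classes and their state counts:

* HIS — 6 states: 2 imidazole rotamers (180 deg flip about CB-CG) x 3
  protonation states (HID: Nd1-H, HIE: Ne1-H, HIP: both, +1).
* ASN / GLN — 2 states: the terminal amide flipped 180 deg about its
  C-C bond axis (chi2 for ASN, chi3 for GLN).
* SER / THR — 1 state carrying 9 candidate hydroxyl hydrogen positions
  (three sp3-staggered dihedrals and +/-20 deg around each).
* TYR — 1 state carrying the 2 trigonal-planar (sp2) hydroxyl positions.
* ASP / GLU in an acid dyad — the controlling residue of the pair carries
  4 singly-protonated states (one per carboxylate oxygen) plus the
  doubly-deprotonated reference; outside a dyad they are fixed
  deprotonated.

Flips are implemented as rigid 180-degree rotations (not atom-name swaps)
so distorted experimental geometry is preserved; applying a flip twice
restores the original coordinates exactly.

Polar hydrogens are always placed at idealized geometry: N-H 1.01 A,
O-H 0.96 A, S-H 1.34 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, IncompleteSideChainError
from .geometry import place_atom, rotate_about_axis, unit
from .structure_model import (
    CARBOXYLATE_ATOMS,
    Residue,
    ResidueKey,
    Structure,
)

NH_BOND = 1.01
OH_BOND = 0.96
SH_BOND = 1.34

AMBIGUOUS_RESNAMES = {"HIS", "ASN", "GLN", "SER", "THR", "TYR"}

HIS_PROTONATIONS = ("HID", "HIE", "HIP")


# ---------------------------------------------------------------------------
# domain types

@dataclass
class RPState:
    """One rotamer/protonation variant of a residue.

    ``coord_overrides`` maps heavy-atom names to flipped positions;
    ``hydrogen_placements`` maps donor heavy-atom names to candidate
    hydrogen positions (several for hydroxyls/amines, one otherwise).
    For acid-dyad states, ``dyad_proton`` names the single protonated
    carboxylate oxygen — possibly on the partner residue — and
    ``dyad_hydrogen`` its position.
    """

    residue_key: ResidueKey
    rotamer_id: int = 0
    protonation: str = ""
    coord_overrides: dict[str, np.ndarray] = field(default_factory=dict)
    hydrogen_placements: dict[str, list[np.ndarray]] = field(default_factory=dict)
    hydroxyl_role: str | None = None        # None = free, else donor|acceptor
    dyad_proton: tuple[ResidueKey, str] | None = None
    dyad_hydrogen: np.ndarray | None = None

    @property
    def identity(self) -> tuple:
        return (self.residue_key, self.rotamer_id, self.protonation,
                self.dyad_proton, self.hydroxyl_role)

    def position_of(self, residue: Residue, atom_name: str) -> np.ndarray:
        if atom_name in self.coord_overrides:
            return self.coord_overrides[atom_name]
        return residue.atom(atom_name).position


@dataclass
class DyadState:
    """One singly-protonated configuration of an ASP/GLU acid dyad."""

    pair: tuple[ResidueKey, ResidueKey]
    protonated_oxygen: tuple[ResidueKey, str]
    hydrogen: np.ndarray


# ---------------------------------------------------------------------------
# flips

def _rigid_flip(r: Residue, origin_name: str, axis_end_name: str,
                moved: tuple[str, ...]) -> dict[str, np.ndarray]:
    for name in (origin_name, axis_end_name, *moved):
        if not r.has(name):
            raise IncompleteSideChainError(
                f"{r.resname} {r.key}: missing atom {name!r} for flip")
    origin = r.atom(origin_name).position
    axis = r.atom(axis_end_name).position - origin
    return {
        name: rotate_about_axis(r.atom(name).position, origin, axis, 180.0)
        for name in moved
    }


def flip_amide(r: Residue) -> dict[str, np.ndarray]:
    """180-degree rigid rotation of the terminal amide of ASN (about CB-CG)
    or GLN (about CG-CD). The carbonyl O and amide N exchange positions for
    ideal geometry; distorted geometry is carried along rigidly."""
    if r.resname == "ASN":
        return _rigid_flip(r, "CB", "CG", ("OD1", "ND2"))
    if r.resname == "GLN":
        return _rigid_flip(r, "CG", "CD", ("OE1", "NE2"))
    raise ContractError(f"flip_amide expects ASN/GLN, got {r.resname}")


def flip_imidazole(r: Residue) -> dict[str, np.ndarray]:
    """180-degree rigid rotation of the HIS imidazole about CB-CG;
    ND1<->CD2 and CE1<->NE2 exchange positions for ideal geometry."""
    if r.resname != "HIS":
        raise ContractError(f"flip_imidazole expects HIS, got {r.resname}")
    return _rigid_flip(r, "CB", "CG", ("ND1", "CD2", "CE1", "NE2"))


# ---------------------------------------------------------------------------
# hydrogen placement

def _bisector_h(center: np.ndarray, n1: np.ndarray, n2: np.ndarray,
                bond: float) -> np.ndarray:
    """In-plane hydrogen on the outward bisector of two bonded neighbors."""
    d = -(unit(n1 - center) + unit(n2 - center))
    return center + bond * unit(d)


def _amide_hydrogens(c: np.ndarray, o: np.ndarray, n: np.ndarray) -> list[np.ndarray]:
    """Two in-plane hydrogens on a primary amide nitrogen (C-N-H 120 deg)."""
    u = unit(n - c)
    nrm = unit(np.cross(o - c, u))
    p = np.cross(nrm, u)
    cos60, sin60 = np.cos(np.radians(60.0)), np.sin(np.radians(60.0))
    return [
        n + NH_BOND * (cos60 * u + sin60 * p),
        n + NH_BOND * (cos60 * u - sin60 * p),
    ]


def _staggered_hydrogens(a: np.ndarray, b: np.ndarray, x: np.ndarray,
                         bond: float, angle: float,
                         dihedrals: tuple[float, ...]) -> list[np.ndarray]:
    return [place_atom(a, b, x, bond, angle, d) for d in dihedrals]


def hydroxy_hydrogen_positions(r: Residue) -> list[np.ndarray]:
    """Candidate hydroxyl hydrogen positions.

    SER/THR: 9 positions — H-O-C-C(antecedent) dihedrals 60/180/-60 deg
    (sp3 staggered) each with -20/0/+20 deg offsets; O-H 0.96 A,
    C-O-H 109.5 deg. TYR: the 2 in-plane sp2 positions (dihedral 0 and
    180 deg against CE1, C-O-H 120 deg).
    """
    if r.resname in ("SER", "THR"):
        oname = "OG" if r.resname == "SER" else "OG1"
        for need in ("CA", "CB", oname):
            if not r.has(need):
                raise IncompleteSideChainError(f"{r.resname} {r.key}: missing {need}")
        dihedrals = tuple(base + off for base in (60.0, 180.0, -60.0)
                          for off in (-20.0, 0.0, 20.0))
        return _staggered_hydrogens(
            r.atom("CA").position, r.atom("CB").position, r.atom(oname).position,
            OH_BOND, 109.5, dihedrals)
    if r.resname == "TYR":
        for need in ("CE1", "CZ", "OH"):
            if not r.has(need):
                raise IncompleteSideChainError(f"TYR {r.key}: missing {need}")
        return _staggered_hydrogens(
            r.atom("CE1").position, r.atom("CZ").position, r.atom("OH").position,
            OH_BOND, 120.0, (0.0, 180.0))
    raise ContractError(f"hydroxy positions defined for SER/THR/TYR, not {r.resname}")


def donor_hydrogen_candidates(
    s: Structure, r: Residue, atom_name: str,
    overrides: dict[str, np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Idealized hydrogen candidate positions for a donor-capable heavy
    atom, honoring flipped coordinates in ``overrides``."""
    overrides = overrides or {}

    def pos(name: str) -> np.ndarray:
        return overrides.get(name, r.atom(name).position)

    rn = r.resname
    if atom_name == "N":
        n = pos("N")
        prev_c = s.prev_c(r)
        if prev_c is not None and r.has("CA"):
            return [_bisector_h(n, prev_c, pos("CA"), NH_BOND)]
        if r.has("CA"):
            return [n + NH_BOND * unit(n - pos("CA"))]
        return []
    if rn == "ASN" and atom_name == "ND2":
        return _amide_hydrogens(pos("CG"), pos("OD1"), pos("ND2"))
    if rn == "GLN" and atom_name == "NE2":
        return _amide_hydrogens(pos("CD"), pos("OE1"), pos("NE2"))
    if rn == "HIS" and atom_name == "ND1":
        return [_bisector_h(pos("ND1"), pos("CG"), pos("CE1"), NH_BOND)]
    if rn == "HIS" and atom_name == "NE2":
        return [_bisector_h(pos("NE2"), pos("CD2"), pos("CE1"), NH_BOND)]
    if rn in ("SER", "THR", "TYR"):
        return hydroxy_hydrogen_positions(r)
    if rn == "CYS" and atom_name == "SG":
        return _staggered_hydrogens(pos("CA"), pos("CB"), pos("SG"),
                                    SH_BOND, 96.0, (60.0, 180.0, -60.0))
    if rn == "LYS" and atom_name == "NZ":
        return _staggered_hydrogens(pos("CD"), pos("CE"), pos("NZ"),
                                    NH_BOND, 109.5, (60.0, 180.0, -60.0))
    if rn == "ARG" and atom_name == "NE":
        return [_bisector_h(pos("NE"), pos("CD"), pos("CZ"), NH_BOND)]
    if rn == "ARG" and atom_name in ("NH1", "NH2"):
        other = "NH2" if atom_name == "NH1" else "NH1"
        return _amide_hydrogens(pos("CZ"), pos(other), pos(atom_name))
    if rn == "TRP" and atom_name == "NE1":
        return [_bisector_h(pos("NE1"), pos("CD1"), pos("CE2"), NH_BOND)]
    return []


def _donor_atoms_for_state(r: Residue, protonation: str) -> list[str]:
    """Heavy atoms that actually carry a hydrogen in the given state."""
    rn = r.resname
    out: list[str] = []
    if r.has("N") and rn != "PRO":
        out.append("N")
    if rn == "ASN":
        out.append("ND2")
    elif rn == "GLN":
        out.append("NE2")
    elif rn == "HIS":
        if protonation in ("HID", "HIP"):
            out.append("ND1")
        if protonation in ("HIE", "HIP"):
            out.append("NE2")
    elif rn == "SER":
        out.append("OG")
    elif rn == "THR":
        out.append("OG1")
    elif rn == "TYR":
        out.append("OH")
    elif rn == "CYS" and r.disulfide_partner is None:
        out.append("SG")
    elif rn == "LYS":
        out.append("NZ")
    elif rn == "ARG":
        out.extend(["NE", "NH1", "NH2"])
    elif rn == "TRP":
        out.append("NE1")
    return [a for a in out if r.has(a) or a == "N"]


def _build_state(
    s: Structure, r: Residue, rotamer_id: int, protonation: str,
    overrides: dict[str, np.ndarray] | None = None, **kw,
) -> RPState:
    overrides = overrides or {}
    hpl: dict[str, list[np.ndarray]] = {}
    for heavy in _donor_atoms_for_state(r, protonation):
        try:
            cands = donor_hydrogen_candidates(s, r, heavy, overrides)
        except (KeyError, IncompleteSideChainError):
            cands = []
        if cands:
            hpl[heavy] = cands
    # HIS: also keep candidates for the deprotonated ring nitrogen so that
    # role resolution never needs them but inspection tools can show them.
    return RPState(residue_key=r.key, rotamer_id=rotamer_id,
                   protonation=protonation, coord_overrides=dict(overrides),
                   hydrogen_placements=hpl, **kw)


def base_state(s: Structure, r: Residue) -> RPState:
    """The input-equivalent state of a residue (rotamer 0, default or
    input-derived protonation), with idealized hydrogens on every fixed
    donor. Used for residues that are known from initialization and for
    fully-solvated residues, which keep their input assignment."""
    protonation = ""
    if r.resname == "HIS":
        protonation = _input_his_tautomer(r)
    return _build_state(s, r, 0, protonation)


def _input_his_tautomer(r: Residue) -> str:
    if r.input_resname in ("HID", "HSD"):
        return "HID"
    if r.input_resname in ("HIP", "HSP"):
        return "HIP"
    has_hd1 = r.has("HD1")
    has_he2 = r.has("HE2")
    if has_hd1 and has_he2:
        return "HIP"
    if has_hd1:
        return "HID"
    return "HIE"  # default epsilon tautomer when the input does not say


# ---------------------------------------------------------------------------
# per-residue enumeration

def enumerate_states(r: Residue, s: Structure) -> list[RPState]:
    """All candidate RP states of an ambiguous residue, in deterministic
    order. State counts: HIS 6, ASN/GLN 2, SER/THR/TYR 1 (with 9 / 9 / 2
    hydroxyl hydrogen candidates), dyad-controlling ASP/GLU 5, lone
    ASP/GLU 1 (deprotonated)."""
    if r.status != "ambiguous":
        raise ContractError(f"{r.resname} {r.key} is not ambiguous")
    rn = r.resname
    if rn == "HIS":
        states = []
        for rot, ov in ((0, {}), (1, flip_imidazole(r))):
            for prot in HIS_PROTONATIONS:
                states.append(_build_state(s, r, rot, prot, ov))
        return states
    if rn in ("ASN", "GLN"):
        return [
            _build_state(s, r, 0, "amide"),
            _build_state(s, r, 1, "amide", flip_amide(r)),
        ]
    if rn in ("SER", "THR", "TYR"):
        return [_build_state(s, r, 0, "hydroxyl")]
    if rn in ("ASP", "GLU"):
        if r.dyad_partner is not None:
            if not r.dyad_controller:
                raise ContractError(
                    f"{rn} {r.key} is the follower of its dyad; "
                    "states are enumerated on the controller")
            partner = s.residue(r.dyad_partner)
            dyads = enumerate_dyad_states((r, partner))
            states = [_build_state(s, r, 0, "deprotonated")]
            for d in dyads:
                st = _build_state(s, r, 0, f"protonated:{d.protonated_oxygen[1]}"
                                  f"@{d.protonated_oxygen[0][0]}{d.protonated_oxygen[0][1]}")
                st.dyad_proton = d.protonated_oxygen
                st.dyad_hydrogen = d.hydrogen
                states.append(st)
            return states
        return [_build_state(s, r, 0, "deprotonated")]
    raise ContractError(f"no RP states defined for residue type {rn}")


def enumerate_dyad_states(pair: tuple[Residue, Residue],
                          proximal: float = 3.8) -> list[DyadState]:
    """The four singly-protonated states of an ASP/GLU acid dyad, one per
    carboxylate oxygen. The hydrogen is placed in the carboxylate plane,
    oriented toward the partner carboxylate's nearest oxygen (O-H 0.96 A).
    The doubly-deprotonated reference carries no DyadState entry."""
    a, b = pair
    for r in (a, b):
        if r.resname not in CARBOXYLATE_ATOMS:
            raise ContractError(f"{r.resname} {r.key} is not ASP/GLU")
    oa = [n for n in CARBOXYLATE_ATOMS[a.resname][1:] if a.has(n)]
    ob = [n for n in CARBOXYLATE_ATOMS[b.resname][1:] if b.has(n)]
    if len(oa) != 2 or len(ob) != 2:
        raise IncompleteSideChainError("incomplete carboxylate in dyad pair")
    dmin = min(
        float(np.linalg.norm(a.atom(x).position - b.atom(y).position))
        for x in oa for y in ob
    )
    if dmin > proximal:
        raise ContractError(
            f"carboxylate oxygens {dmin:.2f} A apart exceed the proximal "
            f"threshold {proximal} A; not a dyad")
    states: list[DyadState] = []
    for owner, own_names, other, other_names in ((a, oa, b, ob), (b, ob, a, oa)):
        cname = CARBOXYLATE_ATOMS[owner.resname][0]
        for oxname in own_names:
            o = owner.atom(oxname).position
            target = min(
                (other.atom(n).position for n in other_names),
                key=lambda p: float(np.linalg.norm(p - o)),
            )
            h = _carboxyl_hydrogen(owner, cname, own_names, oxname, target)
            states.append(DyadState(pair=(a.key, b.key),
                                    protonated_oxygen=(owner.key, oxname),
                                    hydrogen=h))
    return states


def _carboxyl_hydrogen(r: Residue, cname: str, onames: list[str],
                       oxname: str, target: np.ndarray) -> np.ndarray:
    """O-H on a protonated carboxylate oxygen: in the carboxylate plane,
    pointing toward the partner's nearest oxygen."""
    o = r.atom(oxname).position
    c = r.atom(cname).position
    o2 = r.atom([n for n in onames if n != oxname][0]).position
    normal = unit(np.cross(o - c, o2 - c))
    d = target - o
    d_inplane = d - np.dot(d, normal) * normal
    if np.linalg.norm(d_inplane) < 1e-6:
        d_inplane = o - c
    return o + OH_BOND * unit(d_inplane)


# ---------------------------------------------------------------------------
# output-time hydrogen resolution

def resolved_hydrogens(r: Residue, state: RPState, s: Structure,
                       config) -> list[tuple[str, list[np.ndarray]]]:
    """Hydrogens to write for a residue in its final state.

    Multi-candidate donors (hydroxyls, thiols) are collapsed to the single
    direction that best serves the final neighborhood: the candidate
    closest to the nearest acceptor-capable polar heavy atom, or the first
    staggered position if the residue has no neighbors. Amide/amine donors
    keep all their hydrogens.
    """
    out: list[tuple[str, list[np.ndarray]]] = []
    free_direction = r.resname in ("SER", "THR", "TYR", "CYS")
    for heavy, cands in sorted(state.hydrogen_placements.items()):
        if free_direction and heavy != "N" and len(cands) > 1:
            target = _nearest_polar_neighbor(r, heavy, s, config)
            if target is not None:
                best = min(cands, key=lambda h: float(np.linalg.norm(h - target)))
            else:
                best = cands[0]
            out.append((heavy, [best]))
        else:
            out.append((heavy, list(cands)))
    if state.dyad_proton is not None and state.dyad_hydrogen is not None:
        key, oxname = state.dyad_proton
        if key == r.key:
            out.append((oxname, [state.dyad_hydrogen]))
    # a dyad follower's proton lives on the controller's state
    if r.dyad_partner is not None and not r.dyad_controller:
        ctrl_state = config.assignments.get(r.dyad_partner)
        if (ctrl_state is not None and ctrl_state.dyad_proton is not None
                and ctrl_state.dyad_proton[0] == r.key):
            out.append((ctrl_state.dyad_proton[1], [ctrl_state.dyad_hydrogen]))
    return out


def _nearest_polar_neighbor(r: Residue, heavy: str, s: Structure,
                            config) -> np.ndarray | None:
    """Nearest polar heavy atom of another residue, for orienting a free
    hydroxyl/thiol hydrogen on output."""
    from .structure_model import SIDECHAIN_POLAR

    origin = r.atom(heavy).position
    best: np.ndarray | None = None
    best_d = 4.0
    for other in s:
        if other.key == r.key:
            continue
        polar = {"O"} | set(SIDECHAIN_POLAR.get(other.resname, {}))
        ostate = config.assignments.get(other.key)
        for name in polar:
            if not other.has(name):
                continue
            p = ostate.position_of(other, name) if ostate is not None \
                else other.atom(name).position
            d = float(np.linalg.norm(p - origin))
            if d < best_d:
                best_d, best = d, p
    return best
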