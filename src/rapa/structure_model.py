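"""Protein structure model: PDB parsing/writing, polar-site typing, the
proximal-neighbor graph and disulfide detection.

The in-memory model is deliberately small: a ``Structure`` is an ordered
list of ``Residue`` objects (chain, then sequence number, then insertion
code), each holding plain ``Atom`` records. Parsing is done with gemmi;
waters and non-protein hetero groups are dropped on load, alternate
locations are resolved to a single conformer, and existing hydrogens are
kept but treated as replaceable (polar hydrogens are always re-placed at
idealized geometry downstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import ContractError, EmptyStructureError, ParseError

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# residue vocabulary

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Variant names mapped back to their parent residue on input.
RESNAME_ALIASES = {
    "MSE": "MET",
    "HID": "HIS", "HIE": "HIS", "HIP": "HIS", "HSD": "HIS", "HSE": "HIS",
    "HSP": "HIS",
    "ASH": "ASP", "GLH": "GLU", "CYX": "CYS", "CYM": "CYS", "LYN": "LYS",
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# Side-chain polar heavy atoms and their hydrogen-bonding roles.
# "donor_or_acceptor" covers hydroxyls/thiols (free proton direction) and
# the state-dependent sites (HIS ring nitrogens, carboxylate oxygens in an
# acid dyad) whose effective role is resolved from the assigned RP state.
SIDECHAIN_POLAR: dict[str, dict[str, str]] = {
    "ASN": {"OD1": "acceptor", "ND2": "donor"},
    "GLN": {"OE1": "acceptor", "NE2": "donor"},
    "HIS": {"ND1": "donor_or_acceptor", "NE2": "donor_or_acceptor"},
    "ASP": {"OD1": "acceptor", "OD2": "acceptor"},
    "GLU": {"OE1": "acceptor", "OE2": "acceptor"},
    "SER": {"OG": "donor_or_acceptor"},
    "THR": {"OG1": "donor_or_acceptor"},
    "TYR": {"OH": "donor_or_acceptor"},
    "LYS": {"NZ": "donor"},
    "ARG": {"NE": "donor", "NH1": "donor", "NH2": "donor"},
    "TRP": {"NE1": "donor"},
    "CYS": {"SG": "donor_or_acceptor"},
}

# For flip-capable residues: the atom whose *input* position a polar site
# occupies in the flipped rotamer. Used to make neighbor detection aware of
# both rotamers.
FLIP_SOURCE = {
    ("ASN", "OD1"): "ND2", ("ASN", "ND2"): "OD1",
    ("GLN", "OE1"): "NE2", ("GLN", "NE2"): "OE1",
    ("HIS", "ND1"): "CD2", ("HIS", "NE2"): "CE1",
}

CARBOXYLATE_ATOMS = {"ASP": ("CG", "OD1", "OD2"), "GLU": ("CD", "OE1", "OE2")}

# AMBER-convention histidine tautomer names used on output.
HIS_TAUTOMER_NAMES = {"HID": "HID", "HIE": "HIE", "HIP": "HIP"}

ResidueKey = tuple[str, int, str]


# ---------------------------------------------------------------------------
# domain types

@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    resname: str
    chain: str
    seqnum: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    status: str = "known"          # known | ambiguous
    label: str = "unset"           # unset | fully_solvated | fixed | degenerate
    input_resname: str = ""        # name as read, before alias mapping
    disulfide_partner: ResidueKey | None = None
    dyad_partner: ResidueKey | None = None
    dyad_controller: bool = False

    @property
    def key(self) -> ResidueKey:
        return (self.chain, self.seqnum, self.icode)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.resname} {self.key}: no atom {name!r}")

    def has(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def set_known(self) -> None:
        self.status = "known"

    def set_ambiguous(self) -> None:
        if self.status == "known" and self.label != "unset":
            raise ContractError("status transition known->ambiguous is forbidden")
        self.status = "ambiguous"


@dataclass
class Structure:
    residues: list[Residue] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {r.key: r for r in self.residues}

    def __iter__(self):
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, key: ResidueKey) -> Residue:
        return self._index[key]

    def prev_c(self, r: Residue) -> np.ndarray | None:
        """Position of the preceding residue's backbone C (peptide bond
        partner of r's N), or None at a chain start / chain break."""
        i = self.residues.index(r)
        if i == 0:
            return None
        p = self.residues[i - 1]
        if p.chain != r.chain or not p.has("C") or not r.has("N"):
            return None
        c = p.atom("C").position
        if np.linalg.norm(c - r.atom("N").position) > 2.0:  # chain break
            return None
        return c


@dataclass
class PolarSite:
    residue_key: ResidueKey
    atom_name: str
    role: str                       # donor | acceptor | donor_or_acceptor
    position: np.ndarray
    is_backbone: bool = False
    flip_source: str | None = None  # atom providing the flipped-rotamer position
    alt_position: np.ndarray | None = None
    hydrogens: list[np.ndarray] = field(default_factory=list)

    @property
    def id(self) -> tuple:
        return (*self.residue_key, self.atom_name)


@dataclass
class NeighborGraph:
    """Undirected proximity graph over polar sites.

    Edges connect sites of *different* residues whose heavy atoms lie
    within the proximal threshold. With ``flip_aware`` builds, a site's
    flipped-rotamer position also counts for edge inclusion, so that
    interactions present only in the alternate rotamer are not missed.
    """

    sites: list[PolarSite]
    threshold: float
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._site_edges: dict[int, list[int]] = {i: [] for i in range(len(self.sites))}
        for e, (i, j, _) in enumerate(self.edges):
            self._site_edges[i].append(e)
            self._site_edges[j].append(e)
        self._residue_sites: dict[ResidueKey, list[int]] = {}
        for i, s in enumerate(self.sites):
            self._residue_sites.setdefault(s.residue_key, []).append(i)

    def edges_of_site(self, i: int) -> list[tuple[int, int, float]]:
        return [self.edges[e] for e in self._site_edges[i]]

    def site_indices(self, key: ResidueKey, sidechain_only: bool = False) -> list[int]:
        idx = self._residue_sites.get(key, [])
        if sidechain_only:
            idx = [i for i in idx if not self.sites[i].is_backbone]
        return idx

    def incident_edges(
        self, key: ResidueKey, sidechain_only: bool = True
    ) -> list[tuple[int, int, float]]:
        """Edges touching the residue's (side-chain) polar sites."""
        own = set(self.site_indices(key, sidechain_only=sidechain_only))
        seen: set[int] = set()
        out = []
        for i in own:
            for e in self._site_edges[i]:
                if e not in seen:
                    seen.add(e)
                    out.append(self.edges[e])
        return out

    def residue_neighbors(self, key: ResidueKey, sidechain_only: bool = True) -> list[ResidueKey]:
        """Residues sharing an edge with this residue's (side-chain) sites,
        in deterministic sorted order."""
        nb: set[ResidueKey] = set()
        for i, j, _ in self.incident_edges(key, sidechain_only=sidechain_only):
            for s in (self.sites[i], self.sites[j]):
                if s.residue_key != key:
                    nb.add(s.residue_key)
        return sorted(nb)


# ---------------------------------------------------------------------------
# parsing

def _resolve_altlocs(atoms: list[Atom], policy: str) -> list[Atom]:
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            out.append(group[0])
            continue
        if policy == "first":
            out.append(group[0])
        elif policy == "occupancy":
            # highest occupancy wins; ties go to altloc 'A' (then alphabetical)
            best = sorted(
                group, key=lambda a: (-a.occupancy, a.altloc != "A", a.altloc)
            )[0]
            out.append(best)
        else:
            raise ContractError(f"unknown altloc policy {policy!r}")
    return out


def read_structure(pdb_text: str, altloc_policy: str = "occupancy") -> Structure:
    """Parse PDB-format text into a ``Structure``.

    Waters and non-protein hetero groups are removed; nonstandard residues
    with a trivial parent mapping (e.g. MSE) are renamed; unknown hetero
    residues are skipped with a warning. Only the first model of a
    multi-model file is used. Alternate locations are collapsed according
    to ``altloc_policy`` ('occupancy': keep highest occupancy, ties -> 'A';
    'first': keep the first conformer encountered).
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse PDB text: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError("no models in input")
    model = st[0]

    residues: list[Residue] = []
    for chain in model:
        for gres in chain:
            name = gres.name.strip()
            if name in WATER_NAMES:
                continue
            resname = RESNAME_ALIASES.get(name, name)
            if resname not in STANDARD_RESIDUES:
                logger.warning("skipping non-protein residue %s %s %d",
                               name, chain.name, gres.seqid.num)
                continue
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    bfactor=a.b_iso,
                    occupancy=a.occ,
                    altloc="" if a.altloc in ("\x00", " ", "") else a.altloc,
                )
                for a in gres
            ]
            atoms = _resolve_altlocs(atoms, altloc_policy)
            residues.append(
                Residue(
                    resname=resname,
                    chain=chain.name,
                    seqnum=gres.seqid.num,
                    icode=gres.seqid.icode.strip(),
                    atoms=atoms,
                    input_resname=name,
                )
            )
    if not residues:
        raise EmptyStructureError("no protein residues after filtering")
    residues.sort(key=lambda r: (r.chain, r.seqnum, r.icode))
    meta = {"title": st.name} if st.name else {}
    return Structure(residues=residues, metadata=meta)


# ---------------------------------------------------------------------------
# polar sites

def assign_polar_sites(s: Structure) -> list[PolarSite]:
    """Type every polar heavy atom (N/O/S able to donate or accept) as a
    ``PolarSite``.

    Backbone amide nitrogens are donor-only (except proline, which carries
    no amide hydrogen); backbone carbonyl oxygens are acceptor-only.
    Side-chain roles follow the per-residue table; disulfide-bridged
    cysteine sulfurs (detect_disulfides must run first) get no site.
    """
    sites: list[PolarSite] = []
    for r in s:
        if r.resname not in STANDARD_RESIDUES:
            logger.warning("unknown residue %s treated as nonpolar", r.resname)
            continue
        # backbone
        if r.has("N") and r.resname != "PRO":
            sites.append(PolarSite(r.key, "N", "donor",
                                   r.atom("N").position, is_backbone=True))
        for oname in ("O", "OXT"):
            if r.has(oname):
                sites.append(PolarSite(r.key, oname, "acceptor",
                                       r.atom(oname).position, is_backbone=True))
        # side chain
        for aname, role in SIDECHAIN_POLAR.get(r.resname, {}).items():
            if not r.has(aname):
                continue
            if r.resname == "CYS" and r.disulfide_partner is not None:
                continue  # bridged sulfur: deprotonated, not an h-bond site
            site = PolarSite(r.key, aname, role, r.atom(aname).position)
            src = FLIP_SOURCE.get((r.resname, aname))
            if src is not None and r.has(src):
                site.flip_source = src
                site.alt_position = r.atom(src).position
            sites.append(site)
    return sites


def build_neighbor_graph(
    sites: Sequence[PolarSite],
    threshold: float = 3.8,
    flip_aware: bool = False,
) -> NeighborGraph:
    """Connect polar sites of different residues whose heavy atoms are
    within ``threshold`` Angstrom (the proximal range at which local
    interactions are scored).

    With ``flip_aware=True`` the flipped-rotamer position of amide/imidazole
    sites also qualifies a pair, so both rotamers' contacts are represented.
    """
    if threshold <= 0:
        raise ContractError("threshold must be positive")
    edges: list[tuple[int, int, float]] = []
    n = len(sites)
    for i in range(n):
        a = sites[i]
        pa = [a.position] + ([a.alt_position] if flip_aware and a.alt_position is not None else [])
        for j in range(i + 1, n):
            b = sites[j]
            if a.residue_key == b.residue_key:
                continue
            pb = [b.position] + ([b.alt_position] if flip_aware and b.alt_position is not None else [])
            dmin = min(float(np.linalg.norm(x - y)) for x in pa for y in pb)
            if dmin <= threshold:
                edges.append((i, j, float(np.linalg.norm(a.position - b.position))))
    return NeighborGraph(sites=list(sites), threshold=threshold, edges=edges)


# ---------------------------------------------------------------------------
# disulfides

def detect_disulfides(s: Structure, threshold: float = 2.3) -> list[tuple[ResidueKey, ResidueKey]]:
    """Pair cysteine SG atoms within ``threshold`` Angstrom into disulfide
    bridges (closest pair first; each sulfur joins at most one bridge).

    Bridged cysteines are marked deprotonated/known via
    ``Residue.disulfide_partner``; unpaired cysteines stay protonated.
    Idempotent: re-running clears and recomputes annotations.
    """
    if threshold <= 0:
        raise ContractError("threshold must be positive")
    cys = [r for r in s if r.resname == "CYS" and r.has("SG")]
    for r in cys:
        r.disulfide_partner = None
    cand = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = float(np.linalg.norm(cys[i].atom("SG").position - cys[j].atom("SG").position))
            if d <= threshold:
                cand.append((d, cys[i], cys[j]))
    cand.sort(key=lambda t: (t[0], t[1].key, t[2].key))
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    used: set[ResidueKey] = set()
    for d, a, b in cand:
        if a.key in used or b.key in used:
            logger.warning("CYS %s/%s also near an assigned bridge; keeping closest pair",
                           a.key, b.key)
            continue
        a.disulfide_partner = b.key
        b.disulfide_partner = a.key
        used.update((a.key, b.key))
        pairs.append((a.key, b.key))
    return pairs


# ---------------------------------------------------------------------------
# writing

_PDB_ATOM = (
    "{rec:<6}{serial:>5} {name:<4}{altloc:1}{resname:<3} {chain:1}"
    "{seqnum:>4}{icode:1}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2}"
)


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def structure_to_pdb(s: Structure) -> str:
    """Serialize a Structure to PDB text (ATOM/TER/END records)."""
    lines: list[str] = []
    serial = 0
    prev_chain: str | None = None
    for r in s:
        if prev_chain is not None and r.chain != prev_chain:
            lines.append("TER")
        prev_chain = r.chain
        for a in r.atoms:
            serial += 1
            lines.append(_PDB_ATOM.format(
                rec="ATOM", serial=serial,
                name=_format_atom_name(a.name, a.element),
                altloc=a.altloc or " ",
                resname=r.resname, chain=r.chain, seqnum=r.seqnum,
                icode=r.icode or " ",
                x=a.position[0], y=a.position[1], z=a.position[2],
                occ=a.occupancy, b=a.bfactor, element=a.element,
            ))
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# Hydrogen names emitted for each placed polar hydrogen, by (resname, heavy atom).
_H_NAMES: dict[tuple[str, str], list[str]] = {
    ("ASN", "ND2"): ["HD21", "HD22"],
    ("GLN", "NE2"): ["HE21", "HE22"],
    ("HIS", "ND1"): ["HD1"],
    ("HIS", "NE2"): ["HE2"],
    ("SER", "OG"): ["HG"],
    ("THR", "OG1"): ["HG1"],
    ("TYR", "OH"): ["HH"],
    ("CYS", "SG"): ["HG"],
    ("LYS", "NZ"): ["HZ1", "HZ2", "HZ3"],
    ("ARG", "NE"): ["HE"],
    ("ARG", "NH1"): ["HH11", "HH12"],
    ("ARG", "NH2"): ["HH21", "HH22"],
    ("TRP", "NE1"): ["HE1"],
    ("ASP", "OD1"): ["HD1"], ("ASP", "OD2"): ["HD2"],
    ("GLU", "OE1"): ["HE1"], ("GLU", "OE2"): ["HE2"],
}


def write_configuration(config, s: Structure, his_naming: str = "tautomer") -> str:
    """Serialize one fully-resolved configuration to PDB text.

    Heavy-atom coordinates reflect the assigned RP states (flipped amides /
    imidazoles); polar hydrogens are written at their assigned idealized
    positions; input hydrogens are dropped (they are always re-placed).
    Histidines are named HID/HIE/HIP when ``his_naming == 'tautomer'``,
    or kept as HIS with ``his_naming == 'plain'``.
    """
    from .state_enumeration import resolved_hydrogens  # local import: avoid cycle

    for key, status in config.statuses.items():
        if status != "known":
            raise ContractError(f"residue {key} still ambiguous; cannot write")

    lines: list[str] = []
    serial = 0
    prev_chain: str | None = None
    for r in s:
        state = config.assignments.get(r.key)
        resname = r.resname
        if r.resname == "HIS" and his_naming == "tautomer" and state is not None:
            resname = HIS_TAUTOMER_NAMES.get(state.protonation, "HIS")
        if prev_chain is not None and r.chain != prev_chain:
            lines.append("TER")
        prev_chain = r.chain

        def emit(name: str, element: str, pos: np.ndarray, b: float, occ: float) -> None:
            nonlocal serial
            serial += 1
            lines.append(_PDB_ATOM.format(
                rec="ATOM", serial=serial,
                name=_format_atom_name(name, element),
                altloc=" ", resname=resname, chain=r.chain,
                seqnum=r.seqnum, icode=r.icode or " ",
                x=pos[0], y=pos[1], z=pos[2], occ=occ, b=b, element=element,
            ))

        overrides = state.coord_overrides if state is not None else {}
        for a in r.atoms:
            if a.is_hydrogen:
                continue
            pos = overrides.get(a.name, a.position)
            emit(a.name, a.element, pos, a.bfactor, a.occupancy)
        if state is not None:
            for heavy, hpositions in resolved_hydrogens(r, state, s, config):
                names = _H_NAMES.get((r.resname, heavy))
                if heavy == "N":
                    names = ["H"]
                for k, hp in enumerate(hpositions):
                    hname = names[k] if names and k < len(names) else f"H{heavy[-2:]}{k+1}"
                    emit(hname, "H", hp, r.atoms[0].bfactor, 1.0)
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
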