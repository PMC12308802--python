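"""Programmatic generators of minimal synthetic structures exercising every
ambiguity class.

Each fixture places one or two residues with idealized geometry (Chemical
Component Dictionary ideal coordinates, via biotite) so that the motif
under test — an amide facing a hydroxyl, two facing amides, a histidine
probe, an acid dyad, a disulfide pair — occurs at a configurable distance
while every other polar atom stays out of the proximal range.

Exact degeneracy by construction: a probe placed on a residue's flip axis
(the CB-CG line) is equidistant from the original and the flipped
positions of every side-chain atom, because a 180-degree rotation about
the axis preserves distances to points on it. The two rotamers of the
motif residue therefore score *identically*, giving clean ZERO-gap
fixtures for the degeneracy-boundary tests. The ``angle`` parameter
rotates the probe off the axis to break the tie by a controllable amount.

The two-residue fixtures place the partner by point inversion through a
center on the flip axis, which makes the two doubly-flipped
configurations exactly degenerate as well (the facing-amides motif).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import ParameterError
from .geometry import rotate_about_axis, unit
from .structure_model import Atom, Residue, Structure, structure_to_pdb

FIXTURE_KINDS = (
    "asn_ser", "asn_asn", "his_probe", "asp_dyad", "cys_pair",
    "isolated", "multi_pair",
)

_MIN_DIST, _MAX_DIST = 1.5, 20.0


@dataclass
class FixtureSpec:
    kind: str
    geometry: dict = field(default_factory=dict)
    count: int = 1
    seed: int = 0


# ---------------------------------------------------------------------------
# templates

@lru_cache(maxsize=None)
def _template(resname: str) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Ideal heavy-atom coordinates of a residue (names, elements, coords)."""
    import biotite.structure.info as info

    arr = info.residue(resname)
    keep = [i for i, (el, nm) in enumerate(zip(arr.element, arr.atom_name))
            if el != "H" and nm != "OXT"]
    names = tuple(str(arr.atom_name[i]) for i in keep)
    elements = tuple(str(arr.element[i]) for i in keep)
    coords = np.array([arr.coord[i] for i in keep], dtype=float)
    return names, elements, coords


def _frame_align(coords: np.ndarray, names: tuple[str, ...],
                 a: str, b: str, c: str) -> np.ndarray:
    """Rigidly move coords so atom a sits at the origin, b lies on +x and
    c lies in the xy-plane with positive y."""
    idx = {n: i for i, n in enumerate(names)}
    pa, pb, pc = (coords[idx[n]] for n in (a, b, c))
    ex = unit(pb - pa)
    v = pc - pa
    ez = unit(np.cross(ex, v))
    ey = np.cross(ez, ex)
    rot = np.vstack([ex, ey, ez])
    return (coords - pa) @ rot.T


def _make_residue(resname: str, chain: str, seqnum: int,
                  coords: np.ndarray) -> Residue:
    names, elements, _ = _template(resname)
    atoms = [Atom(name=n, element=e, position=np.array(p))
             for n, e, p in zip(names, elements, coords)]
    return Residue(resname=resname, chain=chain, seqnum=seqnum, atoms=atoms)


def _coords(resname: str, a: str, b: str, c: str) -> np.ndarray:
    names, _, coords = _template(resname)
    return _frame_align(coords, names, a, b, c)


def _atom_pos(resname: str, coords: np.ndarray, name: str) -> np.ndarray:
    names, _, _ = _template(resname)
    return coords[names.index(name)]


# ---------------------------------------------------------------------------
# placement helpers

def _check_distance(d: float) -> None:
    if not (_MIN_DIST <= d <= _MAX_DIST):
        raise ParameterError(
            f"distance {d} A outside sanity bounds [{_MIN_DIST}, {_MAX_DIST}]")


def _axis_probe_point(targets: list[np.ndarray], distance: float,
                      lo: float = 0.0, hi: float = 25.0) -> np.ndarray:
    """Point on the +x axis whose minimum distance to `targets` equals
    `distance` (bisection; the minimum distance grows monotonically with x
    beyond the targets)."""
    def f(x: float) -> float:
        p = np.array([x, 0.0, 0.0])
        return min(float(np.linalg.norm(p - t)) for t in targets) - distance

    while f(hi) < 0:
        hi *= 2.0
    if f(lo) > 0:
        lo = 0.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return np.array([0.5 * (lo + hi), 0.0, 0.0])


def _inversion(coords: np.ndarray, center: np.ndarray) -> np.ndarray:
    return 2.0 * center - coords


# ---------------------------------------------------------------------------
# individual fixtures

def _asn_ser(distance: float = 2.8, angle: float = 0.0) -> Structure:
    """An asparagine amide facing a serine hydroxyl: the hydroxyl sits on
    the amide's flip axis at `distance` from the nearest amide atom, so
    the two ASN rotamers tie exactly when angle == 0. A nonzero `angle`
    (degrees) swings the serine off-axis and opens an energy gap."""
    _check_distance(distance)
    asn = _coords("ASN", "CB", "CG", "OD1")
    targets = [_atom_pos("ASN", asn, "OD1"), _atom_pos("ASN", asn, "ND2")]
    p = _axis_probe_point(targets, distance)
    if angle != 0.0:
        p = rotate_about_axis(p, _atom_pos("ASN", asn, "CG"),
                              np.array([0.0, 0.0, 1.0]), angle)
    # serine oriented with its body pointing away from the amide (+x)
    ser = _coords("SER", "OG", "CB", "CA")
    away = unit(p - _atom_pos("ASN", asn, "CG"))
    rot = _rotation_from_x(away)
    ser = ser @ rot.T + p
    return Structure(residues=[
        _make_residue("ASN", "A", 1, asn),
        _make_residue("SER", "B", 1, ser),
    ])


def _rotation_from_x(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +x to `direction` (any perpendicular roll)."""
    ex = unit(direction)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ex, helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    ey = unit(np.cross(helper, ex))
    ez = np.cross(ex, ey)
    return np.column_stack([ex, ey, ez])


def _asn_asn(distance: float = 2.9, offset: float = 0.0) -> Structure:
    """Two facing asparagine amides related by point inversion through a
    center on the first amide's flip axis. The O...N cross pairs are
    equidistant and the both-flipped configuration is exactly degenerate
    with the unflipped one, while single flips face O against O and N
    against N (clashes). A nonzero ``offset`` (A) slides the partner
    sideways off the axis, breaking the exact degeneracy."""
    _check_distance(distance)
    a = _coords("ASN", "CB", "CG", "OD1")
    p = _atom_pos("ASN", a, "OD1")
    q = _atom_pos("ASN", a, "ND2")
    w = p + q
    rad = distance ** 2 - w[1] ** 2 - w[2] ** 2
    if rad <= 0:
        raise ParameterError(f"distance {distance} too small for facing amides")
    mx = 0.5 * (w[0] + np.sqrt(rad))
    b = _inversion(a, np.array([mx, 0.0, 0.0])) + np.array([0.0, offset, 0.0])
    return Structure(residues=[
        _make_residue("ASN", "A", 1, a),
        _make_residue("ASN", "B", 1, b),
    ])


def _his_probe(distance: float = 2.8, acceptor: bool = True,
               donor: bool = False) -> Structure:
    """A histidine with carbonyl/amide probes from lone alanines:
    `acceptor` puts a backbone carbonyl O on the ND1-H vector (favoring
    Nd-protonated states), `donor` aims a backbone N-H at NE2 (favoring
    states where NE2 accepts). With both probes HID is selected uniquely."""
    _check_distance(distance)
    his = _coords("HIS", "CB", "CG", "ND1")
    residues = [_make_residue("HIS", "A", 1, his)]

    def hpos(center: str, n1: str, n2: str) -> np.ndarray:
        c = _atom_pos("HIS", his, center)
        d = -(unit(_atom_pos("HIS", his, n1) - c)
              + unit(_atom_pos("HIS", his, n2) - c))
        return c, unit(d)

    if acceptor:
        nd1, out_dir = hpos("ND1", "CG", "CE1")
        o_point = nd1 + distance * out_dir
        ala = _coords("ALA", "O", "C", "CA")
        ala = ala @ _rotation_from_x(out_dir).T + o_point
        residues.append(_make_residue("ALA", "B", 1, ala))
    if donor:
        ne2, out_dir = hpos("NE2", "CD2", "CE1")
        n_point = ne2 + distance * out_dir
        ala = _coords("ALA", "N", "CA", "C")
        ala = ala @ _rotation_from_x(out_dir).T + n_point
        residues.append(_make_residue("ALA", "C", 1, ala))
    return Structure(residues=residues)


def _asp_dyad(distance: float = 2.6) -> Structure:
    """Two aspartate carboxylates facing OD2-to-OD2 at `distance`."""
    _check_distance(distance)
    a = _coords("ASP", "CG", "OD2", "OD1")
    od2x = _atom_pos("ASP", a, "OD2")[0]
    mx = od2x + 0.5 * distance  # so that 2*mx - 2*od2x == distance
    b = _inversion(a, np.array([mx, 0.0, 0.0]))
    return Structure(residues=[
        _make_residue("ASP", "A", 1, a),
        _make_residue("ASP", "B", 1, b),
    ])


def _cys_pair(distance: float = 2.05) -> Structure:
    """Two cysteines with SG atoms `distance` apart."""
    _check_distance(distance)
    a = _coords("CYS", "CB", "SG", "CA")
    sgx = _atom_pos("CYS", a, "SG")[0]
    b = _inversion(a, np.array([sgx + 0.5 * distance, 0.0, 0.0]))
    return Structure(residues=[
        _make_residue("CYS", "A", 1, a),
        _make_residue("CYS", "B", 1, b),
    ])


def _isolated(resname: str = "GLN") -> Structure:
    """A single residue with nothing in range: fully solvated."""
    names, _, coords = _template(resname)
    return Structure(residues=[_make_residue(resname, "A", 1,
                                             coords - coords.mean(axis=0))])


# ---------------------------------------------------------------------------
# public surface

_BUILDERS = {
    "asn_ser": _asn_ser,
    "asn_asn": _asn_asn,
    "his_probe": _his_probe,
    "asp_dyad": _asp_dyad,
    "cys_pair": _cys_pair,
    "isolated": _isolated,
}


def make_structure(kind: str, count: int = 1, seed: int = 0,
                   jitter: float = 0.0, spacing: float = 20.0,
                   **geometry) -> Structure:
    """Build a fixture Structure.

    ``count > 1`` (or kind='multi_pair') stitches independent copies of
    the motif at least ``spacing`` A apart, each on its own chains.
    ``jitter`` adds seeded Gaussian noise (clipped to 0.05 A) to every
    coordinate to probe robustness of the grid lookup.
    """
    if kind == "multi_pair":
        unit_kind = geometry.pop("unit", "asn_ser")
        count = geometry.pop("k", count)
        return make_structure(unit_kind, count=count, seed=seed,
                              jitter=jitter, spacing=spacing, **geometry)
    if kind not in _BUILDERS:
        raise ParameterError(f"unknown fixture kind {kind!r}; "
                             f"choose from {FIXTURE_KINDS}")
    if spacing < 15.0:
        raise ParameterError("copies must be at least 15 A apart")
    base = _BUILDERS[kind](**geometry)
    residues = []
    for i in range(count):
        shift = np.array([0.0, 0.0, i * spacing])
        for j, r in enumerate(base.residues):
            rr = Residue(
                resname=r.resname,
                chain=chr(ord("A") + (i * len(base.residues) + j) % 26),
                seqnum=i * 10 + j + 1,
                atoms=[Atom(a.name, a.element, a.position + shift,
                            a.bfactor, a.occupancy) for a in r.atoms],
            )
            residues.append(rr)
    s = Structure(residues=residues)
    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        sigma = min(jitter, 0.05)
        for r in s:
            for a in r.atoms:
                a.position = a.position + np.clip(
                    rng.normal(0.0, sigma, 3), -0.05, 0.05)
    return s


def make_fixture(spec: FixtureSpec | None = None, **kwargs) -> str:
    """Build a fixture and return it as PDB-format text (deterministic
    given the seed). Accepts either a FixtureSpec or keyword arguments."""
    if spec is not None:
        kwargs = dict(kind=spec.kind, count=spec.count, seed=spec.seed,
                      **spec.geometry)
    return structure_to_pdb(make_structure(**kwargs))
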