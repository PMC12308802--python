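# Methods

This note records the model implemented by `rapa`, the parameters that
matter, the numerical choices made where the design was genuinely open,
and what the synthetic fixtures do and do not demonstrate.

## The assignment problem

Medium-resolution crystallography leaves three classes of side-chain
ambiguity: (i) 180° flips of terminal amides (ASN χ₂, GLN χ₃) and of the
histidine imidazole, which are nearly isosteric in electron density;
(ii) protonation of titratable ring nitrogens (HIS: Nδ1, Nε2, or both)
and of carboxylate pairs that sit close enough to share a proton (acid
dyads); and (iii) the rotational position of hydroxyl and thiol protons.
`rapa` treats these as a discrete combinatorial assignment problem scored
purely by local hydrogen-bond geometry. No pKa model, no electrostatics
beyond the h-bond/clash surface, and no solvent model are used; these are
deliberate scope limits, not oversights.

## Energy model

Interactions are evaluated only between polar heavy atoms of *different*
residues within the proximal threshold (default 3.8 Å). Each pair is
classified by the roles the two sites take under the current state
assignment:

* **donor + acceptor** — hydrogen bond. The donor contributes its
  idealized hydrogen candidates (amides two in-plane H, LYS three
  staggered, hydroxyls the 9-/2-position fan, backbone N one in-plane H);
  the candidate with the shortest H···acceptor distance is used, the
  angle is measured donor-heavy–H–acceptor-heavy, and the energy is a
  nearest-grid lookup E(d, θ).
* **donor + donor** — clash. Each donor aims its best-aligned hydrogen at
  the other heavy atom; the energy is −E(d, θ) and the more unfavorable
  of the two orientations is kept.
* **acceptor + acceptor** — clash at −E(d, 180°). No carrier hydrogen
  exists between two acceptors, so the maximally penalizing angle is
  used; this is a modelling decision, chosen so that acceptor–acceptor
  contacts are never silently underpenalized.

The table itself is analytic:

    E(d, θ) = W · [1 − (1 − e^(−a(d−d₀)))²] · cos²(180° − θ)

with well depth W = −5.0 kcal/mol, equilibrium distance d₀ = 2.8 Å and
radial steepness a = 1.8 Å⁻¹, tabulated on d ∈ [2.5, 4.0] Å × θ ∈
[90°, 180°] at 0.1 Å / 0.1° resolution. The defaults reproduce the shape
of a water-dimer binding curve: a steep inner wall, a −5 kcal/mol minimum
near 2.8 Å, a soft outer tail, and an angular falloff vanishing at 90°.
The numbers produced by this surface are *relative* scores for ranking
states, not binding free energies, and gaps between specific states
depend on the surface chosen; the TSV round-trip format exists precisely
so a quantum-chemistry-derived table can be substituted without touching
code. Lookups are nearest-grid (half-up at midpoints, with a 1e-9 guard
against float noise); distances beyond 4.0 Å and angles below 90° score
zero, and sub-2.5 Å distances clamp to the 2.5 Å row.

Charged donors (LYS, ARG, HIP) use the same neutral table — no scaling
is applied to charged interactions.

## State enumeration details

Flips are implemented as rigid 180° rotations about the relevant bond
axis (CB–CG for ASN and HIS, CG–CD for GLN), never as atom-name swaps,
so distorted experimental geometry is carried along unchanged and the
operation is an exact involution. Hydrogens are always re-placed at
idealized geometry (N–H 1.01 Å, O–H 0.96 Å, S–H 1.34 Å) regardless of
what the input contained, so results cannot depend on upstream
preparation. SER/THR hydroxyl fans use CA as the dihedral antecedent
(H–O–CB–CA at 60/180/−60° ± 20°, C–O–H 109.5°); TYR measures its two
in-plane positions against CE1 at 120°.

Acid dyads are detected as ASP/GLU pairs with any carboxylate O–O cross
distance within the proximal threshold (closest pair first, each residue
in at most one dyad). The dyad proton is placed in the carboxylate plane
of its oxygen, pointing at the partner's nearest oxygen — the
syn/anti choice is left to geometry rather than convention. The
first residue of the pair in sequence order "controls" the dyad's five
states; the partner's site roles resolve through the controller's
assigned state. Lone ASP/GLU are fixed deprotonated at initialization
(a `protonatable_acids` switch re-opens them, off by default). HIP is
enumerated on equal footing with HID/HIE; no pKa-based prior demotes it.

Hydroxyl/thiol directionality is an internal degree of freedom, not a
branching one: in any environment evaluation the hydroxyl presents
exactly two discrete alternatives — donor (with its best-aligned H
candidate per interaction) or acceptor — and this is true whether the
residue is still formally ambiguous or already fixed, so scores are
stable across workflow passes. The concrete proton direction is chosen
only at output time, toward the nearest polar neighbor in the final
configuration. Consequently hydroxyl residues never spawn branches by
themselves; only amide/imidazole flips, histidine protonation and dyads
multiply configurations.

## Workflow decisions

* "Uniquely favorable" in the per-residue sweep uses the same cutoff as
  branching: a state is assigned immediately only if every alternative
  scores more than `cutoff` above it. This makes the fixing step and the
  branching step mutually consistent — a residue is either fixed or
  (eventually) branched, by the same criterion.
* The degeneracy test is inclusive (≤ cutoff), so exact ties branch.
  Exact ties are robust in practice because the nearest-grid lookup maps
  symmetric geometries to identical table cells bit-for-bit.
* Residues fixed mid-sweep are visible to later residues in the same
  sweep ("sequential" is read literally).
* Branch children are explored depth-first, lowest-energy state first,
  so the output list is naturally priority-ordered; duplicates (branches
  that reconverge) are removed by exact assignment identity.
* A residue whose side-chain polar sites have no proximal neighbors is
  *fully solvated*: it keeps its input-equivalent state (for HIS with no
  informative hydrogens, the common ε-tautomer default) and becomes
  known immediately.
* The proximity graph is built once from input coordinates but is
  *flip-aware*: a site's flipped-rotamer position (the input position of
  its exchange partner) also qualifies an edge, so interactions present
  only in the alternate rotamer are scored rather than silently missed.
  Energies always use the actual per-state coordinates; geometry that a
  flip moves out of range simply scores zero through the table cap.
* Safety bounds: the neighbor-state product is capped at 10⁶
  evaluations and the output at 4096 configurations (both configurable);
  exceeding either raises an explicit resource error naming the
  residues involved.

## Synthetic fixtures and what they show

The fixture generator builds minimal motifs from ideal residue-template
coordinates (Chemical Component Dictionary): an amide facing a hydroxyl,
two facing amides, a histidine with carbonyl/amide probes, an acid dyad,
a disulfide pair, isolated residues, and k independent copies ≥ 15 Å
apart. Two constructions give *exact* degeneracy by symmetry rather than
by tuning: a probe placed on the flip axis (a 180° rotation about the
axis preserves distances to points on it), and a partner residue placed
by point inversion through a center on that axis (which maps the
doubly-flipped pair geometry onto the unflipped one isometrically).
Perturbation parameters (`angle`, `offset`) slide the partner off the
symmetric position to open a controllable energy gap across the cutoff
boundary.

These fixtures exercise every code path — enumeration counts, role
resolution, clash inversion, branching, duplicate elimination, the 2^k
scaling of independent degenerate units — at sub-second cost. They are
*not* miniature proteins: they lack a connected backbone, crowding,
waters and ligands, multi-neighbor frustration, and realistic B-factor /
altloc noise. Passing them demonstrates the correctness of the
combinatorial machinery and the scoring rules, not assignment accuracy
on experimental structures, which additionally depends on the quality of
the energy surface.

## Known limitations

* The analytic surface is a stand-in for a quantum-chemical potential;
  absolute energy gaps (and therefore borderline degenerate/fixed calls)
  shift if a different table is supplied.
* Termini are not treated specially (no N-terminal NH₃⁺ / C-terminal
  COO⁻ protonation states); proline backbone N is simply a non-donor.
* Waters and ligands are removed on input; a residue h-bonded only to
  solvent is indistinguishable from a fully solvated one.
* mmCIF, multi-model ensembles, nucleic acids and metal coordination are
  out of scope.
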