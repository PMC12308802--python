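# rapa

**R**otamer **a**nd **p**rotonation **a**ssignment for protein structures.

X-ray electron density cannot distinguish the terminal oxygen and nitrogen
of an asparagine or glutamine amide, the four heavy-atom arrangements of a
histidine imidazole, or the position of a hydroxyl proton. Downstream
modelling (docking, molecular dynamics, pKa analysis) nevertheless needs a
concrete choice for every one of them. `rapa` resolves these ambiguities
from the local hydrogen-bond network — and, crucially, does **not** force a
single answer when the evidence is ambiguous: it returns *every*
configuration whose local energetics are within a degeneracy cutoff of the
best one.

## Method

For each ambiguous residue the candidate rotamer/protonation (RP) states
are enumerated:

| residue | states |
|---|---|
| HIS | 6 = 2 ring flips × {HID, HIE, HIP} |
| ASN / GLN | 2 (180° amide flip about χ₂ / χ₃) |
| SER / THR | 1 geometric state, 9 hydroxyl H candidates (staggered ±20°) |
| TYR | 1 geometric state, 2 in-plane H candidates |
| ASP/GLU in an acid dyad | 4 singly-protonated + 1 charged reference |

Polar heavy atoms within the *proximal* threshold (3.8 Å) interact. A
donor–acceptor pair scores a hydrogen bond from a lookup table
E(d, θ) over heavy-atom distance d ∈ [2.5, 4.0] Å (0.1 Å steps) and
donor–H–acceptor angle θ ∈ [90°, 180°] (0.1° steps); two donors or two
acceptors facing each other score an electrostatic clash equal to
−E(d, θ) at the same geometry. A residue's state score is the minimum,
over all combinations of its ambiguous neighbors' states, of the summed
local interactions.

The workflow then iterates: any residue whose best state beats every
alternative by more than the cutoff (default 1 kcal/mol) becomes *known*;
when a full pass fixes nothing, the first still-ambiguous residue is
*branched* — one copy of the system per degenerate state — and each branch
is processed recursively. The result is the set of unique, fully assigned
configurations, plus a label for every ASN/GLN/HIS: `fully_solvated`
(no protein h-bond), `fixed`, or `degenerate`.

The bundled energy table is an analytic water-dimer-like surface
(Morse-type radial well, −5 kcal/mol at 2.8 Å/180°, cos² angular falloff);
a user-supplied table in the documented TSV format can replace it
(`rapa table --out my_table.tsv`, edit, then `rapa run --table ...`).

## Worked example

Generate a synthetic motif of two facing asparagine amides (the classic
coupled-flip situation) and run the protocol:

```sh
rapa fixtures --kind asn_asn --out pair.pdb
rapa run pair.pdb -o out/ --log-level WARNING
```

prints

```
out/pair_rapa_0.pdb
out/pair_rapa_1.pdb
2 configuration(s) at cutoff 1.0 kcal/mol
```

The two amides h-bond to each other in either the flipped or the unflipped
arrangement with *exactly* equal energy, so both are kept: configuration 0
has both amides unflipped, configuration 1 has both flipped (a single flip
would face O against O and N against N — a clash — and is discarded). The
label report:

```
$ cat out/pair_report.tsv
chain	seqnum	resname	label	n_states_within_cutoff	best_energy	runner_up_gap
A	1	ASN	degenerate	2	-6.9309	0.0000
B	2	ASN	degenerate	1	-6.9309	14.7192
```

Residue A was branched on with two exactly tied states (runner-up gap
0.0000). Residue B's row reflects its evaluation *inside* a branch, after
A was already fixed: there its flip is uniquely determined (one state
within the cutoff, the alternative a ~15 kcal/mol clash), but it is still
labeled degenerate because its assignment differs between the two output
configurations.

Python API equivalent:

```python
from rapa import make_structure, build_energy_table, run

result = run(make_structure("asn_asn"), build_energy_table())
print(result.n_configurations)        # 2
print(result.labels[("A", 1, "")])    # 'degenerate'
```

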