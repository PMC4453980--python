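# shelxfrag

Semi-automatic modelling of disordered moieties in small-molecule crystal
structures: **shelxfrag** transfers idealized molecular fragments, together
with their stereochemical restraint dictionaries, from a plain-text database
into a SHELXL `.res` refinement file.  It is written for crystallographers
who would otherwise label difference-map peaks, assign free variables and
type SADI/DFIX/SIMU blocks by hand for every disordered solvent molecule or
rotating CF₃ group.

## What it does

Roughly a quarter of published small-molecule structures contain disorder:
some atoms occupy different positions in different unit cells, and each
alternative conformation must be modelled with fractional occupancy and
restrained geometry.  The manual workflow — find the Q peaks of the second
position, assign a free variable so the two components' occupancies sum to
one, then write distance and displacement restraints — is tedious and
error-prone for anything larger than a few atoms.

shelxfrag reduces it to one remark line inside the `.res` file:

```
REM DSR PUT OC(CF3)3 WITH O1 C1 C2 C3 C4 ON O1_1 C1_1 Q4 Q7 Q6 PART 2 OCC -21 RESI
```

which reads: place the database fragment `OC(CF3)3`, matching its atoms
O1 C1 C2 C3 C4 onto the structure's atoms O1/C1 of residue 1 and the
difference-map peaks Q4/Q7/Q6; put the copy in disorder group `PART 2` with
coded occupancy −21 (i.e. 1 − fv(2), so the two components sum to 1) inside
a new residue of the fragment's class.

The core of the placement is a least-squares rigid-body superposition
(Kabsch algorithm): with source atoms **s**ᵢ and target positions **t**ᵢ in
Cartesian Å (fractional coordinates are orthogonalized with the respective
cell, the fragment's own cell for the fragment), it finds the proper
rotation R and translation **t** minimizing

&nbsp;&nbsp;&nbsp;&nbsp;Σᵢ ‖ R(**s**ᵢ − s̄) + t̄ − **t**ᵢ ‖²

via SVD of the cross-covariance matrix, with a determinant correction so a
reflection is never returned — chirality is instead handled by an explicit
inversion switch (negation through the anchor centroid) that reaches the
enantiomeric conformer.  At least three non-collinear anchors are required.
All fragment atoms are then carried through the fitted transform, so e.g.
the nine fluorine atoms of a CF₃ rotor need not be matched to peaks at all;
the restraints take care of them during refinement.

Restraints come from the database entry (SADI/DFIX/DANG/FLAT/HFIX carried
through, suffixed `_CLASS` when a residue is assigned) or, on request, are
computed from the fragment geometry: bonds perceived by a covalent-radius
criterion, DFIX targets for 1,2 distances, DANG for 1,3 distances, and SADI
grouping of chemically equivalent bonds.  SIMU/RIGU displacement-parameter
restraints over the placed range are added when the entry lacks them.

## Worked example

```python
import shelxfrag as sf

db = sf.load_builtin_db()
text, truth = sf.build_fixture(sf.FixtureSpec())   # synthetic structure
new_text, result = sf.process_res_text(text, db)
print(len(result.placed_atoms), result.fit_rmsd, result.resi_number)
```

prints `14 7.6178987101777e-10 2`: all 14 atoms of the OC(CF₃)₃ group were
inserted, the five anchors were hit to numerical precision (the synthetic
target is noiseless), and the copy landed in the next free residue number.
The rewritten file gains six `SADI_CCF3` records, `SIMU_CCF3 O1 > F9`,
`RIGU_CCF3 O1 > F9`, a second free variable started at 0.5, and a
`RESI 2 CCF3` / `PART 2` block of atoms with coded occupancy −21; the three
consumed Q peaks are removed.

The same run from the shell:

```
$ shelxfrag -r demo.res
placed 14 atoms (fit rmsd 0.0000 A)
  PART 2, residue 2 CCF3, free variable 2
  SADI_CCF3 0.02 C1 C2 C1 C3 C1 C4
  ...
```

`shelxfrag -l` lists the database, `-s NEEDLE` searches it, `-e TAG` exports
a fragment as a `.res` template, `-i FILE` imports coordinates into a user
database (which shadows the shipped one on tag conflicts), and `-t` inverts
the fragment for the current placement.  The `examples/` scripts walk
through each capability.

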