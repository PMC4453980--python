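# Methods

## The model

A disordered moiety is represented as a rigid copy of an idealized fragment.
Each database entry carries its own unit cell (a `FRAG` card; Cartesian
entries use the dummy cell 1 1 1 90 90 90), so fragment coordinates are
first orthogonalized with that cell, target coordinates with the structure's
cell, and the fit happens entirely in Cartesian Å.  The orthogonalization
convention is **a** along x, **b** in the xy plane; the choice is
unobservable downstream because only rigid-body-invariant quantities leave
the geometry module, but fixing it makes the matrix upper-triangular and
testable (its determinant is the cell volume).  Fractional coordinates are
never wrapped into [0, 1): placements near cell faces legitimately produce
values outside it, and no periodic-image search is performed — anchors are
taken literally, as they appear in the file.

The superposition is the SVD-based Kabsch fit with determinant correction;
reflections are never returned.  Chirality is explicit instead: the
`invert` switch negates the fragment through the centroid of the *named
anchor atoms* (not the full-fragment centroid) before fitting, which keeps
the anchor correspondence meaningful and makes the inverted branch exactly
reproducible in tests.  Collinearity is detected on the second singular
value of the centered anchor matrices with a 1e-6 Å floor; below it the
rotation is underdetermined and the fit refuses.  Anchors are unweighted:
peak heights are not used, since the density evidence enters only through
the user's choice of anchors.

## File handling

The `.res` document model interprets only the cards the workflow needs
(CELL, SFAC, UNIT, FVAR, RESI, PART, atoms, Q peaks, HKLF, END) and carries
everything else through verbatim; writing an unedited model reproduces the
input byte for byte.  This is deliberately stricter than "don't damage the
file": it makes diffs after a placement exactly the placement.  Atom records
are recognized structurally (unknown first token, integer scattering-factor
index, ≥3 reals), `=` continuations are joined for interpretation but
preserved for output, and residue/part contexts are recomputed from the
cards preceding each atom, so every edit re-derives them from the current
text.  Newly written atom lines use 6-decimal coordinates and 5-decimal
occupancies, matching the refinement program's own output width; the exact
pre-rounding coordinates are additionally reported on the placement result
for callers that need them.

Coded occupancies follow the free-variable convention: |code| = 10·m + p
means p·fv(m), negative codes p·(1 − fv(m)), fv(1) being the overall scale
(treated as 1 in occupancy evaluation); codes of magnitude below 10 are
plain fixed occupancies.  New free variables start at 0.5 — an
uninformative 50:50 split that the subsequent least-squares refinement,
which is outside this package's scope, adjusts.

## The placement step

Targets may be atoms (optionally residue-qualified, `O1_1`) or Q peaks.
`PUT` leaves target atoms untouched; `REPLACE` deletes them.  Consumed Q
peaks are deleted in both modes: they are density evidence, not atoms, and
leaving them would duplicate scatterers.  With a residue request the
database atom names are kept (residue scoping guarantees uniqueness) and
restraint keywords get the `_CLASS` suffix; without one, colliding names
receive alphabetic suffixes within the 4-character limit and restraint atom
labels are rewritten accordingly.  The default residue number is the
smallest positive integer unused in the file; a pinned number already
holding a different class is refused rather than renumbered, since silently
moving existing residues could damage unrelated restraints.  The restraint
block is inserted directly after the SFAC/UNIT header, atoms immediately
before HKLF inside `RESI`/`PART` brackets.  The fragment is placed as real
atoms — the fit is done internally rather than by emitting FRAG/FEND cards
for the refinement program to process — so the output file is
refinement-ready as written.  The command line is kept in the file with a
`done` marker: provenance stays visible and re-running the tool on its own
output is a no-op.  No hydrogen atoms are placed; entries (except water)
omit them and instead ship `HFIX` cards, carried through for the refinement
program's riding-model treatment.

## Restraint generation

Bond perception uses single-bond covalent radii with an additive tolerance
of +0.40 Å and a 0.5 Å minimum separation — conventional crystallographic
defaults, exposed as parameters.  Calculated restraints emit one DFIX per
bond and, by default, one DANG per 1,3 pair (two bonds sharing an atom whose
endpoints are not themselves bonded); emitting bonds only is available via a
flag, since either reading of "restraints for all bonds" is defensible.
Standard uncertainties default to 0.02 Å (1,2) and 0.04 Å (1,3), the
refinement program's own defaults, and are printed only when they differ.
SADI grouping uses radius-1 colouring — element plus the sorted multiset of
neighbour elements at each endpoint — which refines element-pair classes
and never merges bonds of different element pairs; singleton groups fall
back to DFIX because similarity needs at least two distances.  FLAT records
are never computed, only carried from the database: no planarity-detection
threshold is defensible from geometry alone.

## The synthetic-data generator

Fixtures emulate the "peaks found, disorder identified" stage: a fragment
pushed through a known axis-angle rotation, translation and optional
inversion into a chosen cell, with some anchor images written as residue-1
atoms and the rest as Q peaks, and isotropic Gaussian noise (in Cartesian
space, the way difference-map peak scatter behaves) optionally applied to
the anchors.  The exact images of all fragment atoms are returned as ground
truth.  Anchor coordinates are written at 10 decimals so a noiseless
fixture is numerically exact and recovery can be asserted at the 1e-9 Å
level.  The generator is deterministic under a fixed seed.  What passing
tests on these fixtures do *not* show: behaviour on measured diffraction
data, refinement convergence, or the quality of real difference maps — the
generator produces geometry, not density, and the actual least-squares
refinement is explicitly out of scope.

## Defaults and problem sizes

The shipped database holds six idealized entries (water, OC(CF₃)₃, toluene,
twisted THF, dichloromethane, tert-butyl) with analytically constructed
geometries (ideal tetrahedral/hexagonal/twist-ring closed forms) and
hand-written restraint dictionaries; the OC(CF₃)₃ entry carries the full
six-line SADI dictionary of a CF₃ rotor with the deliberately soft 0.1 Å
s.u. on the 1,3 F···C distances that lets the groups tilt.  Property suites
run at sizes chosen to exercise the mathematics comfortably: 100 round-trip
fixtures, 200 random rigid transforms for Kabsch recovery, 200 noisy trials
(σ = 0.1 Å on 5 anchors) for the 5° rotation-recovery rate; the whole suite
runs in a few seconds.

## Known limitations

No space-group symmetry expansion or nearest-image handling: anchors must
be given in a consistent asymmetric-unit neighbourhood.  No torsional or
flexible fitting — fragments are rigid.  Which peaks belong to which
disorder component is the user's call; the tool never guesses, and rejects
ambiguous input (unequal anchor lists, bare names matching several residues)
instead of realigning it.  Line endings are normalized to `\n` on output.
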