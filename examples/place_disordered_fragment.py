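"""Place a disordered perfluoro-tert-butoxide group onto difference-map peaks.

Builds a small synthetic structure (cubic 20 A cell) whose residue-1 atoms
O1/C1 and Q peaks Q4/Q7/Q6 mark the second position of an OC(CF3)3 moiety,
then executes the embedded placement command and reports what was done.
"""

import shelxfrag as sf

db = sf.load_builtin_db()

# the generator plays the role of a real refinement result: anchors are the
# images of the fragment under a known rigid motion
text, truth = sf.build_fixture(sf.FixtureSpec(), db)
print("embedded command:")
print("  " + sf.extract_command(sf.parse_res(text)))

new_text, result = sf.process_res_text(text, db)

print(f"\nplaced {len(result.placed_atoms)} atoms, "
      f"anchor fit rmsd {result.fit_rmsd:.2e} A")
print(f"assigned: PART {result.part}, RESI {result.resi_number} "
      f"{result.resi_class}, free variable {result.fv_index}")
print("restraints wired up:")
for rec in result.applied_restraints:
    print("  " + rec)

model = sf.parse_res(new_text)
worst = max(sf.distance(frac, truth[a.name], model.cell)
            for a, frac in zip(sf.lookup(db, "OC(CF3)3").atoms,
                               result.placed_frac))
print(f"\nmax deviation from ground truth: {worst:.2e} A")
print("Q peaks remaining:", len(model.qpeaks()),
      "(consumed peaks are removed so no scatterer is duplicated)")
# The rmsd and deviation are at numerical precision because the fixture is
# noiseless; the -21 coded occupancy ties this component's occupancy to
# 1 - fv(2), so both disorder parts sum to one.
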