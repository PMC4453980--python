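"""Derive distance restraints from fragment geometry.

Bond perception uses covalent radii (+0.40 A tolerance); DFIX records carry
the measured 1,2 distances, DANG the 1,3 distances (the distance form of a
bond angle), and SADI groups chemically equivalent bonds instead of pinning
target values.
"""

import shelxfrag as sf

db = sf.load_builtin_db()
ccf3 = sf.lookup(db, "OC(CF3)3")

bonds = sf.infer_connectivity(ccf3)
print(f"{len(bonds)} bonds perceived in OC(CF3)3:")
for b in bonds:
    print(f"  {b.atom1:<3}-{b.atom2:<3} {b.length:.3f} A")

print("\ntarget-value restraints (DFIX = bonds, DANG = 1,3 distances):")
for rec in sf.make_distance_restraints(ccf3):
    print("  " + rec)

print("\nsimilarity grouping (SADI, one group per equivalent bond class):")
for rec in sf.group_equivalent(bonds, ccf3):
    print("  " + rec)
# The 9 C-F bonds collapse to one SADI group and the three central C-C bonds
# to another; the unique O1-C1 bond falls back to a DFIX target.
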