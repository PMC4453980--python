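"""Fit the second (enantiomeric) twist conformer of tetrahydrofuran.

The twisted THF ring is chiral: a proper rotation can never superpose it on
its mirror image.  The placement engine therefore offers an inversion switch
that negates the fragment through the centroid of its anchor atoms before
fitting.
"""

import shelxfrag as sf

db = sf.load_builtin_db()
kw = dict(fragment_tag="THF",
          atom_anchors=(("O1", "O1"),),
          peak_anchors=(("C2", "Q1"), ("C3", "Q2"), ("C4", "Q3"),
                        ("C5", "Q4")),
          part=None, occ=None, resi=True, resi1_class="THF",
          invert=True)          # the fixture holds the *other* enantiomer

text, _ = sf.build_fixture(sf.FixtureSpec(**kw), db)
_out, plain = sf.process_res_text(text, db, invert=False)
text, _ = sf.build_fixture(sf.FixtureSpec(**kw), db)
_out, inverted = sf.process_res_text(text, db, invert=True)

print(f"fit rmsd without inversion: {plain.fit_rmsd:.4f} A")
print(f"fit rmsd with inversion:    {inverted.fit_rmsd:.2e} A")
# Only the inverted branch reaches the enantiomer; the residual of the
# uninverted fit is the geometric mismatch between the two twist forms.
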