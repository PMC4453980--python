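"""List, search and export entries of the fragment database."""

import shelxfrag as sf

db = sf.load_builtin_db()

print("shipped fragments:")
for tag, cls, n, src in sf.list_entries(db):
    print(f"  {tag:<12} residue class {cls:<5} {n:>2} atoms  [{src}]")

print("\nsearch 'tol' ->", sf.search(db, "tol"))

print("\nwater as a standalone .res template:")
print(sf.export_fragment(sf.lookup(db, "water"), "res-template"))
# The template carries the fragment's own cell and one scattering-factor
# entry per element, so it can be opened directly in refinement GUIs.
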