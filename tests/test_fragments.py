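"""Fragment-database parsing, lookup precedence, import/export round trips."""

import numpy as np
import pytest

import shelxfrag as sf
from shelxfrag.errors import (DbParseError, DbValidationError,
                              FragmentNotFoundError)
from shelxfrag.fragments import USER_DB, parse_db, validate_entry

from conftest import MINIMAL_WATER_DB


def test_minimal_water_entry_parses():
    entries = parse_db(MINIMAL_WATER_DB)
    assert len(entries) == 1
    e = entries[0]
    assert e.tag == "water" and e.resi_class == "H2O"
    assert [a.element for a in e.atoms] == ["O", "H", "H"]
    assert e.restraints == ["DFIX 0.9584 O1 H1 O1 H2"]


def test_ccf3_entry_is_the_14_atom_moiety(ccf3):
    assert len(ccf3.atoms) == 14
    assert ccf3.resi_class == "CCF3"
    assert ccf3.atom_names() == (
        ["O1", "C1", "C2", "C3", "C4"] + [f"F{i}" for i in range(1, 10)])
    # restraint block = the published SADI dictionary without residue suffix
    sadi = [r for r in ccf3.restraints if r.startswith("SADI")]
    assert len(sadi) == 6
    assert sadi[0].split() == "SADI 0.02 C1 C2 C1 C3 C1 C4".split()
    assert sadi[1].split() == ("SADI 0.02 F1 C2 F2 C2 F3 C2 F4 C3 F5 C3 "
                               "F6 C3 F7 C4 F8 C4 F9 C4").split()
    assert sadi[5].split()[1] == "0.1"


def test_continuation_lines_joined_into_one_record():
    txt = MINIMAL_WATER_DB.replace(
        "DFIX 0.9584 O1 H1 O1 H2", "DFIX 0.9584 O1 H1 =\n  O1 H2")
    e = parse_db(txt)[0]
    assert e.restraints == ["DFIX 0.9584 O1 H1 O1 H2"]


@pytest.mark.parametrize("mutation, exc", [
    (lambda t: t.replace("</water>", ""), DbParseError),          # no end tag
    (lambda t: t.replace("RESI H2O\n", ""), DbValidationError),   # no class
    (lambda t: t.replace("FRAG 17 1 1 1 90 90 90\n", ""), DbValidationError),
    (lambda t: t.replace("O1 -8 0 0 0", "O1 -8 0 0"), DbParseError),
    (lambda t: t.replace("H2", "H1"), DbValidationError),         # dup name
    (lambda t: t.replace("O1 H2", "O1 H9"), DbValidationError),   # bad ref
])
def test_malformed_entries_rejected(mutation, exc):
    with pytest.raises(exc):
        parse_db(mutation(MINIMAL_WATER_DB))


def test_negative_sfac_maps_atomic_number_to_element():
    for z in (1, 6, 8, 17, 26, 92, 103):
        txt = (f"<x>\nRESI XXX\nFRAG 17 1 1 1 90 90 90\n"
               f"A1 {-z} 0 0 0\n</x>\n")
        e = parse_db(txt)[0]
        assert sf.FragmentEntry is type(e)
        from shelxfrag.elements import number_for_symbol
        assert number_for_symbol(e.atoms[0].element) == z


def test_positive_sfac_needs_entry_sfac_line():
    ok = ("<x>\nRESI XXX\nSFAC C O\nFRAG 17 1 1 1 90 90 90\n"
          "A1 2 0 0 0\n</x>\n")
    assert parse_db(ok)[0].atoms[0].element == "O"
    with pytest.raises(DbParseError):
        parse_db("<x>\nRESI XXX\nFRAG 17 1 1 1 90 90 90\nA1 2 0 0 0\n</x>\n")


def test_lookup_is_case_insensitive_and_user_db_wins(db):
    assert sf.lookup(db, "oc(cf3)3").tag == "OC(CF3)3"
    override = parse_db(MINIMAL_WATER_DB.replace("water", "OC(CF3)3"),
                        source=USER_DB)
    merged = db + override
    assert sf.lookup(merged, "OC(CF3)3").source == USER_DB
    with pytest.raises(FragmentNotFoundError):
        sf.lookup(db, "nonexistent")


def test_near_matches_reported_for_unknown_tag(db):
    with pytest.raises(FragmentNotFoundError) as err:
        sf.lookup(db, "toluen")
    assert "toluene" in str(err.value)


def test_db_text_export_round_trips_every_shipped_entry(db):
    for e in db:
        again = parse_db(sf.export_fragment(e, "db-text"), source=e.source)[0]
        assert again.model_equal(e), e.tag


def test_every_shipped_entry_passes_validation(db):
    for e in db:
        validate_entry(e, placeable=True)


def test_res_template_water(db):
    text = sf.export_fragment(sf.lookup(db, "water"), "res-template")
    model = sf.parse_res(text)
    assert len(model.real_atoms()) == 3
    assert "CELL 0.71073 1 1 1 90 90 90" in text


def test_res_template_ccf3_sfac_elements(ccf3):
    model = sf.parse_res(sf.export_fragment(ccf3, "res-template"))
    assert sorted(model.sfac) == ["C", "F", "O"]


def test_import_cartesian_identity_and_roundtrip():
    rows = [("N1", "N", 0.0, 0.0, 0.0), ("C1", "C", 1.47, 0.0, 0.0),
            ("C2", "C", 2.2, 1.3, 0.0)]
    e = sf.import_fragment(rows, "cartesian", tag="amine", resi_class="AMI")
    assert np.allclose(e.coords_array(), [r[2:] for r in rows])
    assert e.cell == sf.UnitCell(1, 1, 1, 90, 90, 90)
    again = parse_db(sf.export_fragment(e, "db-text"), source=e.source)[0]
    assert again.model_equal(e)


def test_import_fractional_requires_cell_and_rejects_empty():
    with pytest.raises(DbValidationError):
        sf.import_fragment([("A1", "C", 0, 0, 0)], "fractional",
                           tag="x", resi_class="X")
    with pytest.raises(DbValidationError):
        sf.import_fragment([], "cartesian", tag="x", resi_class="X")
    with pytest.raises(DbValidationError):
        sf.import_fragment([("A1", "C", 0, 0, 0), ("a1", "C", 1, 0, 0),
                            ("B1", "C", 0, 1, 0)],
                           "cartesian", tag="x", resi_class="X")


def test_list_and_search(db):
    rows = sf.list_entries(db)
    assert ("OC(CF3)3", "CCF3", 14, "main-db") in rows
    assert sf.search(db, "tol")[0] == "toluene"
    assert sf.search(db, "THF")[0] == "THF"
    extra = parse_db(MINIMAL_WATER_DB.replace("water", "water2"),
                     source=USER_DB)
    merged = db + extra
    assert {r[3] for r in sf.list_entries(merged)} == {"main-db", "user-db"}
    assert sf.search(merged, "water")[0] == "water"
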