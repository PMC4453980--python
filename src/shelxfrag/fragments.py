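"""The plain-text fragment database: parsing, lookup, import and export.

A database file is a sequence of tagged blocks::

    <tag>
    RESI CLASS
    ...restraint and REM comment lines (SHELXL syntax, ``=`` continuation)...
    FRAG 17 a b c alpha beta gamma
    NAME SFAC x y z        (one atom per line; negative SFAC = atomic number)
    </tag>

Two files are consulted: the main database shipped with the package and an
optional user database.  On a tag conflict the user entry wins, so local
additions and overrides survive package updates.

Atom coordinates are fractional in the fragment's *own* cell (the FRAG card);
Cartesian entries simply use the dummy cell 1 1 1 90 90 90, for which
fractional and Cartesian coincide.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from . import elements
from .cell import UnitCell
from .errors import DbParseError, DbValidationError, FragmentNotFoundError

__all__ = [
    "FragmentAtom", "FragmentEntry", "parse_db", "load_builtin_db",
    "load_databases", "lookup", "import_fragment", "export_fragment",
    "list_entries", "search",
]

MAIN_DB = "main-db"
USER_DB = "user-db"

# restraint cards whose non-numeric arguments must be atom names of the entry
_RESTRAINT_CARDS = {
    "DFIX", "DANG", "SADI", "SAME", "FLAT", "CHIV", "DELU", "SIMU", "RIGU",
    "ISOR", "EADP", "EXYZ", "BUMP", "HFIX", "AFIX", "NCSY", "BIND", "FREE",
}


@dataclass(frozen=True)
class FragmentAtom:
    name: str
    element: str
    coords: np.ndarray  # fractional in the fragment's own cell

    def __eq__(self, other):
        if not isinstance(other, FragmentAtom):
            return NotImplemented
        return (self.name == other.name and self.element == other.element
                and np.allclose(self.coords, other.coords, atol=1e-12))


@dataclass
class FragmentEntry:
    """One database entry: geometry plus its restraint dictionary."""

    tag: str
    resi_class: str
    cell: UnitCell
    afix_code: int
    atoms: list[FragmentAtom]
    restraints: list[str] = field(default_factory=list)
    comments: list[str] = field(default_factory=list)
    source: str = MAIN_DB

    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def atom(self, name: str) -> FragmentAtom:
        key = name.upper()
        for a in self.atoms:
            if a.name.upper() == key:
                return a
        raise DbValidationError(f"fragment {self.tag!r} has no atom {name!r}")

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def has_restraint_card(self, card: str) -> bool:
        card = card.upper()
        return any(r.split(None, 1)[0].upper().split("_")[0] == card
                   for r in self.restraints if r.split())

    def model_equal(self, other: "FragmentEntry") -> bool:
        """Field-level equality ignoring provenance."""
        return (self.tag == other.tag
                and self.resi_class == other.resi_class
                and self.cell == other.cell
                and self.afix_code == other.afix_code
                and self.atoms == other.atoms
                and [r.split() for r in self.restraints]
                == [r.split() for r in other.restraints]
                and [c.split() for c in self.comments]
                == [c.split() for c in other.comments])


def _join_continuations(lines: list[tuple[int, str]]) -> list[tuple[int, str]]:
    """Join SHELX ``=`` continuations; keeps the first physical line number."""
    out: list[tuple[int, str]] = []
    pending: tuple[int, str] | None = None
    for no, line in lines:
        if pending is not None:
            no0, head = pending
            line = head + " " + line.strip()
            no = no0
            pending = None
        stripped = line.rstrip()
        if stripped.endswith("="):
            pending = (no, stripped[:-1].rstrip())
        else:
            out.append((no, line))
    if pending is not None:
        out.append(pending)
    return out


def _resolve_element(token: str, sfac_line: list[str] | None, line_no: int) -> str:
    try:
        num = int(token)
    except ValueError:
        if elements.is_element(token):
            return elements.symbol_for_number(elements.number_for_symbol(token))
        raise DbParseError(f"cannot resolve element from {token!r}", line_no)
    if num < 0:
        try:
            return elements.symbol_for_number(-num)
        except ValueError as exc:
            raise DbParseError(str(exc), line_no) from None
    if num == 0:
        raise DbParseError("SFAC number 0 is not valid", line_no)
    if sfac_line is None:
        raise DbParseError(
            f"positive SFAC index {num} but the entry carries no SFAC line",
            line_no)
    if num > len(sfac_line):
        raise DbParseError(f"SFAC index {num} out of range", line_no)
    return elements.symbol_for_number(elements.number_for_symbol(sfac_line[num - 1]))


def _restraint_atom_tokens(record: str) -> list[str]:
    toks = record.split()
    if not toks:
        return []
    card = toks[0].upper().split("_")[0]
    if card not in _RESTRAINT_CARDS:
        return []
    names = []
    for t in toks[1:]:
        if t == ">" or t == "<":
            continue
        try:
            float(t)
            continue
        except ValueError:
            names.append(t)
    return names


def validate_entry(entry: FragmentEntry, placeable: bool = True) -> None:
    """Enforce the database contract on one entry."""
    if not entry.resi_class:
        raise DbValidationError(f"fragment {entry.tag!r}: RESI class is required")
    if not entry.atoms:
        raise DbValidationError(f"fragment {entry.tag!r}: no atoms")
    if placeable and len(entry.atoms) < 3:
        raise DbValidationError(
            f"fragment {entry.tag!r}: placeable fragments need at least 3 atoms")
    seen: set[str] = set()
    for a in entry.atoms:
        key = a.name.upper()
        if key in seen:
            raise DbValidationError(
                f"fragment {entry.tag!r}: duplicate atom name {a.name!r}")
        seen.add(key)
        if not elements.is_element(a.element):
            raise DbValidationError(
                f"fragment {entry.tag!r}: invalid element {a.element!r}")
    names = {a.name.upper() for a in entry.atoms}
    for rec in entry.restraints:
        for tok in _restraint_atom_tokens(rec):
            if tok.upper() not in names:
                raise DbValidationError(
                    f"fragment {entry.tag!r}: restraint references unknown "
                    f"atom {tok!r} in record {rec!r}")


def parse_db(text: str, source: str = MAIN_DB) -> list[FragmentEntry]:
    """Parse a database file into validated entries."""
    entries: list[FragmentEntry] = []
    numbered = list(enumerate(text.splitlines(), start=1))
    i = 0
    start_re = re.compile(r"^<([^/>][^>]*)>\s*$")
    while i < len(numbered):
        no, line = numbered[i]
        stripped = line.strip()
        if not stripped:
            i += 1
            continue
        m = start_re.match(stripped)
        if not m:
            raise DbParseError(f"expected a start tag, got {stripped!r}", no)
        tag = m.group(1)
        end_token = f"</{tag}>"
        block: list[tuple[int, str]] = []
        i += 1
        closed = False
        while i < len(numbered):
            no2, line2 = numbered[i]
            if line2.strip().lower() == end_token.lower():
                closed = True
                i += 1
                break
            block.append((no2, line2))
            i += 1
        if not closed:
            raise DbParseError(f"missing end tag {end_token!r} for <{tag}>", no)
        entries.append(_parse_entry(tag, block, source))
    return entries


def _parse_entry(tag: str, block: list[tuple[int, str]], source: str) -> FragmentEntry:
    logical = _join_continuations([(n, l) for n, l in block if l.strip()])
    resi_class = ""
    restraints: list[str] = []
    comments: list[str] = []
    sfac_line: list[str] | None = None
    cell: UnitCell | None = None
    afix_code = 17
    atoms: list[FragmentAtom] = []
    frag_line_no = None
    in_atoms = False
    for no, line in logical:
        toks = line.split()
        card = toks[0].upper()
        if not in_atoms:
            if card == "RESI":
                if len(toks) < 2:
                    raise DbParseError("RESI line without a class", no)
                resi_class = toks[1]
            elif card == "REM" or line.lstrip().startswith("!"):
                comments.append(line.strip())
            elif card == "SFAC":
                sfac_line = toks[1:]
                restraints.append(" ".join(toks))
            elif card == "FRAG":
                if len(toks) != 8:
                    raise DbParseError(
                        "FRAG card needs an AFIX number and six cell parameters", no)
                try:
                    afix_code = int(toks[1])
                    params = [float(t) for t in toks[2:8]]
                except ValueError:
                    raise DbParseError("malformed FRAG card", no) from None
                cell = UnitCell(*params)
                frag_line_no = no
                in_atoms = True
            else:
                restraints.append(" ".join(toks))
        else:
            if card == "REM" or line.lstrip().startswith("!"):
                comments.append(line.strip())
                continue
            if len(toks) != 5:
                raise DbParseError(
                    f"atom line needs 'name sfac x y z' (got {len(toks)} fields)", no)
            name = toks[0]
            element = _resolve_element(toks[1], sfac_line, no)
            try:
                xyz = np.array([float(t) for t in toks[2:5]])
            except ValueError:
                raise DbParseError("non-numeric atom coordinate", no) from None
            atoms.append(FragmentAtom(name=name, element=element, coords=xyz))
    if not resi_class:
        raise DbValidationError(f"fragment {tag!r}: RESI class is required")
    if cell is None:
        raise DbValidationError(f"fragment {tag!r}: FRAG card is required")
    del frag_line_no
    entry = FragmentEntry(tag=tag, resi_class=resi_class, cell=cell,
                          afix_code=afix_code, atoms=atoms,
                          restraints=restraints, comments=comments, source=source)
    validate_entry(entry, placeable=False)
    return entry


def load_builtin_db() -> list[FragmentEntry]:
    """Entries of the database shipped with the package."""
    text = resources.files("shelxfrag").joinpath("data/dsr_db.txt").read_text()
    return parse_db(text, source=MAIN_DB)


def load_databases(main_path: str | Path | None = None,
                   user_path: str | Path | None = None) -> list[FragmentEntry]:
    """Load main + user databases; ``None`` main means the built-in file."""
    if main_path is None:
        entries = load_builtin_db()
    else:
        entries = parse_db(Path(main_path).read_text(), source=MAIN_DB)
    if user_path is not None and Path(user_path).exists():
        entries += parse_db(Path(user_path).read_text(), source=USER_DB)
    return entries


def lookup(databases: list[FragmentEntry], tag: str) -> FragmentEntry:
    """Case-insensitive tag lookup; user-database entries shadow main ones."""
    if not tag:
        raise FragmentNotFoundError(tag)
    key = tag.upper()
    hit: FragmentEntry | None = None
    for entry in databases:
        if entry.tag.upper() == key:
            if entry.source == USER_DB:
                return entry
            hit = hit or entry
    if hit is not None:
        return hit
    near = difflib.get_close_matches(tag, [e.tag for e in databases], n=3, cutoff=0.5)
    raise FragmentNotFoundError(tag, near)


def import_fragment(coords_source, mode: str, tag: str, resi_class: str,
                    cell: UnitCell | None = None,
                    source: str = USER_DB) -> FragmentEntry:
    """Build a new entry from raw coordinates.

    ``coords_source`` is an iterable of ``(name, element, x, y, z)`` tuples or
    a text block with one such record per line.  In ``cartesian`` mode a dummy
    1 Angstrom cubic cell is attached, so the stored fractional coordinates
    equal the Cartesian input; ``fractional`` mode requires ``cell``.
    No restraints are attached (see :mod:`shelxfrag.restraints` to generate
    some).
    """
    if mode not in ("cartesian", "fractional"):
        raise ValueError(f"mode must be cartesian|fractional, got {mode!r}")
    if isinstance(coords_source, str):
        rows = []
        for no, line in enumerate(coords_source.splitlines(), start=1):
            if not line.strip() or line.strip().upper().startswith("REM"):
                continue
            toks = line.split()
            if len(toks) != 5:
                raise DbParseError("expected 'name element x y z'", no)
            rows.append((toks[0], toks[1], *(float(t) for t in toks[2:5])))
    else:
        rows = [tuple(r) for r in coords_source]
    if not rows:
        raise DbValidationError("cannot import a fragment with no atoms")
    if mode == "cartesian":
        cell = UnitCell(1, 1, 1, 90, 90, 90)
    elif cell is None:
        raise DbValidationError("fractional import requires a cell")
    atoms = []
    for name, el, x, y, z in rows:
        symbol = elements.symbol_for_number(elements.number_for_symbol(str(el)))
        atoms.append(FragmentAtom(name=str(name), element=symbol,
                                  coords=np.array([x, y, z], dtype=float)))
    entry = FragmentEntry(tag=tag, resi_class=resi_class, cell=cell,
                          afix_code=17, atoms=atoms, source=source)
    validate_entry(entry, placeable=False)
    return entry


def _distinct_elements(entry: FragmentEntry) -> list[str]:
    out: list[str] = []
    for a in entry.atoms:
        if a.element not in out:
            out.append(a.element)
    return out


def export_fragment(entry: FragmentEntry, target: str = "db-text") -> str:
    """Serialize an entry as database text or as a standalone .res template."""
    if target == "db-text":
        lines = [f"<{entry.tag}>", f"RESI {entry.resi_class}"]
        lines += entry.comments
        lines += entry.restraints
        p = entry.cell.parameters()
        lines.append(f"FRAG {entry.afix_code} " + " ".join(_fmt_cell(v) for v in p))
        for a in entry.atoms:
            z = elements.number_for_symbol(a.element)
            lines.append(f"{a.name:<4} {-z:>3} "
                         + " ".join(f"{v:10.6f}" for v in a.coords))
        lines.append(f"</{entry.tag}>")
        return "\n".join(lines) + "\n"
    if target == "res-template":
        sfac = _distinct_elements(entry)
        index = {el: i + 1 for i, el in enumerate(sfac)}
        counts = [sum(1 for a in entry.atoms if a.element == el) for el in sfac]
        p = entry.cell.parameters()
        lines = [
            f"TITL {entry.tag} exported from the fragment database",
            "CELL 0.71073 " + " ".join(_fmt_cell(v) for v in p),
            "ZERR 1 0 0 0 0 0 0",
            "LATT -1",
            "SFAC " + " ".join(sfac),
            "UNIT " + " ".join(str(c) for c in counts),
        ]
        lines += entry.restraints
        lines.append("FVAR 1.00000")
        for a in entry.atoms:
            lines.append(f"{a.name:<4} {index[a.element]:>2} "
                         + " ".join(f"{v:10.6f}" for v in a.coords)
                         + "  11.00000  0.04000")
        lines.append("END")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown export target {target!r}")


def _fmt_cell(v: float) -> str:
    s = f"{v:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


def list_entries(databases: list[FragmentEntry]) -> list[tuple[str, str, int, str]]:
    """(tag, residue class, atom count, source) for every entry, sorted by tag."""
    return sorted(((e.tag, e.resi_class, len(e.atoms), e.source)
                   for e in databases), key=lambda t: t[0].lower())


def search(databases: list[FragmentEntry], needle: str) -> list[str]:
    """Rank tags by relevance to ``needle``: exact, substring, then fuzziness."""
    needle_l = needle.lower()
    scored = []
    for tag, cls, _n, _src in list_entries(databases):
        hay = tag.lower()
        ratio = difflib.SequenceMatcher(None, needle_l, hay).ratio()
        if hay == needle_l:
            rank = 0
        elif needle_l in hay or needle_l in cls.lower():
            rank = 1
        elif ratio >= 0.5:
            rank = 2
        else:
            continue
        scored.append((rank, -ratio, tag.lower(), tag))
    return [t for *_ignored, t in sorted(scored)]
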