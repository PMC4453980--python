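"""Execute a placement command against a structure model.

The engine realizes the whole semi-automatic disorder-modelling step:

1. resolve the target tokens (atoms and difference-map peaks) and convert
   them to Cartesian with the structure's cell;
2. rigid-fit the database fragment (orthogonalized with its *own* cell) onto
   those positions, optionally inverted;
3. insert all fragment atoms as fractional coordinates, wrapped in
   ``RESI``/``PART`` brackets, each carrying the command's coded occupancy;
4. extend the free-variable list when the occupancy code references a new
   free variable (new variables start at 0.5, an uninformative disorder
   split that the subsequent refinement adjusts);
5. append the restraint dictionary — the database block, or freshly
   calculated DFIX/DANG records on request — with per-residue ``_CLASS``
   suffixes, plus SIMU/RIGU similarity restraints over the placed range when
   the entry does not bring its own;
6. delete the consumed evidence: all targets under REPLACE, and consumed
   Q peaks always, since leaving placed density maxima in the file would
   duplicate scatterers.

The command line itself stays in the file, disarmed with a ``done`` marker,
so re-running the program on its own output is a no-op.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from . import restraints as rc
from .cell import cart_to_frac, frac_to_cart
from .command import DsrCommand, extract_command, parse_command
from .errors import ResidueCollisionError, ShelxFragError
from .fit import fit_fragment
from .fragments import FragmentEntry, lookup, validate_entry
from .resfile import (ResAtom, ResModel, encode_sof, format_atom_line)

__all__ = ["PlacementResult", "place_fragment", "make_adp_restraints",
           "assign_free_variable", "process_res_text"]


@dataclass
class PlacementResult:
    model: ResModel
    placed_atoms: list[ResAtom]
    applied_restraints: list[str]
    fit_rmsd: float
    placed_frac: np.ndarray      # exact fractional coordinates, pre-rounding
    part: int
    resi_class: str | None
    resi_number: int | None
    fv_index: int
    name_map: dict[str, str]


def make_adp_restraints(entry: FragmentEntry, placed_names: list[str],
                        resi_class: str | None = None) -> list[str]:
    """SIMU/RIGU over the placed non-hydrogen range, unless the entry
    already provides that card itself."""
    heavy = [n for n in placed_names if entry.atom(n).element != "H"]
    if not heavy:
        return []
    suffix = f"_{resi_class}" if resi_class else ""
    span = heavy[0] if heavy[0] == heavy[-1] else f"{heavy[0]} > {heavy[-1]}"
    records = []
    for card in ("SIMU", "RIGU"):
        if not entry.has_restraint_card(card):
            records.append(f"{card}{suffix} {span}")
    return records


def assign_free_variable(model: ResModel, occ_code: float) -> int:
    """Make sure the free variable referenced by ``occ_code`` exists.

    New variables (and any intermediate ones) start at 0.5.  Returns the
    index used, 0 for a plain fixed occupancy.
    """
    m, _p, sense = encode_sof(occ_code)
    if m == 1 and sense < 0:
        raise ShelxFragError(
            "free variable 1 is the overall scale factor and cannot carry a "
            "1-fv disorder occupancy")
    if m >= 2 and len(model.fvar) < m:
        model.set_fvar(m, 0.5)
    return m


_SUFFIXES = [chr(c) for c in range(ord("A"), ord("Z") + 1)]


def _free_name(base: str, taken: set[str]) -> str:
    """A collision-free SHELX atom name (<= 4 characters)."""
    if base.upper() not in taken:
        return base
    for s in _SUFFIXES:
        cand = (base + s) if len(base) < 4 else (base[:3] + s)
        if cand.upper() not in taken:
            return cand
    for s1 in _SUFFIXES:
        for s2 in _SUFFIXES:
            cand = (base[:2] + s1 + s2)
            if cand.upper() not in taken:
                return cand
    raise ShelxFragError(f"cannot find a free name for atom {base!r}")


def _rewrite_restraint_names(record: str, mapping: dict[str, str]) -> str:
    toks = record.split()
    out = [toks[0]]
    for t in toks[1:]:
        out.append(mapping.get(t.upper(), t))
    return " ".join(out)


def _suffix_restraint(record: str, resi_class: str) -> str:
    toks = record.split()
    if not toks:
        return record
    toks[0] = f"{toks[0]}_{resi_class}"
    return " ".join(toks)


def place_fragment(model: ResModel, command: DsrCommand,
                   databases: list[FragmentEntry],
                   invert: bool = False) -> PlacementResult:
    """Carry out one placement command.  Edits ``model`` in place."""
    entry = lookup(databases, command.fragment_tag)
    validate_entry(entry, placeable=True)

    # -- targets -> Cartesian ---------------------------------------------
    targets = [model.find_atom(tok) for tok in command.target_tokens]
    target_cart = np.array([frac_to_cart(a.frac, model.cell) for a in targets])

    # -- rigid fit ---------------------------------------------------------
    fit = fit_fragment(entry, list(command.source_names), target_cart,
                       invert=invert)
    placed_frac = cart_to_frac(fit.positions, model.cell)

    # -- residue assignment ------------------------------------------------
    resi_class: str | None = None
    resi_number: int | None = None
    if command.resi is not None:
        resi_class = command.resi.resi_class or entry.resi_class
        in_use = model.residue_numbers()
        if command.resi.number is not None:
            resi_number = command.resi.number
            existing = in_use.get(resi_number)
            if existing is not None and existing.upper() != resi_class.upper():
                raise ResidueCollisionError(
                    f"residue number {resi_number} already holds class "
                    f"{existing!r}, not {resi_class!r}")
        else:
            resi_number = 1
            while resi_number in in_use:
                resi_number += 1

    part = command.part if command.part is not None else 0
    occ = command.occ_code if command.occ_code is not None else 11.0
    fv_index = assign_free_variable(model, occ)

    # -- naming ------------------------------------------------------------
    name_map: dict[str, str] = {}
    if resi_class is not None:
        for a in entry.atoms:
            name_map[a.name.upper()] = a.name
    else:
        taken = set(model.atom_names())
        for a in entry.atoms:
            new = _free_name(a.name, taken)
            taken.add(new.upper())
            name_map[a.name.upper()] = new

    # -- scattering factors ------------------------------------------------
    _ensure_sfac(model, entry)
    sfac_index = {el.upper(): i + 1 for i, el in enumerate(model.sfac)}

    # -- restraint block ---------------------------------------------------
    if command.use_dfix:
        block = rc.calculated_restraints(entry)
    else:
        block = list(entry.restraints)
    block += make_adp_restraints(entry, [a.name for a in entry.atoms],
                                 resi_class=None)
    if resi_class is not None:
        block = [_suffix_restraint(r, resi_class) for r in block]
    else:
        block = [_rewrite_restraint_names(r, name_map) for r in block]

    # -- perform the edits -------------------------------------------------
    _disarm_command(model)
    to_delete = []
    for tok, atom in zip(command.target_tokens, targets):
        if atom.is_qpeak or command.action == "REPLACE":
            to_delete.append(tok)
    if to_delete:
        model.delete_atoms(to_delete)

    model.insert_lines(block, anchor=model.header_insert_index())

    atom_lines: list[str] = []
    if resi_number is not None:
        atom_lines.append(f"RESI {resi_number} {resi_class}")
    if part:
        atom_lines.append(f"PART {part}")
    for a, frac in zip(entry.atoms, placed_frac):
        atom_lines.append(format_atom_line(
            name_map[a.name.upper()],
            sfac_index[a.element.upper()], frac, occ))
    if part:
        atom_lines.append("PART 0")
    if resi_number is not None:
        atom_lines.append("RESI 0")
    model.insert_lines(atom_lines)

    placed_atoms = []
    for a in entry.atoms:
        tok = name_map[a.name.upper()]
        if resi_number:
            tok = f"{tok}_{resi_number}"
        placed_atoms.append(model.find_atom(tok))

    return PlacementResult(model=model, placed_atoms=placed_atoms,
                           applied_restraints=block, fit_rmsd=fit.rmsd,
                           placed_frac=placed_frac,
                           part=part, resi_class=resi_class,
                           resi_number=resi_number, fv_index=fv_index,
                           name_map={k: v for k, v in name_map.items()})


def _ensure_sfac(model: ResModel, entry: FragmentEntry) -> None:
    """Extend the SFAC (and UNIT) records with any new fragment elements."""
    have = {el.upper() for el in model.sfac}
    missing: list[str] = []
    for a in entry.atoms:
        if a.element.upper() not in have:
            have.add(a.element.upper())
            missing.append(a.element)
    if not missing:
        return
    if not model._sfac_lines:
        raise ShelxFragError("file has no SFAC record to extend")
    counts = {el: sum(1 for a in entry.atoms if a.element == el)
              for el in missing}
    last_sfac = model._sfac_lines[-1]
    model.lines[last_sfac] = (model.lines[last_sfac].rstrip()
                              + " " + " ".join(missing))
    if model._unit_line is not None:
        extra = " ".join(str(counts[el]) for el in missing)
        model.lines[model._unit_line] = (model.lines[model._unit_line].rstrip()
                                         + " " + extra)
    model._reparse()


def _disarm_command(model: ResModel) -> None:
    """Mark the active command line as done so the edit is idempotent."""
    for text, idxs in list(model._logical_records()):
        toks = text.split()
        if len(toks) >= 3 and toks[0].upper() == "REM" \
                and toks[1].upper() == "DSR" \
                and toks[2].upper() in ("PUT", "REPLACE"):
            first = idxs[0]
            line = model.lines[first]
            m = re.match(r"(\s*\S+\s+\S+)(\s+)", line)
            model.lines[first] = (f"{m.group(1)} done{m.group(2)}"
                                  + line[m.end():]) if m else ("REM DSR done " + line)
    model._reparse()


def process_res_text(text: str, databases: list[FragmentEntry],
                     invert: bool = False
                     ) -> tuple[str, PlacementResult | None]:
    """Top-level read-modify-write on .res text.

    Extracts the embedded command, executes it and returns the updated text.
    With no active command the text is returned unchanged and the result is
    ``None``.
    """
    model = ResModel(text)
    raw = extract_command(model)
    if raw is None:
        return text, None
    command = parse_command(raw)
    result = place_fragment(model, command, databases, invert=invert)
    return model.write(), result
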