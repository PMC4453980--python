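"""Round-trippable document model of a SHELXL ``.res``/``.ins`` file.

The model keeps every physical line verbatim; only the cards the placement
workflow needs are interpreted (CELL, SFAC, UNIT, FVAR, RESI, PART, AFIX,
atom records, Q peaks, HKLF, END).  Writing an unedited model reproduces the
input byte for byte.  Edits (delete/insert/FVAR updates) splice lines and
re-derive the interpreted view, so residue/part contexts always reflect the
current text.

Atom records are recognized structurally: the first token is not a known
instruction card, the second token is an integer scattering-factor index, and
at least three reals follow.  Q peaks are atom records named ``Q<digits>``;
SHELXL appends them after END, but they are accepted anywhere.

Coded site occupancies follow the SHELXL free-variable convention: a code of
``10*m + p`` means ``p * fv(m)``, a negative code means ``p * (1 - fv(m))``,
and ``fv(1)`` is the overall scale factor, treated as 1 when evaluating
occupancies.  Codes with magnitude below 10 are plain fixed occupancies.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .cell import UnitCell
from .errors import (AmbiguousAtomError, InvalidSofCodeError, ResParseError,
                     UnknownAtomError)

__all__ = ["ResAtom", "ResModel", "parse_res", "encode_sof", "decode_sof",
           "evaluate_sof"]

# SHELXL instruction vocabulary (first four characters are significant)
_KNOWN_CARDS = {
    "TITL", "CELL", "ZERR", "LATT", "SYMM", "SFAC", "DISP", "UNIT", "LAUE",
    "REM", "MORE", "TIME", "END", "HKLF", "OMIT", "SHEL", "BASF", "TWIN",
    "EXTI", "SWAT", "HOPE", "MERG", "SPEC", "RESI", "MOVE", "ANIS", "AFIX",
    "HFIX", "FRAG", "FEND", "EXYZ", "EADP", "EQIV", "CONN", "PART", "BIND",
    "FREE", "DFIX", "DANG", "BUMP", "SAME", "SADI", "CHIV", "FLAT", "DELU",
    "SIMU", "RIGU", "DEFS", "ISOR", "NCSY", "SUMP", "L.S.", "CGLS", "BLOC",
    "DAMP", "STIR", "WGHT", "FVAR", "BOND", "CONF", "MPLA", "RTAB", "HTAB",
    "LIST", "ACTA", "SIZE", "TEMP", "FMAP", "GRID", "PLAN", "MOLE", "WPDB",
    "ABIN", "ANSC", "ANSR", "NEUT", "PRIG", "XNPD", "TANG",
}

_QPEAK_RE = re.compile(r"^Q\d+$", re.IGNORECASE)


def _card_of(token: str) -> str | None:
    base = token.upper().split("_")[0]
    if base in _KNOWN_CARDS or base[:4] in _KNOWN_CARDS:
        return base[:4] if base[:4] in _KNOWN_CARDS else base
    return None


def _is_int(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False


def _floats(tokens: list[str]) -> list[float] | None:
    out = []
    for t in tokens:
        try:
            out.append(float(t))
        except ValueError:
            return None
    return out


@dataclass
class ResAtom:
    """One atom (or difference-map peak) with its file context."""

    name: str
    sfac_index: int
    frac: np.ndarray
    sof_code: float = 11.0
    displacement: tuple[float, ...] = (0.05,)
    part: int = 0
    resi_class: str = ""
    resi_number: int = 0
    is_qpeak: bool = False
    line_index: int = -1       # first physical line of the record
    n_lines: int = 1           # physical lines (2 with '=' continuation)
    peak_height: float | None = None

    @property
    def element_index(self) -> int:
        return self.sfac_index

    def qualified_name(self) -> str:
        if self.resi_number:
            return f"{self.name}_{self.resi_number}"
        return self.name


class ResModel:
    """Ordered, editable view of a .res file.  Construct via :func:`parse_res`."""

    def __init__(self, text: str):
        self._trailing_newline = text.endswith("\n")
        self.lines: list[str] = text.split("\n")
        if self._trailing_newline:
            self.lines.pop()
        self.cell: UnitCell | None = None
        self.wavelength: float = 0.0
        self.sfac: list[str] = []
        self.unit: list[float] = []
        self.fvar: list[float] = []
        self.atoms: list[ResAtom] = []
        self.hklf_index: int | None = None
        self.end_index: int | None = None
        self._fvar_lines: list[int] = []
        self._sfac_lines: list[int] = []
        self._unit_line: int | None = None
        self._reparse()

    # -- parsing -----------------------------------------------------------

    def _logical_records(self):
        """Yield (text, [line indices]) with '=' continuations joined."""
        i = 0
        n = len(self.lines)
        while i < n:
            idxs = [i]
            text = self.lines[i]
            while text.rstrip().endswith("=") and idxs[-1] + 1 < n:
                nxt = idxs[-1] + 1
                text = text.rstrip()[:-1].rstrip() + " " + self.lines[nxt].strip()
                idxs.append(nxt)
            yield text, idxs
            i = idxs[-1] + 1

    def _reparse(self) -> None:
        self.cell = None
        self.sfac = []
        self.unit = []
        self.fvar = []
        self.atoms = []
        self.hklf_index = None
        self.end_index = None
        self._fvar_lines = []
        self._sfac_lines = []
        self._unit_line = None
        part = 0
        resi_class = ""
        resi_number = 0
        for text, idxs in self._logical_records():
            stripped = text.strip()
            if not stripped or stripped.startswith("!"):
                continue
            toks = stripped.split()
            card = _card_of(toks[0])
            if card == "CELL":
                vals = _floats(toks[1:8])
                if vals is None or len(vals) != 7:
                    raise ResParseError("CELL needs wavelength + 6 parameters",
                                        idxs[0] + 1)
                self.wavelength = vals[0]
                self.cell = UnitCell(*vals[1:])
            elif card == "SFAC":
                if len(toks) > 2 and _floats(toks[2:]) is not None:
                    self.sfac.append(toks[1])       # long form: label + numbers
                else:
                    self.sfac.extend(toks[1:])
                self._sfac_lines.extend(idxs)
            elif card == "UNIT":
                self.unit = _floats(toks[1:]) or []
                self._unit_line = idxs[0]
            elif card == "FVAR":
                vals = _floats(toks[1:])
                if vals is None:
                    raise ResParseError("non-numeric FVAR value", idxs[0] + 1)
                self.fvar.extend(vals)
                self._fvar_lines.extend(idxs)
            elif card == "RESI":
                cls, num = "", 0
                for t in toks[1:]:
                    if _is_int(t):
                        num = int(t)
                    else:
                        cls = t
                if num == 0:
                    cls = ""
                resi_class, resi_number = cls, num
            elif card == "PART":
                if len(toks) > 1 and _is_int(toks[1]):
                    part = int(toks[1])
                else:
                    part = 0
            elif card == "HKLF":
                if self.hklf_index is None:
                    self.hklf_index = idxs[0]
            elif card == "END":
                if self.end_index is None:
                    self.end_index = idxs[0]
            elif card is None and len(toks) >= 5 and _is_int(toks[1]):
                vals = _floats(toks[2:])
                if vals is None or len(vals) < 3 or len(toks[0]) > 4:
                    continue
                name = toks[0]
                sfac_index = int(toks[1])
                frac = np.array(vals[:3])
                sof = vals[3] if len(vals) > 3 else 11.0
                is_q = bool(_QPEAK_RE.match(name))
                disp = tuple(vals[4:10]) if len(vals) > 4 else (0.05,)
                height = None
                if is_q and len(vals) >= 6:
                    disp = (vals[4],)
                    height = vals[-1]
                if self.cell is None or not self.sfac:
                    raise ResParseError(
                        f"atom {name!r} before CELL/SFAC", idxs[0] + 1)
                if not 1 <= sfac_index <= len(self.sfac):
                    raise ResParseError(
                        f"atom {name!r}: SFAC index {sfac_index} out of range",
                        idxs[0] + 1)
                self.atoms.append(ResAtom(
                    name=name, sfac_index=sfac_index, frac=frac, sof_code=sof,
                    displacement=disp, part=part,
                    resi_class=resi_class, resi_number=resi_number,
                    is_qpeak=is_q, line_index=idxs[0], n_lines=len(idxs),
                    peak_height=height))
        if self.cell is None:
            raise ResParseError("file has no CELL record")
        if not self.sfac:
            raise ResParseError("file has no SFAC record")

    # -- output ------------------------------------------------------------

    def write(self) -> str:
        text = "\n".join(self.lines)
        if self._trailing_newline:
            text += "\n"
        return text

    # -- queries -----------------------------------------------------------

    def element_of(self, atom: ResAtom) -> str:
        return self.sfac[atom.sfac_index - 1]

    def qpeaks(self) -> list[ResAtom]:
        return [a for a in self.atoms if a.is_qpeak]

    def real_atoms(self) -> list[ResAtom]:
        return [a for a in self.atoms if not a.is_qpeak]

    def residue_numbers(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for a in self.atoms:
            if a.resi_number:
                out[a.resi_number] = a.resi_class
        # also honour RESI cards without atoms yet
        for text, _ in self._logical_records():
            toks = text.split()
            if toks and _card_of(toks[0]) == "RESI":
                num, cls = 0, ""
                for t in toks[1:]:
                    if _is_int(t):
                        num = int(t)
                    else:
                        cls = t
                if num:
                    out.setdefault(num, cls)
        return out

    def atom_names(self) -> set[str]:
        return {a.name.upper() for a in self.atoms if not a.is_qpeak}

    def find_atom(self, token: str) -> ResAtom:
        """Resolve ``X``, ``X_n`` or ``Qn`` to an atom/peak record."""
        if not token:
            raise UnknownAtomError("empty atom token")
        tok = token.strip()
        if _QPEAK_RE.match(tok):
            for a in self.atoms:
                if a.is_qpeak and a.name.upper() == tok.upper():
                    return a
            raise UnknownAtomError(f"no difference-map peak {tok!r} in the file")
        name, _, suffix = tok.partition("_")
        if suffix:
            try:
                num = int(suffix)
            except ValueError:
                raise UnknownAtomError(
                    f"bad residue suffix in {token!r}") from None
            for a in self.atoms:
                if a.resi_number == num and a.name.upper() == name.upper():
                    return a
            raise UnknownAtomError(f"no atom {name!r} in residue {num}")
        hits = [a for a in self.atoms
                if not a.is_qpeak and a.name.upper() == name.upper()]
        outside = [a for a in hits if a.resi_number == 0]
        if len(outside) == 1:
            return outside[0]
        if len(hits) == 1:
            return hits[0]
        if not hits:
            raise UnknownAtomError(f"no atom named {token!r}")
        raise AmbiguousAtomError(
            f"atom name {token!r} is ambiguous: "
            + ", ".join(a.qualified_name() for a in hits))

    # -- edits -------------------------------------------------------------

    def delete_atoms(self, names: list[str]) -> None:
        """Delete the listed atoms/peaks (tokens as for :meth:`find_atom`)."""
        doomed: set[int] = set()
        for token in names:
            a = self.find_atom(token)
            doomed.update(range(a.line_index, a.line_index + a.n_lines))
        self.lines = [l for i, l in enumerate(self.lines) if i not in doomed]
        self._reparse()

    def insert_lines(self, new_lines: list[str], anchor: int | None = None) -> None:
        """Insert physical lines; default anchor is just before HKLF
        (before END if there is no HKLF, else at the end of file)."""
        if anchor is None:
            if self.hklf_index is not None:
                anchor = self.hklf_index
            elif self.end_index is not None:
                anchor = self.end_index
            else:
                anchor = len(self.lines)
        self.lines[anchor:anchor] = list(new_lines)
        self._reparse()

    def set_fvar(self, index: int, value: float) -> None:
        """Set free variable ``index`` (>= 2), padding the list with 0.5."""
        if index < 2:
            raise InvalidSofCodeError(
                "free variable 1 is the overall scale and cannot be set")
        while len(self.fvar) < index:
            self.fvar.append(0.5)
        self.fvar[index - 1] = value
        self._rewrite_fvar()

    def _rewrite_fvar(self) -> None:
        body = " ".join(f"{v:.5f}" for v in self.fvar)
        new = f"FVAR {body}"
        if self._fvar_lines:
            first = self._fvar_lines[0]
            keep = [i for i, _ in enumerate(self.lines)
                    if i not in self._fvar_lines[1:]]
            self.lines = [self.lines[i] for i in keep]
            # first index is unchanged: continuation lines follow it
            self.lines[first] = new
        else:
            anchor = (self._unit_line + 1 if self._unit_line is not None
                      else len(self._sfac_lines) and self._sfac_lines[-1] + 1 or 0)
            self.lines.insert(anchor, new)
        self._reparse()

    def header_insert_index(self) -> int:
        """Line index just after the SFAC/UNIT header block."""
        if self._unit_line is not None:
            return self._unit_line + 1
        if self._sfac_lines:
            return self._sfac_lines[-1] + 1
        return 1


def parse_res(text: str) -> ResModel:
    """Parse SHELXL .res text into a :class:`ResModel`."""
    return ResModel(text)


def encode_sof(occ_code: float) -> tuple[int, float, int]:
    """Split a coded occupancy into ``(fv_index, factor, sense)``.

    ``sense`` is +1 for ``factor*fv`` and -1 for ``factor*(1-fv)``.
    Codes with ``0 < code < 10`` are plain fixed occupancies, returned as
    ``(0, code, +1)``.
    """
    if occ_code == 0:
        raise InvalidSofCodeError("occupancy code 0 is not valid")
    mag = abs(occ_code)
    if mag < 10.0:
        if occ_code < 0:
            raise InvalidSofCodeError(
                f"negative occupancy code {occ_code} must reference a free "
                "variable (|code| >= 10)")
        return (0, occ_code, 1)
    m = int(mag // 10)
    p = mag - 10.0 * m
    sense = -1 if occ_code < 0 else 1
    return (m, p, sense)


def decode_sof(fv_index: int, factor: float, sense: int) -> float:
    """Inverse of :func:`encode_sof`."""
    if fv_index == 0:
        if sense != 1 or not 0 < factor < 10:
            raise InvalidSofCodeError("fixed occupancy must be in (0, 10)")
        return factor
    if fv_index < 0:
        raise InvalidSofCodeError("free-variable index must be positive")
    code = 10.0 * fv_index + factor
    return -code if sense < 0 else code


def evaluate_sof(occ_code: float, fvar: list[float]) -> float:
    """Numeric occupancy for a coded sof given the FVAR list.

    ``fv(1)`` is the overall scale and is treated as 1 in occupancies.
    """
    m, p, sense = encode_sof(occ_code)
    if m == 0:
        return p
    fv = 1.0 if m == 1 else fvar[m - 1]
    return p * (1.0 - fv) if sense < 0 else p * fv


def format_atom_line(name: str, sfac_index: int, frac, sof_code: float,
                     u_iso: float = 0.04) -> str:
    """One atom record in SHELXL layout (6-decimal coords, 5-decimal sof)."""
    x, y, z = (float(v) for v in frac)
    return (f"{name:<4} {sfac_index:>2} {x:10.6f} {y:10.6f} {z:10.6f} "
            f"{sof_code:11.5f} {u_iso:10.5f}")
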