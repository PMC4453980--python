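"""The embedded placement command language.

A placement instruction is written into the .res file as a remark so the
refinement program ignores it::

    REM DSR PUT|REPLACE <fragment> WITH <src...> ON <tgt...>
            [PART n] [OCC code] [RESI [class [number]]] [DFIX]

``PUT`` adds the fragment and leaves the target atoms alone; ``REPLACE``
additionally deletes them.  Source atoms belong to the database fragment;
target tokens name atoms (optionally residue-qualified, ``O1_1``) or
difference-map peaks (``Q4``) of the structure.  ``RESI`` without arguments
means "use the fragment's database class with the next free residue number";
``DFIX`` asks for freshly calculated distance restraints instead of the
database dictionary.  Keywords after ON may appear in any order.  Long
commands may wrap with the usual SHELX ``=`` continuation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import (CommandSyntaxError, CorrespondenceMismatchError,
                     MultipleCommandsError, TooFewPointsError)
from .resfile import ResModel

__all__ = ["ResiSpec", "DsrCommand", "extract_command", "parse_command",
           "render_command"]

_OPTION_KEYWORDS = {"PART", "OCC", "RESI", "DFIX"}
_MARKER = "DSR"


@dataclass(frozen=True)
class ResiSpec:
    """Residue request: class ``None`` means "take the database class";
    number ``None`` means "pick the next free number"."""

    resi_class: str | None = None
    number: int | None = None


@dataclass(frozen=True)
class DsrCommand:
    action: str                      # "PUT" | "REPLACE"
    fragment_tag: str
    source_names: tuple[str, ...]
    target_tokens: tuple[str, ...]
    part: int | None = None
    occ_code: float | None = None
    resi: ResiSpec | None = None
    use_dfix: bool = False

    def __post_init__(self):
        if len(self.source_names) != len(self.target_tokens):
            raise CorrespondenceMismatchError(
                f"{len(self.source_names)} source atoms vs "
                f"{len(self.target_tokens)} target positions")
        if len(self.source_names) < 3:
            raise TooFewPointsError(
                "a placement needs at least three anchor pairs, got "
                f"{len(self.source_names)}")


def _command_records(model: ResModel):
    """Active command records as (text, line indices)."""
    hits = []
    for text, idxs in model._logical_records():
        toks = text.split()
        if len(toks) >= 3 and toks[0].upper() == "REM" \
                and toks[1].upper() == _MARKER \
                and toks[2].upper() in ("PUT", "REPLACE"):
            hits.append((text.strip(), idxs))
    return hits


def extract_command(model: ResModel) -> str | None:
    """The single active command line of a file (continuations joined).

    Returns ``None`` when the file holds no command (nothing to do); raises
    when several commands compete.
    """
    hits = _command_records(model)
    if not hits:
        return None
    if len(hits) > 1:
        raise MultipleCommandsError(
            f"found {len(hits)} placement commands; exactly one is allowed")
    return hits[0][0]


def parse_command(text: str) -> DsrCommand:
    """Parse one command line into a :class:`DsrCommand`."""
    toks = text.split()
    if len(toks) < 2 or toks[0].upper() != "REM" or toks[1].upper() != _MARKER:
        raise CommandSyntaxError(f"not a placement command: {text!r}")
    toks = toks[2:]
    if not toks:
        raise CommandSyntaxError("empty command after the REM marker")
    action = toks[0].upper()
    if action not in ("PUT", "REPLACE"):
        raise CommandSyntaxError(
            f"unknown action {toks[0]!r}; expected PUT or REPLACE")
    if len(toks) < 2:
        raise CommandSyntaxError("missing fragment name")
    tag = toks[1]
    pos = 2
    if pos >= len(toks) or toks[pos].upper() != "WITH":
        raise CommandSyntaxError("expected WITH after the fragment name")
    pos += 1
    sources: list[str] = []
    while pos < len(toks) and toks[pos].upper() != "ON":
        sources.append(toks[pos])
        pos += 1
    if pos >= len(toks):
        raise CommandSyntaxError("expected ON after the source atoms")
    pos += 1
    targets: list[str] = []
    while pos < len(toks) and toks[pos].upper() not in _OPTION_KEYWORDS:
        targets.append(toks[pos])
        pos += 1
    part: int | None = None
    occ: float | None = None
    resi: ResiSpec | None = None
    use_dfix = False
    while pos < len(toks):
        kw = toks[pos].upper()
        if kw == "PART":
            if pos + 1 >= len(toks):
                raise CommandSyntaxError("PART needs an integer argument")
            try:
                part = int(toks[pos + 1])
            except ValueError:
                raise CommandSyntaxError(
                    f"PART argument {toks[pos + 1]!r} is not an integer"
                ) from None
            pos += 2
        elif kw == "OCC":
            if pos + 1 >= len(toks):
                raise CommandSyntaxError("OCC needs a numeric argument")
            try:
                occ = float(toks[pos + 1])
            except ValueError:
                raise CommandSyntaxError(
                    f"OCC argument {toks[pos + 1]!r} is not numeric") from None
            pos += 2
        elif kw == "RESI":
            cls: str | None = None
            num: int | None = None
            pos += 1
            while pos < len(toks) and toks[pos].upper() not in _OPTION_KEYWORDS:
                t = toks[pos]
                try:
                    num = int(t)
                except ValueError:
                    if cls is not None:
                        raise CommandSyntaxError(
                            f"unexpected RESI token {t!r}") from None
                    cls = t
                pos += 1
            resi = ResiSpec(resi_class=cls, number=num)
        elif kw == "DFIX":
            use_dfix = True
            pos += 1
        else:
            raise CommandSyntaxError(f"unexpected token {toks[pos]!r}")
    if not sources or not targets:
        raise CommandSyntaxError("both WITH and ON atom lists are required")
    return DsrCommand(action=action, fragment_tag=tag,
                      source_names=tuple(sources),
                      target_tokens=tuple(targets),
                      part=part, occ_code=occ, resi=resi, use_dfix=use_dfix)


def _fmt_occ(v: float) -> str:
    return f"{v:g}"


def render_command(cmd: DsrCommand) -> str:
    """Pretty-print a command so that ``parse_command(render_command(c)) == c``."""
    parts = ["REM", _MARKER, cmd.action, cmd.fragment_tag, "WITH",
             *cmd.source_names, "ON", *cmd.target_tokens]
    if cmd.part is not None:
        parts += ["PART", str(cmd.part)]
    if cmd.occ_code is not None:
        parts += ["OCC", _fmt_occ(cmd.occ_code)]
    if cmd.resi is not None:
        parts.append("RESI")
        if cmd.resi.resi_class is not None:
            parts.append(cmd.resi.resi_class)
        if cmd.resi.number is not None:
            parts.append(str(cmd.resi.number))
    if cmd.use_dfix:
        parts.append("DFIX")
    return " ".join(parts)
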