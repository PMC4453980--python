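"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`ShelxFragError`
so callers (and the command-line wrapper) can catch one type and print a
one-line diagnostic.
"""


class ShelxFragError(Exception):
    """Base class for all package errors."""


class InvalidCellError(ShelxFragError):
    """Unit-cell parameters do not describe a realizable cell."""


class DbParseError(ShelxFragError):
    """Malformed fragment-database text."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DbValidationError(ShelxFragError):
    """A fragment entry violates the database contract."""


class FragmentNotFoundError(ShelxFragError):
    """Requested fragment tag is in neither database."""

    def __init__(self, tag: str, near: list[str] | None = None):
        near = near or []
        msg = f"fragment '{tag}' not found"
        if near:
            msg += "; did you mean: " + ", ".join(near)
        super().__init__(msg)
        self.tag = tag
        self.near = near


class ResParseError(ShelxFragError):
    """Malformed SHELXL .res content."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class UnknownAtomError(ShelxFragError):
    """An atom/peak token does not resolve in the structure."""


class AmbiguousAtomError(ShelxFragError):
    """A bare atom name matches several atoms in different residues."""


class CorrespondenceMismatchError(ShelxFragError):
    """Source and target anchor lists differ in length."""


class TooFewPointsError(ShelxFragError):
    """Fewer than three anchor points were supplied."""


class CollinearPointsError(ShelxFragError):
    """Anchor points are (near) collinear; the fit is underdetermined."""


class CommandSyntaxError(ShelxFragError):
    """The embedded placement command does not parse."""


class MultipleCommandsError(ShelxFragError):
    """More than one active placement command in one file."""


class InvalidSofCodeError(ShelxFragError):
    """A coded site-occupancy value is not a valid SHELXL code."""


class ResidueCollisionError(ShelxFragError):
    """The requested residue number is already used with a different class."""
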