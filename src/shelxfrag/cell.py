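"""Unit-cell metric computations.

Fractional coordinates live in the (generally oblique) basis spanned by the
cell vectors a, b, c; Cartesian coordinates are in Angstrom.  The
orthogonalization convention is the common SHELX/PDB one: **a** along the
Cartesian x axis, **b** in the xy plane.  With that convention the
orthogonalization matrix is upper triangular and its determinant equals the
cell volume.

Fractional coordinates are never wrapped into [0, 1): fragment placement may
legitimately produce coordinates outside that interval and they must survive
round trips unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidCellError

__all__ = ["UnitCell", "frac_to_cart", "cart_to_frac", "distance"]


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    # caches, not part of equality
    _orth: np.ndarray = field(init=False, repr=False, compare=False, default=None)
    _orth_inv: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise InvalidCellError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise InvalidCellError(f"cell angle {name}={ang} must lie in (0, 180)")
        ca, cb, cg = (math.cos(math.radians(getattr(self, n)))
                      for n in ("alpha", "beta", "gamma"))
        # squared volume of the unit parallelepiped; <= 0 means the three
        # angles cannot close a parallelepiped
        v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if v2 <= 0.0:
            raise InvalidCellError(
                f"cell angles ({self.alpha}, {self.beta}, {self.gamma}) give a "
                "non-positive metric determinant")
        sg = math.sin(math.radians(self.gamma))
        m = np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * math.sqrt(v2) / sg],
        ])
        object.__setattr__(self, "_orth", m)
        object.__setattr__(self, "_orth_inv", np.linalg.inv(m))

    @property
    def volume(self) -> float:
        """Cell volume in cubic Angstrom."""
        return float(np.linalg.det(self._orth))

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """Matrix M with cartesian = M @ fractional (upper triangular)."""
        return self._orth.copy()

    @property
    def fractionalization_matrix(self) -> np.ndarray:
        return self._orth_inv.copy()

    @property
    def metric_tensor(self) -> np.ndarray:
        """Real-space metric tensor G = Mᵀ M (squared lengths via ΔfᵀGΔf)."""
        return self._orth.T @ self._orth

    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def orthogonalization_matrix(cell: UnitCell) -> np.ndarray:
    """Fractional-to-Cartesian matrix for ``cell`` (a along x, b in xy)."""
    return cell.orthogonalization_matrix


def frac_to_cart(p, cell: UnitCell) -> np.ndarray:
    """Fractional -> Cartesian (Angstrom).  Accepts shape (3,) or (n, 3)."""
    p = np.asarray(p, dtype=float)
    return p @ cell._orth.T


def cart_to_frac(p, cell: UnitCell) -> np.ndarray:
    """Cartesian (Angstrom) -> fractional.  Accepts shape (3,) or (n, 3)."""
    p = np.asarray(p, dtype=float)
    return p @ cell._orth_inv.T


def distance(p1, p2, cell: UnitCell) -> float:
    """Distance in Angstrom between two fractional positions.

    No periodic-image search is performed: the points are taken literally.
    """
    d = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    return float(np.linalg.norm(cell._orth @ d))
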