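"""Least-squares rigid-body superposition (Kabsch algorithm).

The fit finds the proper rotation R and translation t minimizing
``sum_i || R (s_i - s_bar) + t_bar - t_i ||^2`` by SVD of the cross-covariance
matrix, with the usual determinant correction so a reflection is never
returned.  Chirality is handled explicitly instead: a fragment may be
*inverted* (negated through the centroid of its named anchor atoms) before
fitting, which reaches the enantiomeric conformer, e.g. the second twist form
of tetrahydrofuran.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import frac_to_cart
from .errors import (CollinearPointsError, CorrespondenceMismatchError,
                     TooFewPointsError)
from .fragments import FragmentEntry

__all__ = ["RigidTransform", "kabsch_fit", "fit_fragment", "FragmentFit"]

#: second-singular-value floor below which a point set counts as collinear
COLLINEARITY_TOL = 1e-6


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation; ``inverted`` records a pre-applied
    point inversion of the source fragment."""

    rotation: np.ndarray
    translation: np.ndarray
    inverted: bool = False

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to Cartesian points of shape (n, 3) or (3,).

        The ``inverted`` flag is bookkeeping only; inversion about the anchor
        centroid happens before the fit (see :func:`fit_fragment`).
        """
        p = np.asarray(points, dtype=float)
        return p @ np.asarray(self.rotation).T + np.asarray(self.translation)


def _check_points(pts: np.ndarray, label: str) -> np.ndarray:
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{label} points must have shape (n, 3)")
    if pts.shape[0] < 3:
        raise TooFewPointsError(
            f"need at least 3 {label} points, got {pts.shape[0]}")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < COLLINEARITY_TOL:
        raise CollinearPointsError(
            f"{label} points are collinear within {COLLINEARITY_TOL} A; "
            "the rotation is underdetermined")
    return pts


def kabsch_fit(source, target) -> tuple[RigidTransform, float]:
    """Best proper-rotation superposition of ``source`` onto ``target``.

    Returns the transform (``inverted=False``) and the rmsd in Angstrom over
    the fitted points.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise CorrespondenceMismatchError(
            f"source has {source.shape[0]} points but target has "
            f"{target.shape[0]}")
    source = _check_points(source, "source")
    target = _check_points(target, "target")
    s_bar = source.mean(axis=0)
    t_bar = target.mean(axis=0)
    h = (source - s_bar).T @ (target - t_bar)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = t_bar - rot @ s_bar
    tf = RigidTransform(rotation=rot, translation=trans)
    resid = tf.apply(source) - target
    rmsd = float(np.sqrt((resid ** 2).sum() / source.shape[0]))
    return tf, rmsd


@dataclass(frozen=True)
class FragmentFit:
    """All fragment atoms mapped into the target Cartesian frame."""

    names: tuple[str, ...]
    positions: np.ndarray          # (n_atoms, 3) Cartesian, target frame
    transform: RigidTransform
    rmsd: float

    def placements(self) -> list[tuple[str, np.ndarray]]:
        return [(n, p) for n, p in zip(self.names, self.positions)]


def fit_fragment(entry: FragmentEntry, source_names, target_points,
                 invert: bool = False) -> FragmentFit:
    """Fit a database fragment onto target Cartesian positions.

    Only the named subset anchors the fit; every fragment atom is then
    carried through the recovered transform, so e.g. fluorine atoms need not
    be matched to density peaks explicitly.  Fragment coordinates are first
    orthogonalized with the fragment's own cell.  With ``invert`` the
    fragment is negated through the centroid of the named source atoms before
    fitting, which selects the enantiomer.
    """
    target_points = np.asarray(target_points, dtype=float)
    names = list(source_names)
    if len(names) != target_points.shape[0]:
        raise CorrespondenceMismatchError(
            f"{len(names)} source atoms vs {target_points.shape[0]} targets")
    all_names = tuple(a.name for a in entry.atoms)
    cart = frac_to_cart(entry.coords_array(), entry.cell)
    index = {n.upper(): i for i, n in enumerate(all_names)}
    try:
        rows = [index[n.upper()] for n in names]
    except KeyError as exc:
        raise CorrespondenceMismatchError(
            f"fragment {entry.tag!r} has no atom {exc.args[0]!r}") from None
    if invert:
        center = cart[rows].mean(axis=0)
        cart = 2.0 * center - cart
    tf, rmsd = kabsch_fit(cart[rows], target_points)
    placed = tf.apply(cart)
    tf = RigidTransform(rotation=tf.rotation, translation=tf.translation,
                        inverted=invert)
    return FragmentFit(names=all_names, positions=placed, transform=tf,
                       rmsd=rmsd)
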