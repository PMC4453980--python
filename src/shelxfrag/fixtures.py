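"""Deterministic generator of synthetic target structures.

The generator emulates the situation the placement workflow is built for: a
structure whose difference-Fourier map shows the second position of a
disordered moiety.  A database fragment is pushed through a known rigid
motion (optionally an inversion) into a chosen unit cell; some anchor images
are written as ordinary residue-1 atoms, the rest as Q peaks, and optional
isotropic Gaussian noise (in Cartesian space, like real peak scatter) blurs
the anchors.  The exact images of *all* fragment atoms are returned as
ground truth so tests can assert recovery to numerical precision.

It does not simulate diffraction data or electron density — only the
geometry of a .res file at the "peaks found, disorder identified" stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .cell import UnitCell, cart_to_frac, frac_to_cart
from .fragments import FragmentEntry, load_builtin_db, lookup

__all__ = ["FixtureSpec", "build_fixture", "ground_truth_text",
           "parse_ground_truth"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic .res file.

    ``atom_anchors`` maps fragment atoms to named residue-1 atoms of the
    structure; ``peak_anchors`` maps fragment atoms to Q-peak labels.
    The rotation is an axis-angle pair; the translation is Cartesian (A).
    """

    cell: UnitCell = UnitCell(20.0, 20.0, 20.0, 90.0, 90.0, 90.0)
    fragment_tag: str = "OC(CF3)3"
    axis: tuple[float, float, float] = (1.0, 2.0, 3.0)
    angle_deg: float = 40.0
    translation: tuple[float, float, float] = (8.0, 9.0, 10.0)
    invert: bool = False
    atom_anchors: tuple[tuple[str, str], ...] = (("O1", "O1"), ("C1", "C1"))
    peak_anchors: tuple[tuple[str, str], ...] = (
        ("C2", "Q4"), ("C3", "Q7"), ("C4", "Q6"))
    noise_sigma: float = 0.0
    seed: int = 0
    part: int | None = 2
    occ: float | None = -21.0
    resi: bool = True
    include_command: bool = True
    resi1_class: str = "CCF3"


def _transformed_positions(entry: FragmentEntry, spec: FixtureSpec
                           ) -> dict[str, np.ndarray]:
    """Cartesian images of all fragment atoms under the spec's motion."""
    cart = frac_to_cart(entry.coords_array(), entry.cell)
    names = [a.name for a in entry.atoms]
    anchors = [s for s, _t in spec.atom_anchors + spec.peak_anchors]
    idx = {n.upper(): i for i, n in enumerate(names)}
    rows = [idx[a.upper()] for a in anchors]
    if spec.invert:
        center = cart[rows].mean(axis=0)
        cart = 2.0 * center - cart
    rot = Rotation.from_rotvec(
        np.deg2rad(spec.angle_deg) * np.asarray(spec.axis, dtype=float)
        / np.linalg.norm(spec.axis))
    cart = cart @ rot.as_matrix().T + np.asarray(spec.translation, dtype=float)
    return {n: c for n, c in zip(names, cart)}


def default_command(spec: FixtureSpec) -> str:
    sources = [s for s, _t in spec.atom_anchors + spec.peak_anchors]
    targets = [f"{t}_1" for _s, t in spec.atom_anchors] \
        + [t for _s, t in spec.peak_anchors]
    parts = ["REM DSR PUT", spec.fragment_tag,
             "WITH", *sources, "ON", *targets]
    if spec.part is not None:
        parts += ["PART", str(spec.part)]
    if spec.occ is not None:
        parts += ["OCC", f"{spec.occ:g}"]
    if spec.resi:
        parts.append("RESI")
    return " ".join(parts)


def build_fixture(spec: FixtureSpec,
                  databases: list[FragmentEntry] | None = None
                  ) -> tuple[str, dict[str, np.ndarray]]:
    """Emit (.res text, ground truth name -> fractional coordinates)."""
    if spec.noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    if databases is None:
        databases = load_builtin_db()
    entry = lookup(databases, spec.fragment_tag)
    images = _transformed_positions(entry, spec)
    truth = {n: cart_to_frac(c, spec.cell) for n, c in images.items()}

    rng = np.random.default_rng(spec.seed)

    def emitted(cart: np.ndarray) -> np.ndarray:
        if spec.noise_sigma > 0:
            cart = cart + rng.normal(0.0, spec.noise_sigma, size=3)
        return cart_to_frac(cart, spec.cell)

    elements = []
    for a in entry.atoms:
        if a.element not in elements:
            elements.append(a.element)
    sfac_index = {el: i + 1 for i, el in enumerate(elements)}
    counts = [sum(1 for a in entry.atoms if a.element == el)
              for el in elements]

    p = spec.cell.parameters()
    lines = [
        "TITL synthetic disorder fixture",
        "CELL 0.71073 " + " ".join(f"{v:g}" for v in p),
        "ZERR 1 0 0 0 0 0 0",
        "LATT -1",
        "SFAC " + " ".join(elements),
        "UNIT " + " ".join(str(c) for c in counts),
        "L.S. 10",
        "FVAR 1.00000",
    ]
    if spec.include_command:
        lines.append(default_command(spec))
    # anchors carry 10 decimals so a noiseless fixture is numerically exact
    lines.append(f"RESI 1 {spec.resi1_class}")
    for src, tgt in spec.atom_anchors:
        fr = emitted(images[src])
        el = entry.atom(src).element
        lines.append(f"{tgt:<4} {sfac_index[el]:>2} "
                     + " ".join(f"{v:14.10f}" for v in fr)
                     + "    11.00000    0.04000")
    lines += ["RESI 0", "HKLF 4", "END"]
    for src, tgt in spec.peak_anchors:
        fr = emitted(images[src])
        lines.append(f"{tgt:<4}  1 " + " ".join(f"{v:14.10f}" for v in fr)
                     + "    11.00000    0.05000    2.50")
    return "\n".join(lines) + "\n", truth


def ground_truth_text(truth: dict[str, np.ndarray]) -> str:
    """Plain-text sidecar: one ``name x y z`` (fractional) line per atom."""
    return "\n".join(
        f"{n:<4} " + " ".join(f"{v:.10f}" for v in fr)
        for n, fr in truth.items()) + "\n"


def parse_ground_truth(text: str) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        toks = line.split()
        out[toks[0]] = np.array([float(t) for t in toks[1:4]])
    return out
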