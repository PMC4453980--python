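"""Geometry-derived stereochemical restraints for a fragment.

Connectivity is perceived from the idealized geometry with a covalent-radius
criterion; from the bond graph the module emits SHELXL restraint records:

* ``DFIX`` for 1,2 distances (bonds) with the measured target value,
* ``DANG`` for 1,3 distances (the distance equivalent of a bond angle),
* optionally ``SADI`` groups of chemically equivalent bonds, where
  equivalence is decided by the element pair plus the elements of the
  immediate neighbourhood of each endpoint (radius-1 colouring).

Standard uncertainties default to the SHELXL conventions (0.02 A for 1,2 and
0.04 A for 1,3 records) and are printed only when they differ from them.
All targets are measured in the fragment's own cell, so they are invariant
under any rigid motion or re-expression of the fragment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .cell import distance
from .elements import covalent_radius
from .fragments import FragmentEntry

__all__ = ["Bond", "infer_connectivity", "make_distance_restraints",
           "group_equivalent", "calculated_restraints"]

#: additive tolerance on the covalent-radius sum, Angstrom
BOND_TOLERANCE = 0.40
#: below this separation two positions are considered duplicates, not bonded
MIN_BOND_LENGTH = 0.5

DEFAULT_SU_12 = 0.02
DEFAULT_SU_13 = 0.04


@dataclass(frozen=True)
class Bond:
    """An unordered 1,2 contact; atom order follows the entry's atom list."""

    atom1: str
    atom2: str
    length: float


def infer_connectivity(entry: FragmentEntry,
                       tolerance: float = BOND_TOLERANCE,
                       min_length: float = MIN_BOND_LENGTH) -> list[Bond]:
    """Perceive bonds: d(i, j) < r_cov(i) + r_cov(j) + tolerance, d > min.

    The result is sorted by the atom order of the entry, so it is
    deterministic for a given database entry.
    """
    bonds: list[Bond] = []
    atoms = entry.atoms
    for i, j in combinations(range(len(atoms)), 2):
        d = distance(atoms[i].coords, atoms[j].coords, entry.cell)
        cutoff = (covalent_radius(atoms[i].element)
                  + covalent_radius(atoms[j].element) + tolerance)
        if min_length < d < cutoff:
            bonds.append(Bond(atoms[i].name, atoms[j].name, d))
    return bonds


def _graph(entry: FragmentEntry, bonds: list[Bond]) -> nx.Graph:
    g = nx.Graph()
    for a in entry.atoms:
        g.add_node(a.name, element=a.element)
    for b in bonds:
        g.add_edge(b.atom1, b.atom2, length=b.length)
    return g


def _fmt(value: float) -> str:
    return f"{value:.3f}"


def _su(value: float, default: float) -> str:
    return "" if abs(value - default) < 1e-12 else f" {value:g}"


def one_three_pairs(entry: FragmentEntry,
                    bonds: list[Bond]) -> list[tuple[str, str, float]]:
    """Unique 1,3 pairs: endpoints of two bonds sharing an atom, the
    endpoints themselves not bonded.  Deterministic entry-order sorting."""
    g = _graph(entry, bonds)
    order = {a.name: i for i, a in enumerate(entry.atoms)}
    coords = {a.name: a.coords for a in entry.atoms}
    seen: set[tuple[str, str]] = set()
    out = []
    for mid in g.nodes:
        for a, b in combinations(sorted(g.neighbors(mid), key=order.get), 2):
            if g.has_edge(a, b):
                continue
            key = (a, b) if order[a] < order[b] else (b, a)
            if key in seen:
                continue
            seen.add(key)
            out.append((*key, distance(coords[key[0]], coords[key[1]],
                                       entry.cell)))
    out.sort(key=lambda t: (order[t[0]], order[t[1]]))
    return out


def make_distance_restraints(entry: FragmentEntry,
                             su_12: float = DEFAULT_SU_12,
                             su_13: float = DEFAULT_SU_13,
                             include_13: bool = True,
                             bonds: list[Bond] | None = None) -> list[str]:
    """DFIX records for every bond, plus DANG records for 1,3 pairs."""
    if bonds is None:
        bonds = infer_connectivity(entry)
    records = [f"DFIX {_fmt(b.length)}{_su(su_12, 0.02)} {b.atom1} {b.atom2}"
               for b in bonds]
    if include_13:
        for a, b, d in one_three_pairs(entry, bonds):
            records.append(f"DANG {_fmt(d)}{_su(su_13, 0.04)} {a} {b}")
    return records


def _color(g: nx.Graph, node: str) -> tuple:
    neigh = tuple(sorted(g.nodes[n]["element"] for n in g.neighbors(node)))
    return (g.nodes[node]["element"], neigh)


def group_equivalent(bonds: list[Bond], entry: FragmentEntry,
                     su: float = DEFAULT_SU_12) -> list[str]:
    """SADI records over chemically equivalent bonds (radius-1 colouring).

    Bonds whose endpoint colours match form one SADI group; a group of one is
    emitted as DFIX instead, since similarity needs at least two distances.
    """
    g = _graph(entry, bonds)
    groups: dict[tuple, list[Bond]] = {}
    group_order: list[tuple] = []
    for b in bonds:
        key = tuple(sorted((_color(g, b.atom1), _color(g, b.atom2))))
        if key not in groups:
            groups[key] = []
            group_order.append(key)
        groups[key].append(b)
    records = []
    for key in group_order:
        members = groups[key]
        if len(members) == 1:
            b = members[0]
            records.append(f"DFIX {_fmt(b.length)}{_su(su, 0.02)} "
                           f"{b.atom1} {b.atom2}")
        else:
            pairs = " ".join(f"{b.atom1} {b.atom2}" for b in members)
            records.append(f"SADI {su:g} {pairs}")
    return records


def calculated_restraints(entry: FragmentEntry,
                          su_12: float = DEFAULT_SU_12,
                          su_13: float = DEFAULT_SU_13,
                          include_13: bool = True) -> list[str]:
    """The full calculated replacement for a database restraint block."""
    bonds = infer_connectivity(entry)
    return make_distance_restraints(entry, su_12=su_12, su_13=su_13,
                                    include_13=include_13, bonds=bonds)
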