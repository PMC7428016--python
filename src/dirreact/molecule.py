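"""Molecular geometry, bond perception, and terminal reactive sites.

A molecule is an ordered list of atoms with Cartesian coordinates in
Ångström; atom indices are stable 0-based positions.  Bonds are perceived
with the covalent-radius-sum heuristic, and "terminal sites" — a carbon
together with one exocyclic substituent (H or the first atom of a
functional group) and the unit vector along that bond — are the geometric
inputs of the directional-reactivity score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from rdkit import Chem

__all__ = [
    "Atom",
    "Molecule",
    "BondGraph",
    "TerminalSite",
    "covalent_radius",
    "perceive_bonds",
    "ring_carbon_indices",
    "find_terminal_sites",
    "bond_unit_vector",
]

_PT = Chem.GetPeriodicTable()

#: atoms closer than this (Å) are treated as erroneous overlapping input
MIN_ATOM_SEPARATION = 0.5


def covalent_radius(element: str) -> float:
    """Covalent radius in Å for a chemical symbol.

    Raises ``ValueError`` for symbols without a tabulated radius.
    """
    try:
        z = _PT.GetAtomicNumber(element)
    except Exception:
        z = 0
    if z <= 0:
        raise ValueError(f"unknown element symbol: {element!r}")
    r = _PT.GetRcovalent(z)
    if r <= 0:
        raise ValueError(f"no covalent radius tabulated for element {element!r}")
    return float(r)


@dataclass(frozen=True)
class Atom:
    """One atom: chemical symbol plus Cartesian position (Å)."""

    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ValueError("atom coordinates must be finite")
        covalent_radius(self.element)  # validates the symbol
        object.__setattr__(self, "position", pos)


@dataclass
class Molecule:
    """An ordered collection of atoms; indices are stable 0-based positions."""

    name: str
    atoms: list[Atom]
    formal_charge: int = 0

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("a molecule needs at least one atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) coordinate array in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def atomic_numbers(self) -> np.ndarray:
        return np.array([_PT.GetAtomicNumber(a.element) for a in self.atoms])


@dataclass(frozen=True)
class BondGraph:
    """Undirected molecular graph: edges are unordered 0-based index pairs."""

    edges: frozenset[tuple[int, int]]
    n_atoms: int

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on atom {i}")
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ValueError(f"edge ({i}, {j}) outside atom range")
            if i > j:
                raise ValueError("edges must be stored as (low, high) pairs")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]], n_atoms: int) -> "BondGraph":
        return cls(frozenset((min(i, j), max(i, j)) for i, j in pairs), n_atoms)

    def neighbors(self, i: int) -> list[int]:
        out = [j if a == i else a for a, j in self.edges if i in (a, j)]
        return sorted(out)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.edges)
        return g

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class TerminalSite:
    """A heavy atom, its exocyclic substituent, and the bond unit vector.

    ``direction`` points from the heavy atom toward the substituent and has
    unit norm; it is the n̂ entering the directional-reactivity sum.
    """

    heavy_index: int
    substituent_index: int
    direction: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3,):
            raise ValueError("direction must be a 3-vector")
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("terminal-site direction must be a unit vector")
        object.__setattr__(self, "direction", d)


def perceive_bonds(mol: Molecule, scale: float = 1.2) -> BondGraph:
    """Perceive bonds by the covalent-radius-sum distance heuristic.

    Atoms *i*, *j* are bonded iff ``d(i, j) <= scale * (r_cov(i) + r_cov(j))``.
    ``scale`` defaults to 1.2, the standard slack factor for idealized
    geometries; values in (1.0, 1.5] are accepted.
    """
    if not (1.0 < scale <= 1.5):
        raise ValueError("scale must lie in (1.0, 1.5]")
    radii = np.array([covalent_radius(el) for el in mol.elements])
    pos = mol.positions
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    n = mol.n_atoms
    iu, ju = np.triu_indices(n, k=1)
    too_close = dist[iu, ju] < MIN_ATOM_SEPARATION
    if np.any(too_close):
        k = int(np.argmax(too_close))
        raise ValueError(
            f"atoms {iu[k]} and {ju[k]} are {dist[iu[k], ju[k]]:.3f} Å apart "
            "(< 0.5 Å): overlapping input geometry"
        )
    cutoff = scale * (radii[:, None] + radii[None, :])
    bonded = dist <= cutoff
    pairs = [(int(i), int(j)) for i, j in zip(iu, ju) if bonded[i, j]]
    return BondGraph.from_pairs(pairs, n)


def ring_carbon_indices(mol: Molecule, bonds: BondGraph) -> set[int]:
    """Indices of atoms that belong to any cycle of the bond graph."""
    g = bonds.to_networkx()
    ring: set[int] = set()
    for cyc in nx.cycle_basis(g):
        ring.update(cyc)
    return ring


def bond_unit_vector(mol: Molecule, i: int, j: int) -> np.ndarray:
    """Unit vector from atom *i* toward atom *j*."""
    if i == j:
        raise ValueError("atom indices must differ")
    v = mol.atoms[j].position - mol.atoms[i].position
    norm = float(np.linalg.norm(v))
    if norm == 0.0:
        raise ValueError(f"atoms {i} and {j} have coincident positions")
    return v / norm


# substituent first atoms that qualify a neighbor as exocyclic
_HETERO_SUBSTITUENTS = {"H", "O", "N"}


def find_terminal_sites(mol: Molecule, bonds: BondGraph) -> list[TerminalSite]:
    """Enumerate terminal reactive sites: carbon → exocyclic substituent bonds.

    For every carbon with at least one neighbor that is not a ring carbon —
    i.e. the neighbor is H, O, N, or an acyclic carbon such as a methyl
    carbon — one site is emitted per such neighbor.  For multi-atom groups
    the direction uses the first atom of the group (C→C for methyl, C→O for
    hydroxyl).  Sites are ordered by (heavy_index, substituent_index).
    """
    if mol.n_atoms == 0:
        raise ValueError("empty molecule")
    in_ring = ring_carbon_indices(mol, bonds)
    sites: list[TerminalSite] = []
    for i, atom in enumerate(mol.atoms):
        if atom.element != "C":
            continue
        for j in bonds.neighbors(i):
            nel = mol.atoms[j].element
            exocyclic = nel in _HETERO_SUBSTITUENTS or (nel == "C" and j not in in_ring)
            if not exocyclic:
                continue
            sites.append(TerminalSite(i, j, bond_unit_vector(mol, i, j)))
    sites.sort(key=lambda s: (s.heavy_index, s.substituent_index))
    return sites
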