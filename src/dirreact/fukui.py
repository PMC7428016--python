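"""Conceptual-DFT reactivity descriptors from charge populations.

Condensed Fukui functions are finite-difference reactivity indicators built
from partial atomic charges of the N-, (N+1)- and (N−1)-electron states of
the same geometry:

    f⁺_k = q_k(neutral) − q_k(anion)      (nucleophilic-attack sites)
    f⁻_k = q_k(cation)  − q_k(neutral)    (electrophilic-attack sites)
    f⁰_k = (f⁺_k + f⁻_k) / 2

Each full atom-resolved vector sums to 1 (one electron added or removed).
Charges are supplied externally (population analyses such as Hirshfeld from
a quantum-chemistry run, or synthetic fixtures); no electronic-structure
computation happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .molecule import BondGraph, Molecule

__all__ = [
    "ChargeSet",
    "FukuiVector",
    "DipoleVector",
    "OrbitalEnergies",
    "DEBYE_PER_E_ANGSTROM",
    "condensed_fukui",
    "hydrogen_condense",
    "dipole_from_point_charges",
    "largest_fukui_sites",
]

logger = logging.getLogger(__name__)

#: conversion constant, Debye per (elementary charge × Å)
DEBYE_PER_E_ANGSTROM = 4.80320

_STATE_TOTAL_CHARGE = {"neutral": 0.0, "anion": -1.0, "cation": 1.0}

#: tolerance on the sum of a charge set against its nominal total charge
CHARGE_SUM_TOL = 1e-3


@dataclass(frozen=True)
class ChargeSet:
    """Per-atom partial charges (e) at a labeled electron-count state."""

    state_label: str
    charges: np.ndarray
    charge_model: str = "unspecified"

    def __post_init__(self) -> None:
        if self.state_label not in _STATE_TOTAL_CHARGE:
            raise ValueError(
                f"state_label must be one of {sorted(_STATE_TOTAL_CHARGE)}, "
                f"got {self.state_label!r}"
            )
        q = np.asarray(self.charges, dtype=float)
        if q.ndim != 1 or q.size == 0:
            raise ValueError("charges must be a non-empty 1-D array")
        total = _STATE_TOTAL_CHARGE[self.state_label]
        if abs(float(q.sum()) - total) > CHARGE_SUM_TOL:
            raise ValueError(
                f"{self.state_label} charges sum to {q.sum():+.5f}, "
                f"expected {total:+.0f} within {CHARGE_SUM_TOL}"
            )
        object.__setattr__(self, "charges", q)

    def __len__(self) -> int:
        return int(self.charges.size)


@dataclass(frozen=True)
class FukuiVector:
    """Per-atom (or per-heavy-atom, once condensed) reactivity weights."""

    mode: str
    values: np.ndarray
    condensed: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("f_plus", "f_minus", "f_zero"):
            raise ValueError(f"unknown Fukui mode {self.mode!r}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class DipoleVector:
    """Molecular dipole moment, Debye."""

    vector: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if v.shape != (3,):
            raise ValueError("dipole vector must be a 3-vector")
        if not np.all(np.isfinite(v)):
            raise ValueError("dipole vector must be finite")
        object.__setattr__(self, "vector", v)

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.vector))

    def unit(self) -> np.ndarray:
        m = self.magnitude
        if m == 0.0:
            raise ValueError("zero dipole has no direction")
        return self.vector / m


@dataclass(frozen=True)
class OrbitalEnergies:
    """HOMO/LUMO energies and their gap, eV."""

    homo: float
    lumo: float

    @property
    def gap(self) -> float:
        return self.lumo - self.homo

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise ValueError("LUMO below HOMO: gap must be non-negative")


def _check_alignment(*sets: ChargeSet) -> int:
    lengths = {len(cs) for cs in sets}
    if len(lengths) != 1:
        raise ValueError(f"charge sets have mismatched lengths: {sorted(lengths)}")
    return lengths.pop()


def condensed_fukui(
    neutral: ChargeSet,
    anion: ChargeSet,
    cation: ChargeSet,
    mode: str = "f_plus",
) -> FukuiVector:
    """Finite-difference condensed Fukui vector from a charge-state triple.

    All three sets must be aligned to the same atom ordering and carry the
    matching state labels.  Negative per-atom values (orbital-relaxation
    artifacts) are legal and propagate as-is with a logged warning.
    """
    for cs, want in ((neutral, "neutral"), (anion, "anion"), (cation, "cation")):
        if cs.state_label != want:
            raise ValueError(
                f"argument expected the {want!r} state, got {cs.state_label!r}"
            )
    _check_alignment(neutral, anion, cation)
    f_plus = neutral.charges - anion.charges
    f_minus = cation.charges - neutral.charges
    if mode == "f_plus":
        values = f_plus
    elif mode == "f_minus":
        values = f_minus
    elif mode == "f_zero":
        values = 0.5 * (f_plus + f_minus)
    else:
        raise ValueError(f"unknown Fukui mode {mode!r}")
    if np.any(values < 0):
        logger.warning(
            "negative condensed Fukui values present (min %.4f); "
            "propagating as-is",
            float(values.min()),
        )
    return FukuiVector(mode=mode, values=values, condensed=False)


def hydrogen_condense(
    fv: FukuiVector, mol: Molecule, bonds: BondGraph
) -> FukuiVector:
    """Fold each hydrogen's Fukui weight into its unique bonded heavy atom.

    Returns a vector indexed by the heavy atoms in their original relative
    order; the total sum is preserved exactly (summation order fixed by atom
    index).
    """
    if fv.condensed:
        raise ValueError("vector is already hydrogen-condensed")
    if len(fv) != mol.n_atoms:
        raise ValueError("Fukui vector length does not match molecule")
    heavy = [i for i, a in enumerate(mol.atoms) if a.element != "H"]
    pos_of = {idx: k for k, idx in enumerate(heavy)}
    out = np.zeros(len(heavy))
    for k, idx in enumerate(heavy):
        out[k] = fv.values[idx]
    for i, atom in enumerate(mol.atoms):
        if atom.element != "H":
            continue
        heavy_nb = [j for j in bonds.neighbors(i) if mol.atoms[j].element != "H"]
        if len(heavy_nb) != 1:
            raise ValueError(
                f"hydrogen {i} has {len(heavy_nb)} heavy neighbors; "
                "cannot condense"
            )
        out[pos_of[heavy_nb[0]]] += fv.values[i]
    return FukuiVector(mode=fv.mode, values=out, condensed=True)


def dipole_from_point_charges(
    mol: Molecule,
    cs: ChargeSet,
    origin: np.ndarray | None = None,
) -> DipoleVector:
    """Dipole moment of a point-charge distribution, in Debye.

    ``D = k · Σ_i q_i (r_i − origin)`` with k = 4.80320 D/(e·Å).  The origin
    defaults to the center of nuclear charge; for net-charged distributions
    the dipole is origin-dependent, so an explicit origin is then required.
    """
    if len(cs) != mol.n_atoms:
        raise ValueError("charge set length does not match molecule")
    q = cs.charges
    if origin is None:
        if abs(float(q.sum())) > 1e-3:
            raise ValueError(
                "net-charged distribution: dipole is origin-dependent, "
                "supply an explicit origin"
            )
        z = mol.atomic_numbers().astype(float)
        origin = (z[:, None] * mol.positions).sum(axis=0) / z.sum()
    origin = np.asarray(origin, dtype=float)
    vec = DEBYE_PER_E_ANGSTROM * (q[:, None] * (mol.positions - origin)).sum(axis=0)
    return DipoleVector(vector=vec)


def largest_fukui_sites(fv: FukuiVector, tol: float = 1e-3) -> list[int]:
    """Indices of the maximal Fukui sites, ties within ``tol`` reported.

    Expects a hydrogen-condensed vector; returns every index whose value is
    within ``tol`` of the maximum, in ascending index order.
    """
    if len(fv) == 0:
        raise ValueError("empty Fukui vector")
    v = fv.values
    vmax = float(v.max())
    return [int(i) for i in np.flatnonzero(v >= vmax - tol)]
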