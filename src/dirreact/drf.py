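"""Directional reactivity factor (DRF): dipole-aligned reactivity scoring.

The score couples the receptor's net charge to the ligand's reactive-site
geometry:

    DRF = C_LR · Q_net · Σ_n  F_n  |D| cos φ_n

where the sum runs over terminal sites (carbon→substituent bonds), F_n is
the condensed Fukui weight of the site's carbon, D is the molecular dipole
and φ_n the angle between the dipole and the site's bond direction.  Sites
pointing along the dipole ("forward", the face presented to the receptor)
add to the score; sites behind the molecule (cos φ < 0) subtract.  C_LR
absorbs the Coulomb prefactor 1/(4π ε₀ ε_R r) and is constant for one
receptor at a fixed approach distance, so scores are reported in model
units (Fukui × Debye × e) and are meaningful relative to one another.

The choice of F⁺ versus F⁻ follows the receptor's charge state: cytosolic
ions screen the charged residues, so the ligand effectively faces a
potential of sign −sign(Q_net); a positively charged receptor is approached
by the ligand's electron-accepting (F⁺) sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fukui import (
    ChargeSet,
    DipoleVector,
    FukuiVector,
    condensed_fukui,
    hydrogen_condense,
)
from .molecule import Molecule, TerminalSite, find_terminal_sites, perceive_bonds

__all__ = [
    "DRFParameters",
    "SiteContribution",
    "DRFResult",
    "select_fukui_mode",
    "site_contributions",
    "compute_drf",
    "classify_orientation",
    "rank_by_drf",
    "score_molecule",
]

#: default perpendicular-band half-width: cos 75°
DEFAULT_TAU = math.cos(math.radians(75.0))


@dataclass(frozen=True)
class DRFParameters:
    """Scoring knobs; ``epsilon_r`` and ``r`` are carried as metadata only."""

    c_lr: float = 1.0
    tau: float = DEFAULT_TAU
    epsilon_r: float | None = None
    r: float | None = None
    fukui_mode_override: str | None = None

    def __post_init__(self) -> None:
        if not self.c_lr > 0:
            raise ValueError("c_lr must be positive")
        if not (0.0 <= self.tau < 1.0):
            raise ValueError("tau must lie in [0, 1)")


@dataclass(frozen=True)
class SiteContribution:
    """One terminal site's term in the DRF sum: fukui × |D| × cos φ."""

    site: TerminalSite
    fukui: float
    cos_phi: float
    term: float


@dataclass(frozen=True)
class DRFResult:
    compound: str
    drf: float
    contributions: tuple[SiteContribution, ...]
    fukui_mode: str
    q_net: float
    orientation_class: str
    max_fukui_atoms: tuple[int, ...]


def select_fukui_mode(q_net: float, override: str | None = None) -> str:
    """Pick F⁺ or F⁻ from the receptor charge state (ion-screening flip).

    The screened potential seen by the ligand has sign −sign(q_net):
    positive receptor → the ligand leads with nucleophilic-attack (F⁺)
    sites; negative receptor → F⁻.  ``override`` wins when supplied.
    """
    if override is not None:
        if override not in ("f_plus", "f_minus"):
            raise ValueError(f"invalid Fukui mode override {override!r}")
        return override
    if not np.isfinite(q_net):
        raise ValueError("q_net must be finite")
    if q_net == 0.0:
        raise ValueError(
            "receptor net charge is zero: Fukui mode is undefined, supply "
            "an override"
        )
    return "f_plus" if q_net > 0 else "f_minus"


def site_contributions(
    sites: Sequence[TerminalSite],
    fukui: FukuiVector,
    dipole: DipoleVector,
    heavy_index_map: dict[int, int] | None = None,
) -> list[SiteContribution]:
    """Per-site terms fukui × |D| × cos φ against the dipole direction.

    ``fukui`` may be atom-resolved (indexed by atom index) or
    hydrogen-condensed, in which case ``heavy_index_map`` must translate
    atom indices of site carbons to positions in the condensed vector.
    A zero dipole degenerates every cos φ (and term) to 0.
    """
    mag = dipole.magnitude
    d_hat = dipole.unit() if mag > 0.0 else None
    out: list[SiteContribution] = []
    for site in sites:
        k = site.heavy_index
        if heavy_index_map is not None:
            if k not in heavy_index_map:
                raise KeyError(f"site atom {k} missing from Fukui index map")
            k = heavy_index_map[k]
        if not (0 <= k < len(fukui)):
            raise IndexError(f"site atom {site.heavy_index} missing from Fukui vector")
        f = float(fukui.values[k])
        cos_phi = float(site.direction @ d_hat) if d_hat is not None else 0.0
        out.append(
            SiteContribution(site=site, fukui=f, cos_phi=cos_phi, term=f * mag * cos_phi)
        )
    return out


def classify_orientation(
    max_fukui_sites: Sequence[int],
    contribs: Sequence[SiteContribution],
    tau: float = DEFAULT_TAU,
) -> str:
    """Forward/perpendicular/backward class of the most-reactive carbon(s).

    Uses the mean cos φ over every site whose carbon is among the maximal
    Fukui atoms: F if mean > +tau, B if mean < −tau, else P.  A zero dipole
    (all cos φ = 0) is P by construction.
    """
    if len(max_fukui_sites) == 0:
        raise ValueError("need at least one maximal-Fukui site")
    chosen = [c for c in contribs if c.site.heavy_index in set(max_fukui_sites)]
    if not chosen:
        raise ValueError("no contribution matches the maximal-Fukui atoms")
    mean_cos = float(np.mean([c.cos_phi for c in chosen]))
    if mean_cos > tau:
        return "F"
    if mean_cos < -tau:
        return "B"
    return "P"


def compute_drf(
    contribs: Sequence[SiteContribution],
    q_net: float,
    params: DRFParameters = DRFParameters(),
    compound: str = "",
    fukui_mode: str = "f_plus",
    max_fukui_atoms: Sequence[int] | None = None,
) -> DRFResult:
    """Assemble the DRF score from per-site contributions.

    ``drf = c_lr × q_net × Σ terms``; negative (behind-the-molecule) terms
    reduce the score as the model prescribes.  When ``max_fukui_atoms`` is
    given the orientation class of those sites is attached, otherwise the
    sites of the largest Fukui weight among the contributions are used.
    """
    if len(contribs) == 0:
        raise ValueError("no site contributions")
    terms = np.array([c.term for c in contribs], dtype=float)
    if not np.all(np.isfinite(terms)) or not np.isfinite(q_net):
        raise ValueError("non-finite input to DRF")
    drf = params.c_lr * q_net * float(terms.sum())
    if max_fukui_atoms is None:
        fmax = max(c.fukui for c in contribs)
        max_fukui_atoms = sorted(
            {c.site.heavy_index for c in contribs if c.fukui >= fmax - 1e-3}
        )
    cls = classify_orientation(max_fukui_atoms, contribs, params.tau)
    return DRFResult(
        compound=compound,
        drf=drf,
        contributions=tuple(contribs),
        fukui_mode=fukui_mode,
        q_net=q_net,
        orientation_class=cls,
        max_fukui_atoms=tuple(int(i) for i in max_fukui_atoms),
    )


def score_molecule(
    mol: Molecule,
    neutral: ChargeSet,
    anion: ChargeSet,
    cation: ChargeSet,
    dipole: DipoleVector,
    q_net: float,
    params: DRFParameters = DRFParameters(),
    condense_hydrogens: bool = True,
) -> DRFResult:
    """End-to-end DRF score of one ligand from its raw inputs.

    Perceives bonds and terminal sites, selects F⁺/F⁻ from the receptor
    charge, builds the condensed Fukui vector (hydrogen weights folded into
    their heavy atoms by default), and assembles the score.
    """
    bonds = perceive_bonds(mol)
    sites = find_terminal_sites(mol, bonds)
    if not sites:
        raise ValueError(f"{mol.name!r} has no terminal reactive sites")
    mode = select_fukui_mode(q_net, params.fukui_mode_override)
    fv = condensed_fukui(neutral, anion, cation, mode=mode)
    heavy_map = None
    if condense_hydrogens:
        fv = hydrogen_condense(fv, mol, bonds)
        heavy = [i for i, a in enumerate(mol.atoms) if a.element != "H"]
        heavy_map = {idx: k for k, idx in enumerate(heavy)}
    contribs = site_contributions(sites, fv, dipole, heavy_index_map=heavy_map)
    return compute_drf(
        contribs, q_net, params, compound=mol.name, fukui_mode=mode
    )


def rank_by_drf(results: Sequence[DRFResult]) -> list[DRFResult]:
    """Results in descending DRF order; ties broken by compound name."""
    if len(results) == 0:
        raise ValueError("nothing to rank")
    names = [r.compound for r in results]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate compound names: {dupes}")
    return sorted(results, key=lambda r: (-r.drf, r.compound))
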