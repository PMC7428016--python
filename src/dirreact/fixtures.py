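"""Deterministic synthetic fixtures emulating the model's input classes.

Real inputs to the directional-reactivity workflow are DFT outputs
(geometries, Hirshfeld charge populations of the neutral/anion/cation
states, dipole vectors) and reporter-assay dose–response tables.  This
module generates stand-ins with *planted* ground truth so every downstream
operation can be tested against known answers:

* idealized planar fused-hexagon scaffolds (benzene → chrysene-like and
  beyond) with optional methyl / hydroxyl substituents;
* charge-state triples solved so that the condensed Fukui functions and the
  point-charge dipole recover planted values exactly (a minimum-norm linear
  solve, independent of the code under test);
* noisy sigmoidal dose–response curves over a fivefold dilution series with
  a planted EC50;
* a deliberately naive brute-force re-derivation of the DRF score (explicit
  loops, own cycle detection, no shared helpers) used as the oracle in
  equivalence tests.

Everything is a pure function of a :class:`FixtureSpec`, so a seed fixes
all randomness bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .bioassay import DoseResponseCurve
from .fukui import DEBYE_PER_E_ANGSTROM, ChargeSet, DipoleVector
from .molecule import Atom, Molecule

__all__ = [
    "FixtureSpec",
    "make_ring_molecule",
    "make_chrysene_like",
    "plant_charge_states",
    "random_fixture",
    "simulate_dose_response",
    "drf_bruteforce_oracle",
]

# idealized bond lengths, Å
CC_RING = 1.40
CH = 1.09
CO = 1.36
OH = 0.96
C_METHYL = 1.50

_RING_CENTER_STEP = CC_RING * math.sqrt(3.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Full recipe for one synthetic fixture; the seed fixes all randomness.

    ``ring_path`` lists lattice step directions (integers 0–5, 60° each)
    between consecutive fused-ring centers; the default zigzag produces
    angular (chrysene-like) fusion.  ``substituents`` maps peripheral C–H
    position index (in site order) to "methyl" or "hydroxyl".
    """

    seed: int = 0
    n_rings: int = 1
    ring_path: tuple[int, ...] | None = None
    substituents: dict[int, str] = field(default_factory=dict)
    planted_dipole: tuple[float, float, float] = (0.0, 0.0, 0.0)
    planted_fukui: tuple[float, ...] | None = None
    planted_fukui_minus: tuple[float, ...] | None = None
    planted_ec50: float = 5.0
    hill: float = 1.2
    top: float = 100.0
    bottom: float = 0.0
    top_dose_um: float = 100.0
    n_replicates: int = 3
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rings < 1:
            raise ValueError("need at least one ring")
        if self.planted_fukui is not None:
            s = sum(self.planted_fukui)
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"planted Fukui weights sum to {s}, not 1")
        if self.planted_ec50 <= 0:
            raise ValueError("planted EC50 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


def _default_path(n_rings: int) -> tuple[int, ...]:
    # zigzag 0, 1, 0, 1, ... : angular fusion as in chrysene
    return tuple(k % 2 for k in range(n_rings - 1))


def _hexagon(center: np.ndarray) -> list[np.ndarray]:
    verts = []
    for j in range(6):
        ang = math.radians(30.0 + 60.0 * j)
        verts.append(center + CC_RING * np.array([math.cos(ang), math.sin(ang)]))
    return verts


def _ring_centers(n_rings: int, path: tuple[int, ...]) -> list[np.ndarray]:
    if len(path) != n_rings - 1:
        raise ValueError("ring_path length must be n_rings - 1")
    centers = [np.zeros(2)]
    for step in path:
        if not 0 <= step <= 5:
            raise ValueError("ring_path steps must be integers 0..5")
        ang = math.radians(60.0 * step)
        nxt = centers[-1] + _RING_CENTER_STEP * np.array(
            [math.cos(ang), math.sin(ang)]
        )
        for c in centers:
            if np.linalg.norm(nxt - c) < 1e-6:
                raise ValueError("ring path revisits an existing ring center")
        centers.append(nxt)
    return centers


def make_ring_molecule(spec: FixtureSpec) -> Molecule:
    """Idealized planar fused-hexagon molecule from a fixture recipe.

    Ring carbons are laid on a hexagonal lattice (C–C 1.40 Å) and
    deduplicated at fused edges; every carbon with fewer than three ring
    neighbors gets one radially outward substituent: H by default, or a
    methyl/hydroxyl group per ``spec.substituents`` (keyed by peripheral
    position index).  Ring carbons come first in the atom order, then the
    substituent atoms in peripheral order; the scaffold lies in z = 0.
    """
    path = spec.ring_path if spec.ring_path is not None else _default_path(spec.n_rings)
    centers = _ring_centers(spec.n_rings, path)

    carbons: list[np.ndarray] = []
    for c in centers:
        for v in _hexagon(c):
            if not any(np.linalg.norm(v - u) < 1e-6 for u in carbons):
                carbons.append(v)

    # peripheral carbons: fewer than 3 ring-C neighbors at the lattice distance
    n_c = len(carbons)
    nb_count = [0] * n_c
    for i in range(n_c):
        for j in range(i + 1, n_c):
            if abs(np.linalg.norm(carbons[i] - carbons[j]) - CC_RING) < 1e-6:
                nb_count[i] += 1
                nb_count[j] += 1
    peripheral = [i for i in range(n_c) if nb_count[i] < 3]

    atoms = [Atom("C", np.array([p[0], p[1], 0.0])) for p in carbons]
    for pos_idx, ci in enumerate(peripheral):
        # outward direction: away from the mean of the ring neighbors
        nbs = [
            carbons[j]
            for j in range(n_c)
            if j != ci and abs(np.linalg.norm(carbons[ci] - carbons[j]) - CC_RING) < 1e-6
        ]
        u2 = carbons[ci] - np.mean(nbs, axis=0)
        u2 = u2 / np.linalg.norm(u2)
        u = np.array([u2[0], u2[1], 0.0])
        p1 = np.array([-u2[1], u2[0], 0.0])  # in-plane perpendicular
        base = np.array([carbons[ci][0], carbons[ci][1], 0.0])

        kind = spec.substituents.get(pos_idx, "H")
        if kind == "H":
            atoms.append(Atom("H", base + CH * u))
        elif kind == "methyl":
            cm = base + C_METHYL * u
            atoms.append(Atom("C", cm))
            # tetrahedral-ish H fan: ~109.5° from the C(ring)–C(methyl) axis
            along, perp = math.cos(math.radians(70.5)), math.sin(math.radians(70.5))
            ez = np.array([0.0, 0.0, 1.0])
            for k in range(3):
                th = math.radians(90.0 + 120.0 * k)
                d = along * u + perp * (math.cos(th) * p1 + math.sin(th) * ez)
                atoms.append(Atom("H", cm + CH * d))
        elif kind == "hydroxyl":
            om = base + CO * u
            atoms.append(Atom("O", om))
            # C–O–H angle ~104.5°, H kept in the molecular plane
            a = math.radians(75.5)
            d = math.cos(a) * u + math.sin(a) * p1
            atoms.append(Atom("H", om + OH * d))
        else:
            raise ValueError(f"unknown substituent kind {kind!r}")
    if spec.substituents and max(spec.substituents) >= len(peripheral):
        raise ValueError(
            f"substituent position out of range: molecule has "
            f"{len(peripheral)} peripheral positions"
        )

    name = f"ring{spec.n_rings}-seed{spec.seed}"
    return Molecule(name=name, atoms=atoms)


def make_chrysene_like(substituents: dict[int, str] | None = None) -> Molecule:
    """Four angularly fused rings (C18H12 when unsubstituted)."""
    spec = FixtureSpec(n_rings=4, substituents=substituents or {})
    return make_ring_molecule(spec)


def plant_charge_states(
    mol: Molecule, spec: FixtureSpec
) -> tuple[ChargeSet, ChargeSet, ChargeSet]:
    """Charge-state triple whose Fukui functions and dipole are known.

    Neutral charges solve the minimum-norm problem subject to Σq = 0 and
    the point-charge dipole equaling ``spec.planted_dipole`` about the
    center of nuclear charge; the anion subtracts the planted f⁺
    distribution and the cation adds the planted f⁻ distribution (both
    defined on heavy atoms, zero on hydrogens), so finite-difference Fukui
    vectors recover the plants exactly.  Raises if the requested dipole is
    geometrically infeasible (e.g. an out-of-plane component on a strictly
    planar molecule).
    """
    heavy = [i for i, a in enumerate(mol.atoms) if a.element != "H"]
    if spec.planted_fukui is None:
        f_plus_h = np.full(len(heavy), 1.0 / len(heavy))
    else:
        if len(spec.planted_fukui) != len(heavy):
            raise ValueError(
                f"planted Fukui length {len(spec.planted_fukui)} != "
                f"{len(heavy)} heavy atoms"
            )
        f_plus_h = np.asarray(spec.planted_fukui, dtype=float)
    if spec.planted_fukui_minus is None:
        f_minus_h = f_plus_h
    else:
        f_minus_h = np.asarray(spec.planted_fukui_minus, dtype=float)
        if abs(f_minus_h.sum() - 1.0) > 1e-9:
            raise ValueError("planted f⁻ weights must sum to 1")

    n = mol.n_atoms
    f_plus = np.zeros(n)
    f_plus[heavy] = f_plus_h
    f_minus = np.zeros(n)
    f_minus[heavy] = f_minus_h

    z = mol.atomic_numbers().astype(float)
    origin = (z[:, None] * mol.positions).sum(axis=0) / z.sum()
    rel = mol.positions - origin  # (n, 3)

    # constraints: [1ᵀ; k·relᵀ] q = [0; D]
    a = np.vstack([np.ones(n), DEBYE_PER_E_ANGSTROM * rel.T])
    b = np.concatenate([[0.0], np.asarray(spec.planted_dipole, dtype=float)])
    q, *_ = np.linalg.lstsq(a, b, rcond=None)
    if np.linalg.norm(a @ q - b) > 1e-8:
        raise ValueError(
            "planted dipole is infeasible for this geometry (rank-deficient "
            "constraint system; e.g. out-of-plane dipole on a planar molecule)"
        )

    neutral = ChargeSet("neutral", q, charge_model="synthetic-planted")
    anion = ChargeSet("anion", q - f_plus, charge_model="synthetic-planted")
    cation = ChargeSet("cation", q + f_minus, charge_model="synthetic-planted")
    return neutral, anion, cation


def _chemically_sane(mol: Molecule) -> bool:
    """True when bond perception yields monovalent hydrogens everywhere.

    Idealized substituent placement can crowd bay regions; a fixture whose
    hydrogens pick up spurious extra bonds does not emulate a real
    geometry and is rejected.
    """
    from .molecule import perceive_bonds

    try:
        bonds = perceive_bonds(mol)  # also rejects < 0.5 Å clashes
    except ValueError:
        return False
    for i, atom in enumerate(mol.atoms):
        if atom.element == "H" and len(bonds.neighbors(i)) != 1:
            return False
    return True


def random_fixture(seed: int, max_rings: int = 6) -> FixtureSpec:
    """Seeded random fixture: ring count, path, substituents, plants.

    The planted dipole is sampled in the molecular plane unless the drawn
    substituents include a methyl group (whose hydrogens leave the plane),
    keeping the charge-planting problem feasible.
    """
    rng = np.random.default_rng(seed)
    n_rings = int(rng.integers(1, max_rings + 1))
    # rejection-sample a non-self-intersecting ring path
    for _ in range(200):
        path = tuple(int(s) for s in rng.integers(0, 6, size=n_rings - 1))
        try:
            _ring_centers(n_rings, path)
        except ValueError:
            continue
        probe = FixtureSpec(seed=seed, n_rings=n_rings, ring_path=path)
        try:
            mol = make_ring_molecule(probe)
        except ValueError:
            continue
        if _chemically_sane(mol):
            break
    else:  # pragma: no cover - rejection loop essentially always succeeds
        raise RuntimeError("could not draw a valid ring path")

    n_peripheral = sum(1 for a in mol.atoms if a.element == "H")
    subs: dict[int, str] = {}
    has_methyl = False
    for pos in range(n_peripheral):
        u = rng.random()
        if u < 0.10:
            subs[pos] = "methyl"
            has_methyl = True
        elif u < 0.20:
            subs[pos] = "hydroxyl"

    spec = FixtureSpec(seed=seed, n_rings=n_rings, ring_path=path,
                       substituents=subs)
    try:
        mol = make_ring_molecule(spec)
        sane = _chemically_sane(mol)
    except ValueError:
        sane = False
    if not sane:
        # substituents clashed with a neighboring ring; fall back to bare
        spec = replace(spec, substituents={})
        mol = make_ring_molecule(spec)
        has_methyl = False

    n_heavy = sum(1 for a in mol.atoms if a.element != "H")
    w = rng.random(n_heavy)
    f_plus = tuple(w / w.sum())
    w2 = rng.random(n_heavy)
    f_minus = tuple(w2 / w2.sum())
    d = rng.normal(0.0, 3.0, size=3)
    if not has_methyl:
        d[2] = 0.0  # planar geometry cannot carry an out-of-plane dipole
    return replace(
        spec,
        planted_fukui=f_plus,
        planted_fukui_minus=f_minus,
        planted_dipole=tuple(float(x) for x in d),
        planted_ec50=float(10.0 ** rng.uniform(-1.0, 1.5)),
    )


def simulate_dose_response(spec: FixtureSpec) -> DoseResponseCurve:
    """Noisy logistic dose–response over a fivefold dilution series.

    Ten doses descending fivefold from ``top_dose_um``, ``n_replicates``
    wells per dose; the mean response follows an increasing log-logistic
    with the planted EC50 and Hill slope, and Gaussian noise of the given
    SD (in %BaP_max) is added with the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    doses = spec.top_dose_um * 5.0 ** -np.arange(10)[::-1]
    doses = np.repeat(doses, spec.n_replicates)
    mean = spec.bottom + (spec.top - spec.bottom) / (
        1.0 + (spec.planted_ec50 / doses) ** spec.hill
    )
    resp = mean + rng.normal(0.0, spec.noise_sd, size=doses.shape) \
        if spec.noise_sd > 0 else mean
    return DoseResponseCurve(
        compound=f"synthetic-ec50-{spec.planted_ec50:g}",
        doses=doses,
        responses=resp,
    )


# --- independent brute-force oracle -------------------------------------
# Everything below re-derives the DRF score with explicit loops and its own
# graph walk; it deliberately shares no helpers with molecule.py / drf.py.

_ORACLE_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66}


def _oracle_cycle_atoms(elements, positions, scale=1.2):
    n = len(elements)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(positions[i], positions[j])
            if d <= scale * (_ORACLE_RADII[elements[i]] + _ORACLE_RADII[elements[j]]):
                adj[i].append(j)
                adj[j].append(i)
    # an atom is in a cycle iff it survives iterative leaf pruning
    deg = [len(a) for a in adj]
    alive = [True] * n
    changed = True
    while changed:
        changed = False
        for i in range(n):
            if alive[i] and deg[i] <= 1:
                alive[i] = False
                changed = True
                for j in adj[i]:
                    if alive[j]:
                        deg[j] -= 1
    return adj, [i for i in range(n) if alive[i]]


def drf_bruteforce_oracle(mol, neutral, anion, cation, dipole, q_net,
                          c_lr=1.0, mode=None):
    """Naive independent DRF computation for oracle-equivalence tests.

    Same inputs and conventions as the engine pipeline, re-implemented with
    plain Python loops: finite-difference Fukui per atom, leaf-pruning
    cycle detection, terminal-site enumeration (any carbon with an H/O/N or
    acyclic-carbon neighbor), and the explicit sum q·Σ f |D| cos φ.
    """
    elements = [a.element for a in mol.atoms]
    positions = [tuple(a.position) for a in mol.atoms]
    n = len(elements)

    if mode is None:
        if q_net == 0:
            raise ValueError("q_net must be nonzero without an explicit mode")
        mode = "f_plus" if q_net > 0 else "f_minus"
    f = []
    for k in range(n):
        if mode == "f_plus":
            f.append(neutral.charges[k] - anion.charges[k])
        else:
            f.append(cation.charges[k] - neutral.charges[k])

    adj, cyclic = _oracle_cycle_atoms(elements, positions)
    cyclic_set = set(cyclic)

    dvec = tuple(float(x) for x in dipole.vector)
    dmag = math.sqrt(dvec[0] ** 2 + dvec[1] ** 2 + dvec[2] ** 2)

    total = 0.0
    for i in range(n):
        if elements[i] != "C":
            continue
        for j in adj[i]:
            ej = elements[j]
            if not (ej in ("H", "O", "N") or (ej == "C" and j not in cyclic_set)):
                continue
            bx = positions[j][0] - positions[i][0]
            by = positions[j][1] - positions[i][1]
            bz = positions[j][2] - positions[i][2]
            bn = math.sqrt(bx * bx + by * by + bz * bz)
            if dmag == 0.0:
                cos_phi = 0.0
            else:
                cos_phi = (bx * dvec[0] + by * dvec[1] + bz * dvec[2]) / (bn * dmag)
            total += f[i] * dmag * cos_phi
    return c_lr * q_net * total
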