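"""File formats: XYZ geometries, charge CSVs, FASTA sequences, run config.

Conventions used by every reader and writer: coordinates in Å, dipoles in
Debye, charges in elementary charges, and 0-based atom indices.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO

from .fukui import ChargeSet
from .molecule import Atom, Molecule, covalent_radius

__all__ = [
    "RunConfig",
    "read_xyz",
    "write_xyz",
    "read_charge_csv",
    "write_charge_csv",
    "read_fasta",
    "parse_population_block",
    "read_config",
]

CHARGE_CSV_COLUMNS = ["atom_index", "element", "q_neutral", "q_anion", "q_cation"]


@dataclass
class RunConfig:
    """Validated knobs for a scoring run."""

    pka_table_name: str = "classic"
    ph: float = 7.4
    c_lr: float = 1.0
    tau: float = 0.2588190451024934
    condense_hydrogens: bool = True
    transform: str = "reciprocal"
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not (0.0 < self.ph < 14.0):
            raise ValueError("ph outside (0, 14)")
        if self.c_lr <= 0:
            raise ValueError("c_lr must be positive")
        if not (0.0 <= self.tau < 1.0):
            raise ValueError("tau must lie in [0, 1)")
        if self.transform not in ("identity", "reciprocal", "log10"):
            raise ValueError(f"unknown transform {self.transform!r}")


def _open(source: str | Path | TextIO) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    return open(source, "r")


def read_xyz(source: str | Path | TextIO, name: str | None = None) -> Molecule:
    """Standard XYZ: count line, comment line, then ``element x y z`` rows (Å)."""
    fh = _open(source)
    lines = fh.read().splitlines()
    if len(lines) < 2:
        raise ValueError("XYZ file too short: need count and comment lines")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"line 1: cannot parse atom count from {lines[0]!r}")
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != n:
        raise ValueError(
            f"count line declares {n} atoms but file has {len(body)} atom lines"
        )
    atoms = []
    for k, ln in enumerate(body):
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"line {k + 3}: expected 'element x y z', got {ln!r}")
        el = parts[0]
        try:
            covalent_radius(el)
        except ValueError:
            raise ValueError(f"line {k + 3}: unknown element {el!r}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ValueError(f"line {k + 3}: unparseable coordinate in {ln!r}")
        atoms.append(Atom(el, np.array(xyz)))
    return Molecule(name=name or (lines[1].strip() or "molecule"), atoms=atoms)


def write_xyz(mol: Molecule, dest: str | Path) -> None:
    with open(dest, "w") as fh:
        fh.write(f"{mol.n_atoms}\n{mol.name}\n")
        for a in mol.atoms:
            x, y, z = a.position
            fh.write(f"{a.element:<3s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def read_charge_csv(
    source: str | Path | TextIO, mol: Molecule
) -> tuple[ChargeSet, ChargeSet, ChargeSet]:
    """Neutral/anion/cation charge sets from the 0-based charge CSV schema.

    Columns: ``atom_index, element, q_neutral, q_anion, q_cation``.  Rows
    may appear in any order (index-keyed); every atom must be present
    exactly once and the element column must match the molecule.
    """
    df = pd.read_csv(source)
    missing = [c for c in CHARGE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"charge CSV missing columns: {missing}")
    if len(df) != mol.n_atoms:
        raise ValueError(
            f"charge CSV has {len(df)} rows for a {mol.n_atoms}-atom molecule"
        )
    df = df.sort_values("atom_index")
    idx = df["atom_index"].to_numpy()
    if not np.array_equal(idx, np.arange(mol.n_atoms)):
        raise ValueError("atom_index must cover 0..N-1 exactly once")
    for i, el in zip(idx, df["element"]):
        if el != mol.atoms[int(i)].element:
            raise ValueError(
                f"element mismatch at atom {i}: CSV says {el!r}, "
                f"molecule has {mol.atoms[int(i)].element!r}"
            )
    return (
        ChargeSet("neutral", df["q_neutral"].to_numpy(), "csv"),
        ChargeSet("anion", df["q_anion"].to_numpy(), "csv"),
        ChargeSet("cation", df["q_cation"].to_numpy(), "csv"),
    )


def write_charge_csv(
    dest: str | Path,
    mol: Molecule,
    neutral: ChargeSet,
    anion: ChargeSet,
    cation: ChargeSet,
) -> None:
    pd.DataFrame(
        {
            "atom_index": np.arange(mol.n_atoms),
            "element": mol.elements,
            "q_neutral": neutral.charges,
            "q_anion": anion.charges,
            "q_cation": cation.charges,
        }
    ).to_csv(dest, index=False)


def read_fasta(source: str | Path | TextIO) -> list[tuple[str, str]]:
    """(header, uppercase sequence) pairs from a FASTA file, in file order."""
    fh = _open(source)
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(fh, "fasta")]
    if not records:
        raise ValueError("no FASTA records found")
    for rid, seq in records:
        for pos, ch in enumerate(seq):
            if ch not in "ACDEFGHIKLMNPQRSTVWY":
                raise ValueError(
                    f"record {rid!r}: illegal residue {ch!r} at position {pos}"
                )
    return records


_POP_LINE = re.compile(
    r"^\s*(\d+)\s+([A-Z][a-z]?)\s*:?\s+(-?\d+\.\d+)", re.MULTILINE
)


def parse_population_block(text: str) -> pd.DataFrame:
    """Best-effort extraction of per-atom charges from a population-analysis
    text block as printed by common quantum-chemistry codes.

    Looks for lines of the form ``<index> <element>[:] <charge> ...`` and
    returns a DataFrame with ``atom_index`` (renumbered to 0-based if the
    block counts from 1), ``element`` and ``charge``.  Dialects vary; this
    parser is deliberately lenient and meant for interactive use.
    """
    hits = _POP_LINE.findall(text)
    if not hits:
        raise ValueError("no population-analysis lines recognized")
    idx = np.array([int(h[0]) for h in hits])
    if idx.min() == 1:
        idx = idx - 1
    return pd.DataFrame(
        {
            "atom_index": idx,
            "element": [h[1] for h in hits],
            "charge": [float(h[2]) for h in hits],
        }
    )


def read_config(source: str | Path) -> RunConfig:
    """RunConfig from a ``key = value`` text file; unknown keys rejected."""
    cfg: dict[str, str] = {}
    for ln in Path(source).read_text().splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        if "=" not in ln:
            raise ValueError(f"config line not 'key = value': {ln!r}")
        k, v = (part.strip() for part in ln.split("=", 1))
        cfg[k] = v
    kwargs: dict = {}
    for k, v in cfg.items():
        if k in ("ph", "c_lr", "tau"):
            kwargs[k] = float(v)
        elif k == "seed":
            kwargs[k] = int(v)
        elif k == "condense_hydrogens":
            kwargs[k] = v.lower() in ("1", "true", "yes")
        elif k in ("pka_table_name", "transform", "out_dir"):
            kwargs[k] = v
        else:
            raise ValueError(f"unknown config key {k!r}")
    return RunConfig(**kwargs)
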