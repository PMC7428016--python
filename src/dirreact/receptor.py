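"""Protein net charge at a given pH from sequence or residue composition.

Each ionizable group contributes its Henderson–Hasselbalch average charge:

    basic sites  (H, K, R, N-terminus):  +1 / (1 + 10^(pH − pKa))
    acidic sites (D, E, C, Y, C-terminus): −1 / (1 + 10^(pKa − pH))

Summed over the residue counts this gives the net charge Q_net that enters
the directional-reactivity score.  Several published pKa presets ship with
the package; supplying a full sequence includes the chain termini by
default, a bare composition excludes them (a composition does not imply a
single chain).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "PkaTable",
    "ResidueComposition",
    "ReceptorChargeResult",
    "PKA_PRESETS",
    "get_pka_table",
    "composition_from_sequence",
    "residue_charge",
    "net_charge",
]

BASIC_SITES = frozenset({"H", "K", "R", "N_term"})
ACIDIC_SITES = frozenset({"D", "E", "C", "Y", "C_term"})
IONIZABLE = BASIC_SITES | ACIDIC_SITES

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PkaTable:
    """Named map from ionizable residue / terminus code to pKa."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        for code, pka in self.values.items():
            if code not in IONIZABLE:
                raise ValueError(f"non-ionizable code in pKa table: {code!r}")
            if not (0.0 < pka < 14.0):
                raise ValueError(f"pKa for {code} out of range (0, 14): {pka}")

    def __getitem__(self, code: str) -> float:
        return self.values[code]

    def __contains__(self, code: str) -> bool:
        return code in self.values


# Side-chain and termini pKa sets in common biochemical use.  "classic" is
# the traditional textbook set; EMBOSS and Sillero are the conventions of
# the respective isoelectric-point calculators.
PKA_PRESETS: dict[str, PkaTable] = {
    "classic": PkaTable(
        "classic",
        {
            "D": 3.65, "E": 4.25, "C": 8.3, "Y": 10.1,
            "H": 6.0, "K": 10.5, "R": 12.5,
            "N_term": 9.0, "C_term": 3.1,
        },
    ),
    "emboss": PkaTable(
        "emboss",
        {
            "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
            "H": 6.5, "K": 10.8, "R": 12.5,
            "N_term": 8.6, "C_term": 3.6,
        },
    ),
    "sillero": PkaTable(
        "sillero",
        {
            "D": 4.0, "E": 4.5, "C": 9.0, "Y": 10.0,
            "H": 6.4, "K": 10.4, "R": 12.0,
            "N_term": 8.2, "C_term": 3.2,
        },
    ),
}

DEFAULT_PKA_TABLE = "classic"


def get_pka_table(name: str) -> PkaTable:
    try:
        return PKA_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown pKa preset {name!r}; available: {sorted(PKA_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class ResidueComposition:
    """Residue one-letter-code counts plus total chain length."""

    counts: dict[str, int]
    length: int

    def __post_init__(self) -> None:
        for code, n in self.counts.items():
            if code not in _STANDARD_AA:
                raise ValueError(f"unknown residue code {code!r}")
            if n < 0:
                raise ValueError(f"negative count for residue {code}")
        n_ionizable = sum(
            n for code, n in self.counts.items() if code in IONIZABLE
        )
        if n_ionizable > self.length:
            raise ValueError("ionizable residue counts exceed chain length")


@dataclass(frozen=True)
class ReceptorChargeResult:
    """Net charge (e) at a pH with the per-site-type breakdown."""

    ph: float
    net_charge: float
    per_type: dict[str, float]
    pka_table_name: str
    termini_included: bool


def composition_from_sequence(seq: str) -> ResidueComposition:
    """Exact residue tally of a one-letter-code amino-acid sequence."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in _STANDARD_AA:
            raise ValueError(
                f"illegal residue character {ch!r} at position {pos}"
            )
    return ResidueComposition(counts=dict(Counter(seq)), length=len(seq))


def residue_charge(code: str, ph: float, table: PkaTable) -> float:
    """Henderson–Hasselbalch average charge of one ionizable site."""
    if code not in IONIZABLE:
        raise ValueError(f"{code!r} is not an ionizable residue or terminus")
    if code not in table:
        raise ValueError(f"pKa table {table.name!r} has no entry for {code}")
    pka = table[code]
    if code in BASIC_SITES:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    return -1.0 / (1.0 + 10.0 ** (pka - ph))


def net_charge(
    comp_or_seq: ResidueComposition | str,
    ph: float,
    table: PkaTable | str = DEFAULT_PKA_TABLE,
    include_termini: bool | None = None,
) -> ReceptorChargeResult:
    """Net protein charge at ``ph`` from a sequence or residue composition.

    ``include_termini`` defaults to True for a sequence input (one chain,
    one N- and one C-terminus) and False for a bare composition; pass a
    boolean to override either default.
    """
    if isinstance(table, str):
        table = get_pka_table(table)
    if not (0.0 < ph < 14.0):
        raise ValueError(f"pH {ph} outside (0, 14)")
    if isinstance(comp_or_seq, str):
        comp = composition_from_sequence(comp_or_seq)
        if include_termini is None:
            include_termini = True
    else:
        comp = comp_or_seq
        if include_termini is None:
            include_termini = False

    per_type: dict[str, float] = {}
    for code in sorted(comp.counts):
        n = comp.counts[code]
        if code in IONIZABLE and code in table and n > 0:
            per_type[code] = n * residue_charge(code, ph, table)
    if include_termini:
        per_type["N_term"] = residue_charge("N_term", ph, table)
        per_type["C_term"] = residue_charge("C_term", ph, table)
    net = sum(per_type.values())
    return ReceptorChargeResult(
        ph=ph,
        net_charge=net,
        per_type=per_type,
        pka_table_name=table.name,
        termini_included=include_termini,
    )
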