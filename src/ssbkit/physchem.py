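"""Monomer mass, isoelectric point and aliphatic index from residue counts.

All three are computable from the residue multiset alone (no sequence order
needed), so they work equally from a parsed FASTA record or from counts
reconstructed from a printed composition table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from ._util import round_half_up
from .composition import ResidueCounts

#: Average (isotope-abundance weighted) residue masses in Da, i.e. the mass
#: each amino acid contributes inside a peptide chain (free amino acid minus
#: one water).
AVERAGE_RESIDUE_MASS_DA: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS_DA = 18.0153

#: Side-chain and terminal pKa values of the Bjellqvist set, the set used by
#: the common web calculators for protein pI. Exposed so an alternative
#: table can be passed to :func:`isoelectric_point`.
PKA_BJELLQVIST: dict[str, float] = {
    "Nterm": 7.5,
    "Cterm": 3.55,
    "D": 4.05,
    "E": 4.45,
    "C": 9.0,
    "Y": 10.0,
    "H": 5.98,
    "K": 10.0,
    "R": 12.0,
}

_POSITIVE = ("Nterm", "K", "R", "H")
_NEGATIVE = ("Cterm", "D", "E", "C", "Y")


def monomer_mass_da(counts: ResidueCounts) -> float:
    """Unrounded average molecular mass of the chain in Da.

    Sum of count-weighted average residue masses plus one water (the chain's
    free N/C termini). Additive: concatenating two chains costs one water.
    """
    return (
        sum(n * AVERAGE_RESIDUE_MASS_DA[r] for r, n in counts.counts.items())
        + WATER_MASS_DA
    )


def monomer_mass(counts: ResidueCounts) -> float:
    """Monomer mass in kDa, rounded half-up to 1 dp (as tabulated)."""
    return round_half_up(monomer_mass_da(counts) / 1000.0, 1)


def aliphatic_index(counts: ResidueCounts) -> float:
    """Ikai's aliphatic index, a thermostability correlate.

    AI = 100 * (nAla + 2.9 nVal + 3.9 (nIle + nLeu)) / L, i.e. the mole
    fraction of aliphatic side chains weighted by relative side-chain
    volume. Rounded to 2 dp. A poly-Ala chain scores 100.
    """
    l = counts.length
    ai = 100.0 * (
        counts.get("A") + 2.9 * counts.get("V") + 3.9 * (counts.get("I") + counts.get("L"))
    ) / l
    return round_half_up(ai, 2)


def net_charge(
    counts: ResidueCounts, ph: float, pka: Mapping[str, float] = PKA_BJELLQVIST
) -> float:
    """Net protein charge at ``ph`` from Henderson-Hasselbalch occupancies.

    One free N-terminus and one free C-terminus are assumed; all Cys are
    treated as reduced (ionizable). Strictly decreasing in pH, so the
    isoelectric point is unique.
    """
    def n_of(group: str) -> float:
        return 1.0 if group in ("Nterm", "Cterm") else float(counts.get(group))

    pos = sum(
        n_of(g) / (1.0 + 10.0 ** (ph - pka[g])) for g in _POSITIVE
    )
    neg = sum(
        n_of(g) / (1.0 + 10.0 ** (pka[g] - ph)) for g in _NEGATIVE
    )
    return pos - neg


def isoelectric_point(
    counts: ResidueCounts,
    pka: Mapping[str, float] = PKA_BJELLQVIST,
    tol: float = 1e-3,
) -> float:
    """pH of zero net charge, by bisection on [0, 14], reported at 2 dp."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(counts, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return round_half_up(0.5 * (lo + hi), 2)


@dataclass(frozen=True)
class PhyschemReport:
    """Tabulated physicochemical summary of one chain."""

    monomer_mass_kda: float
    pI: float
    aliphatic_index: float
    cys_count: int

    def __post_init__(self) -> None:
        if self.monomer_mass_kda <= 0:
            raise ValueError("mass must be positive")
        if not (0.0 < self.pI < 14.0):
            raise ValueError("pI outside (0, 14)")
        if not (0.0 <= self.aliphatic_index <= 390.0):
            raise ValueError("aliphatic index outside [0, 390]")


def physchem_report(counts: ResidueCounts) -> PhyschemReport:
    return PhyschemReport(
        monomer_mass_kda=monomer_mass(counts),
        pI=isoelectric_point(counts),
        aliphatic_index=aliphatic_index(counts),
        cys_count=counts.get("C"),
    )
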