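"""Sequence and table I/O: FASTA records and amino-acid composition tables.

The composition table format is a CSV with a ``name`` column, a ``length``
column (number of residues) and twenty per-residue percentage columns keyed
by the canonical one-letter codes. A transcription of the published
composition table for the seven psychrophilic SSBs plus EcoSSB, TteSSB3 and
TmaSSB ships with the package (:func:`load_reference_composition`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from ._util import round_half_up

#: The twenty canonical amino-acid one-letter codes, alphabetical.
CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Row-sum slack for composition tables. Printed rows carry one-decimal
#: rounding error of up to +-0.05 per residue; the published FpsSSB row
#: additionally contains an internal inconsistency and sums to 102.1, which
#: the wider default accommodates (the row is kept verbatim, never
#: renormalized).
DEFAULT_ROW_SUM_RANGE = (99.0, 102.5)

#: Stricter slack covering only ordinary rounding error.
STRICT_ROW_SUM_RANGE = (99.0, 101.0)


class InvalidResidueError(ValueError):
    """A sequence contains a character outside the canonical alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence over the 20 canonical residues.

    ``len(record)`` is the residue count, used as the chain length L by all
    downstream computations.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = sorted(set(self.residues) - set(CANONICAL_ALPHABET))
        if bad:
            raise InvalidResidueError(
                f"record {self.id!r}: non-canonical residue(s) {', '.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path, on_invalid: str = "error") -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into validated records, preserving order.

    Whitespace and line wrapping inside sequences are removed and residues
    upper-cased. ``on_invalid`` controls what happens when an entry contains
    a non-canonical residue (B, J, O, U, X, Z, ...): ``"error"`` (default)
    raises :class:`InvalidResidueError` naming the record and character;
    ``"skip"`` drops the record with a warning.
    """
    if on_invalid not in ("error", "skip"):
        raise ValueError(f"on_invalid must be 'error' or 'skip', got {on_invalid!r}")
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        residues = "".join(str(entry.seq).split()).upper()
        try:
            records.append(
                SequenceRecord(id=entry.id, residues=residues, description=entry.description)
            )
        except InvalidResidueError:
            if on_invalid == "error":
                raise
            warnings.warn(f"skipping record {entry.id!r}: non-canonical residues")
    if not records:
        raise ValueError(f"no FASTA records read from {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrapping)."""
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


@dataclass(frozen=True)
class CompositionTable:
    """Per-protein residue percentages (as printed, one decimal) and lengths."""

    percent: Mapping[str, Mapping[str, float]]
    lengths: Mapping[str, int]

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(self.percent)

    def row(self, name: str) -> Mapping[str, float]:
        return self.percent[name]

    def row_sum(self, name: str) -> float:
        return round_half_up(sum(self.percent[name].values()), 1)


def read_composition_table(
    path: str | Path,
    row_sum_range: tuple[float, float] = DEFAULT_ROW_SUM_RANGE,
    sep: str | None = None,
) -> CompositionTable:
    """Read and validate a composition CSV/TSV.

    Requires ``name`` and ``length`` columns plus exactly the 20 canonical
    residue columns. Percentages are kept at printed precision and never
    renormalized. Rows whose sum falls outside ``row_sum_range`` raise.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in ("name", "length") if c not in df.columns]
    missing += [r for r in CANONICAL_ALPHABET if r not in df.columns]
    if missing:
        raise ValueError(f"composition table missing column(s): {', '.join(missing)}")
    percent: dict[str, dict[str, float]] = {}
    lengths: dict[str, int] = {}
    lo, hi = row_sum_range
    for _, row in df.iterrows():
        name = str(row["name"])
        values = {r: float(row[r]) for r in CANONICAL_ALPHABET}
        total = sum(values.values())
        if not (lo - 1e-9 <= total <= hi + 1e-9):
            raise ValueError(
                f"composition row {name!r} sums to {total:.1f}, "
                f"outside [{lo}, {hi}]"
            )
        percent[name] = values
        lengths[name] = int(row["length"])
        if lengths[name] <= 0:
            raise ValueError(f"composition row {name!r}: non-positive length")
    if not percent:
        raise ValueError(f"empty composition table: {path}")
    return CompositionTable(percent=percent, lengths=lengths)


def write_composition_table(table: CompositionTable, path: str | Path) -> None:
    """Write a CompositionTable in the package's CSV dialect."""
    rows = []
    for name in table.proteins:
        row = {"name": name, "length": table.lengths[name]}
        row.update(table.percent[name])
        rows.append(row)
    cols = ["name", "length", *CANONICAL_ALPHABET]
    pd.DataFrame(rows)[cols].to_csv(path, index=False)


def load_reference_composition() -> CompositionTable:
    """The packaged composition table for the ten SSBs under comparison.

    Percentages are transcribed verbatim from the published table. Chain
    lengths for the eight proteins with published lengths are as printed;
    TmaSSB (141) is the unique chain length consistent with its printed row,
    and TteSSB3 (150) is the closest-consistent length (its printed row does
    not admit an exact integer realization at any length).
    """
    ref = resources.files("ssbkit.data").joinpath("composition_table.csv")
    with resources.as_file(ref) as path:
        return read_composition_table(path)
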