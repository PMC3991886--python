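"""Pairwise global alignment with identity/similarity percentages under a
residue similarity-group scheme, and MSA conservation shading.

Identity counts columns with identical residues; similarity additionally
counts columns whose residues are co-members of at least one similarity
group. The default scheme is the six-group classification conventionally
used when shading SSB alignments: {V,L,I,M}, {W,F,Y}, {E,D}, {K,R}, {Q,D},
{S,T} (aspartate deliberately appears in two groups).

The dynamic-programming alignment itself is delegated to Biopython's
``PairwiseAligner`` (affine gap penalties, substitution matrices from
``Bio.Align.substitution_matrices``); this module owns the
identity/similarity bookkeeping and the column-conservation classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from ._util import round_half_up
from .io import SequenceRecord

#: The six similarity groups used for shading SSB alignments.
DEFAULT_SIMILARITY_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("VLIM"),
    frozenset("WFY"),
    frozenset("ED"),
    frozenset("KR"),
    frozenset("QD"),
    frozenset("ST"),
)


@dataclass(frozen=True)
class SimilarityScheme:
    """Residues are similar iff identical or co-members of >= 1 group."""

    groups: tuple[frozenset[str], ...] = DEFAULT_SIMILARITY_GROUPS

    def similar(self, a: str, b: str) -> bool:
        if a == b and a != "-":
            return True
        return any(a in g and b in g for g in self.groups)


@dataclass(frozen=True)
class PairwiseAlignmentResult:
    """An aligned pair with its score and percentage summaries."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: int
    similarity_pct: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        if not (self.identity_pct <= self.similarity_pct <= 100):
            raise ValueError("expected identity <= similarity <= 100")


def identity_similarity(
    aligned_a: str,
    aligned_b: str,
    scheme: SimilarityScheme | None = None,
    denominator: str = "alignment",
) -> tuple[int, int]:
    """Percent identity and percent similarity of an aligned pair.

    ``denominator`` is ``"alignment"`` (full alignment length, the default)
    or ``"shorter"`` (length of the shorter de-gapped sequence). Both are
    symmetric in the two sequences. Percentages are rounded to integers, as
    such tables are printed.
    """
    scheme = scheme or SimilarityScheme()
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings differ in length")
    columns = [
        (x, y) for x, y in zip(aligned_a, aligned_b) if not (x == "-" and y == "-")
    ]
    if denominator == "alignment":
        denom = len(columns)
    elif denominator == "shorter":
        denom = min(
            len(aligned_a.replace("-", "")), len(aligned_b.replace("-", ""))
        )
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("zero-length alignment")
    ident = sum(1 for x, y in columns if x == y and x != "-")
    simil = sum(
        1 for x, y in columns if x != "-" and y != "-" and scheme.similar(x, y)
    )
    return (
        int(round_half_up(100.0 * ident / denom)),
        int(round_half_up(100.0 * simil / denom)),
    )


def global_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    scheme: SimilarityScheme | None = None,
    denominator: str = "alignment",
) -> PairwiseAlignmentResult:
    """Optimal end-to-end (Needleman-Wunsch) alignment with affine gaps.

    ``matrix`` names any matrix shipped with Biopython (BLOSUM and PAM
    series); gap penalties are given as positive costs. Among co-optimal
    alignments the aligner's first traceback is taken, which is
    deterministic for fixed inputs and parameters.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aligner.mode = "global"
    aln = aligner.align(sa, sb)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    ident, simil = identity_similarity(aligned_a, aligned_b, scheme, denominator)
    return PairwiseAlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(aln.score),
        identity_pct=ident,
        similarity_pct=simil,
    )


#: Conservation classes, highest first: fully conserved column, >=80%
#: similarity cluster, >=60% similarity cluster, unconserved.
SHADE_CLASSES = ("100%", ">=80%", ">=60%", "none")


def shade_msa(
    msa: Sequence[str],
    scheme: SimilarityScheme | None = None,
    thresholds: tuple[float, float, float] = (1.0, 0.8, 0.6),
) -> list[str]:
    """Classify each column of a pre-aligned MSA by conservation band.

    For each column the largest similarity cluster is found: the maximum,
    over residues present, of the fraction of sequences carrying a residue
    similar to it (gaps never count as similar). Columns are labelled
    ``"100%"``, ``">=80%"``, ``">=60%"`` or ``"none"`` against the given
    thresholds — the shading bands of conventional alignment editors.
    """
    scheme = scheme or SimilarityScheme()
    if not msa:
        raise ValueError("empty MSA")
    width = len(msa[0])
    if any(len(s) != width for s in msa):
        raise ValueError("ragged MSA: sequences differ in length")
    t100, t80, t60 = thresholds
    labels = []
    for j in range(width):
        column = [s[j] for s in msa]
        residues = [c for c in column if c != "-"]
        best = 0.0
        for r in set(residues):
            frac = sum(1 for c in column if c != "-" and scheme.similar(r, c)) / len(
                column
            )
            best = max(best, frac)
        if best >= t100:
            labels.append(SHADE_CLASSES[0])
        elif best >= t80:
            labels.append(SHADE_CLASSES[1])
        elif best >= t60:
            labels.append(SHADE_CLASSES[2])
        else:
            labels.append(SHADE_CLASSES[3])
    return labels
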