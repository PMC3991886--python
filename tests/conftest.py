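from __future__ import annotations

import itertools

import pytest
from hypothesis import settings

from ssbkit.io import load_reference_composition

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_composition()


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing a FASTA file from (id, sequence) pairs."""

    def _write(entries, name="input.fasta"):
        path = tmp_path / name
        path.write_text(
            "".join(f">{rid}\n{seq}\n" for rid, seq in entries)
        )
        return path

    return _write


def brute_force_global_score(
    a: str,
    b: str,
    matrix,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Optimal global alignment score by exhaustive enumeration.

    Enumerates every monotone alignment of ``a`` and ``b`` (including end
    gaps) and scores it with affine gap penalties: a maximal gap run of
    length k costs gap_open + (k-1)*gap_extend, charged per sequence.
    Independent of any dynamic-programming shortcut; exponential, so only
    usable for short sequences.
    """

    best = [float("-inf")]

    def recurse(i, j, score, last):
        # last: 0 = column consumed both, 1 = gap in a, 2 = gap in b
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, score + matrix[a[i], b[j]], 0)
        if j < len(b):  # gap in a (consume b[j])
            cost = gap_extend if last == 1 else gap_open
            recurse(i, j + 1, score - cost, 1)
        if i < len(a):  # gap in b (consume a[i])
            cost = gap_extend if last == 2 else gap_open
            recurse(i + 1, j, score - cost, 2)

    recurse(0, 0, 0.0, -1)
    return best[0]


def all_sequences(alphabet: str, max_len: int):
    """Every non-empty sequence over ``alphabet`` up to ``max_len``."""
    for n in range(1, max_len + 1):
        for tup in itertools.product(alphabet, repeat=n):
            yield "".join(tup)
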