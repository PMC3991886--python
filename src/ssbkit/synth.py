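"""Seeded synthetic-data generators for every input the pipeline consumes.

Each generator is the right inverse of its analyzer at zero noise: a
generated melting curve with Tm 75 yields Tm 75.0 from
:func:`ssbkit.thermal.extract_tm`, a generated titration with n = 32
recovers 32.0 from :func:`ssbkit.titration.fit_site_size`, and so on. At
the documented noise levels recovery holds within the stated tolerances
(see the package methods note). All randomness flows through one
``numpy.random.default_rng(seed)`` per call; no global RNG state.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .composition import reconstruct_counts
from .io import SequenceRecord
from .thermal import DEFAULT_TIME_GRID, MeltingCurve, TimeCourse
from .titration import TitrationCurve, simulate_titration


def generate_protein(
    length: int,
    composition_row: Mapping[str, float],
    seed: int,
    name: str = "synthetic",
) -> SequenceRecord:
    """A uniformly shuffled sequence realizing a printed composition row.

    Counts are reconstructed with largest-remainder apportionment, so
    re-rounded percentages of the output reproduce the row (wherever the
    row is self-consistent).
    """
    counts = reconstruct_counts(composition_row, length)
    residues = [r for r, n in sorted(counts.counts.items()) for _ in range(n)]
    rng = np.random.default_rng(seed)
    rng.shuffle(residues)
    return SequenceRecord(
        id=name,
        residues="".join(residues),
        description=f"synthetic sequence realizing a composition row (seed={seed})",
    )


def generate_titration(
    site_size_n: float,
    quench_q: float,
    k_assoc: float | None = None,
    protein_total: float = 1.5,
    oligo_length: int = 76,
    grid: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    salt_mM: float | None = None,
    seed: int | None = None,
) -> TitrationCurve:
    """An inverse-titration curve in the study geometry.

    Defaults mirror the published assay: 1.5 nmol of tetramer titrated with
    (dT)76. ``k_assoc=None`` selects the tight-binding limit. The default
    grid spans 0 to 1.8x the stoichiometric breakpoint in 19 points, so
    both the declining branch and the plateau are sampled.
    """
    if grid is None:
        d_break = site_size_n * protein_total / oligo_length
        grid = np.linspace(0.0, 1.8 * d_break, 19)
    return simulate_titration(
        site_size_n=site_size_n,
        quench_q=quench_q,
        k_assoc=k_assoc,
        protein_total=protein_total,
        oligo_length=oligo_length,
        grid=np.asarray(grid, dtype=float),
        noise_sd=noise_sd,
        seed=seed,
        salt_mM=salt_mM,
    )


def generate_melting(
    tm: float,
    width: float = 2.0,
    lower_baseline: tuple[float, float] = (0.60, 0.0003),
    upper_baseline: tuple[float, float] = (0.92, 0.0003),
    noise_sd: float = 0.0,
    grid: Sequence[float] | None = None,
    seed: int | None = None,
    label: str = "",
) -> MeltingCurve:
    """A two-state UV melting curve (A260 vs temperature).

    The signal is the lower baseline plus the baseline gap scaled by a
    logistic transition of half-width ``width`` centred at ``tm``.
    Baselines are (intercept, slope) pairs in absorbance units; the default
    grid is 25-95 deg C in 0.5 deg steps (a 1 deg/min heated scan sampled
    twice a degree). ``tm`` must lie inside the grid.
    """
    t = (
        np.arange(25.0, 95.0 + 1e-9, 0.5)
        if grid is None
        else np.asarray(grid, dtype=float)
    )
    if not (t[0] < tm < t[-1]):
        raise ValueError(f"tm={tm} outside the temperature grid [{t[0]}, {t[-1]}]")
    lo = lower_baseline[0] + lower_baseline[1] * t
    hi = upper_baseline[0] + upper_baseline[1] * t
    frac = 1.0 / (1.0 + np.exp(-(t - tm) / width))
    y = lo + (hi - lo) * frac
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd * float(np.mean(hi - lo)), size=y.shape)
    return MeltingCurve(temperature=tuple(t), signal=tuple(y), label=label)


def generate_dsc(
    tm: float,
    width: float = 3.0,
    grid: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    label: str = "",
) -> MeltingCurve:
    """A single-peak calorimetry trace (Gaussian excess heat capacity)."""
    t = (
        np.arange(20.0, 100.0 + 1e-9, 0.5)
        if grid is None
        else np.asarray(grid, dtype=float)
    )
    if not (t[0] < tm < t[-1]):
        raise ValueError(f"tm={tm} outside the temperature grid [{t[0]}, {t[-1]}]")
    y = np.exp(-0.5 * ((t - tm) / width) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return MeltingCurve(temperature=tuple(t), signal=tuple(y), label=label)


def generate_timecourse(
    half_life_min: float,
    grid: Sequence[float] = DEFAULT_TIME_GRID,
    noise_sd: float = 0.0,
    temperature_label: float | None = None,
    seed: int | None = None,
) -> TimeCourse:
    """An exponential-decay inactivation time course.

    fraction_bound(t) = 2^(-t / half_life). The zero-time point is the
    normalization reference and stays at exactly 1; noise on later points
    is Gaussian, clipped to [0, 1].
    """
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    t = np.asarray(grid, dtype=float)
    f = np.power(2.0, -t / half_life_min)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
        f[0] = 1.0
    f = np.clip(f, 0.0, 1.0)
    return TimeCourse(
        times=tuple(t), fraction_bound=tuple(f), temperature_label=temperature_label
    )


def generate_calibration(
    slope: float = -0.076,
    intercept: float = 3.9,
    masses_kda: Sequence[float] = (200.0, 150.0, 66.0, 29.0),
    jitter_min: float = 0.0,
    seed: int | None = None,
) -> list[tuple[float, float]]:
    """Gel-filtration standards (mass kDa, retention min) on a log-linear line.

    The default line and the four default standard masses emulate an
    analytical column resolving 29-200 kDa between roughly 21 and 32 min.
    ``jitter_min`` adds Gaussian retention-time noise.
    """
    if slope == 0:
        raise ValueError("slope must be non-zero")
    rng = np.random.default_rng(seed)
    standards = []
    for m in masses_kda:
        rt = (np.log10(m) - intercept) / slope
        if jitter_min > 0:
            rt += rng.normal(0.0, jitter_min)
        standards.append((float(m), float(rt)))
    return standards
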