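"""Inverse fluorescence titration: forward model and site-size fitting.

In an inverse titration a fixed amount of SSB tetramer is titrated with
increasing amounts of a long oligonucleotide (e.g. (dT)76) while the
intrinsic tryptophan fluorescence is followed. Binding quenches the
fluorescence; the titration end point gives the binding stoichiometry. If
one tetramer occludes ``n`` nucleotides at saturation, each added
oligonucleotide of length ``L`` supplies ``L/n`` tetramer-equivalents of
binding capacity, so the stoichiometric breakpoint sits at
``D_break = n * P / L`` mol of oligonucleotide for ``P`` mol of tetramer.

The forward model is a capacity-based single-equilibrium approximation:
free tetramer and free capacity equilibrate with one observed association
constant ``K`` (mol^-1 in the titration volume); at the tight-binding limit
(K -> inf) the curve is piecewise linear, declining from 1 to the plateau
``1 - Q`` at the breakpoint, with ``Q`` the saturation quench. Cooperative
overlap-lattice effects are deliberately out of scope: the estimands are
``n`` and ``Q``, for which this approximation suffices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


class TitrationNotSaturatedError(ValueError):
    """The curve never reaches a plateau, so n and Q are unidentified."""


@dataclass(frozen=True)
class TitrationCurve:
    """Fluorescence-vs-added-oligonucleotide data for one salt condition.

    Amounts are in nmol (protein as tetramer); ``relative_fluorescence`` is
    normalized to 1 at zero ligand.
    """

    protein_total: float
    oligo_length: int
    added_oligo: tuple[float, ...]
    relative_fluorescence: tuple[float, ...]
    salt_mM: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.added_oligo, dtype=float)
        f = np.asarray(self.relative_fluorescence, dtype=float)
        if d.size != f.size:
            raise ValueError("added_oligo and fluorescence differ in length")
        if d.size < 2 or d[0] != 0.0 or np.any(np.diff(d) <= 0):
            raise ValueError("added_oligo must increase strictly from 0")
        if self.protein_total <= 0 or self.oligo_length <= 0:
            raise ValueError("protein_total and oligo_length must be positive")


def bound_fraction(
    added: np.ndarray | float,
    site_size_n: float,
    k_assoc: float | None,
    protein_total: float,
    oligo_length: int,
) -> np.ndarray:
    """Fraction of tetramer bound at each titration point.

    Solves the mass-action equilibrium between free tetramer P_f and free
    binding capacity S_f (S = L*D/n tetramer-equivalents):
    ``B = K * P_f * S_f``, a quadratic in the bound amount B. ``k_assoc``
    of ``None`` or ``inf`` selects the stoichiometric (tight-binding) limit
    ``B = min(P, S)``.
    """
    d = np.atleast_1d(np.asarray(added, dtype=float))
    p = float(protein_total)
    s = oligo_length * d / float(site_size_n)
    if k_assoc is None or math.isinf(k_assoc):
        b = np.minimum(p, s)
    else:
        if k_assoc <= 0:
            raise ValueError("k_assoc must be positive")
        t = p + s + 1.0 / k_assoc
        b = 0.5 * (t - np.sqrt(t * t - 4.0 * p * s))
    return b / p


def model_fluorescence(
    added: np.ndarray | float,
    site_size_n: float,
    quench_q: float,
    k_assoc: float | None,
    protein_total: float,
    oligo_length: int,
) -> np.ndarray:
    """Noise-free relative fluorescence, ``1 - Q * theta``."""
    theta = bound_fraction(added, site_size_n, k_assoc, protein_total, oligo_length)
    return 1.0 - quench_q * theta


def simulate_titration(
    site_size_n: float,
    quench_q: float,
    k_assoc: float | None,
    protein_total: float,
    oligo_length: int,
    grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    salt_mM: float | None = None,
) -> TitrationCurve:
    """Simulate an inverse titration on ``grid`` (nmol of oligonucleotide).

    Gaussian noise of standard deviation ``noise_sd`` (relative units) is
    added and the signal clipped to [0, 1]; the zero-ligand point stays at
    exactly 1 (the normalization reference). Seeded and reproducible.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or grid[0] != 0.0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must increase strictly from 0")
    if not (0.0 <= quench_q <= 1.0):
        raise ValueError("quench must lie in [0, 1]")
    f = model_fluorescence(
        grid, site_size_n, quench_q, k_assoc, protein_total, oligo_length
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
        f[0] = 1.0
    f = np.clip(f, 0.0, 1.0)
    return TitrationCurve(
        protein_total=float(protein_total),
        oligo_length=int(oligo_length),
        added_oligo=tuple(grid),
        relative_fluorescence=tuple(f),
        salt_mM=salt_mM,
    )


@dataclass(frozen=True)
class BindingFit:
    """Fitted binding parameters from one titration."""

    site_size_n: float
    quench_q: float
    k_obs: float | None
    ci_n: float
    mode: str
    salt_mM: float | None = None

    def __post_init__(self) -> None:
        if self.site_size_n <= 0:
            raise ValueError("site size must be positive")
        if not (0.0 <= self.quench_q <= 1.0 + 1e-9):
            raise ValueError("quench outside [0, 1]")


def fit_site_size(
    curve: TitrationCurve,
    mode: str = "breakpoint",
) -> BindingFit:
    """Estimate binding-site size ``n`` and saturation quench ``Q``.

    ``mode="breakpoint"`` fits a continuous two-segment model (a straight
    line through (0, 1) meeting a plateau at the breakpoint D_b) by least
    squares; ``n = L * D_b / P`` and ``Q = 1 - plateau``. This is the
    classical stoichiometric reading of a tight-binding titration.

    ``mode="equilibrium"`` fits the full finite-K forward model by
    non-linear least squares, returning ``k_obs`` as well; it converges to
    the breakpoint estimate as K grows.

    ``ci_n`` is the ~95% half-width (1.96 sigma) propagated from the fit
    covariance. Raises :class:`TitrationNotSaturatedError` when the fitted
    breakpoint falls at or beyond the penultimate titration point, i.e. the
    data contain no plateau to pin the quench.
    """
    d = np.asarray(curve.added_oligo)
    f = np.asarray(curve.relative_fluorescence)
    if d.size < 6:
        raise ValueError("need at least 6 titration points")
    p_tot, l_oligo = curve.protein_total, curve.oligo_length

    def two_segment(x, d_break, plateau):
        return 1.0 + (plateau - 1.0) * np.minimum(x, d_break) / d_break

    mid = 0.5 * (1.0 + f[-1])  # rough half-quench point seeds the breakpoint
    idx = int(np.argmax(f <= mid)) if np.any(f <= mid) else d.size // 2
    d0 = float(d[idx]) if d[idx] > 0 else float(d[1])
    popt, pcov = curve_fit(
        two_segment,
        d,
        f,
        p0=(d0, float(f[-1])),
        bounds=([d[1] * 0.5, 0.0], [d[-1] * 2.0, 1.0]),
        maxfev=10000,
    )
    d_break, plateau = popt
    if d_break >= d[-2]:
        raise TitrationNotSaturatedError(
            "titration not saturated: no plateau beyond the fitted breakpoint"
        )
    n_bp = l_oligo * d_break / p_tot
    sd_db = float(np.sqrt(max(pcov[0, 0], 0.0)))
    fit_bp = BindingFit(
        site_size_n=float(n_bp),
        quench_q=float(min(max(1.0 - plateau, 0.0), 1.0)),
        k_obs=None,
        ci_n=1.96 * sd_db * l_oligo / p_tot,
        mode="breakpoint",
        salt_mM=curve.salt_mM,
    )
    if mode == "breakpoint":
        return fit_bp
    if mode != "equilibrium":
        raise ValueError(f"unknown mode {mode!r}")

    def equilibrium(x, n, q, log10_k):
        return model_fluorescence(x, n, q, 10.0 ** log10_k, p_tot, l_oligo)

    popt, pcov = curve_fit(
        equilibrium,
        d,
        f,
        p0=(fit_bp.site_size_n, fit_bp.quench_q or 0.5, 3.0),
        bounds=([1.0, 0.0, -2.0], [l_oligo * 4.0, 1.0, 12.0]),
        maxfev=20000,
    )
    n_eq, q_eq, log10_k = popt
    return BindingFit(
        site_size_n=float(n_eq),
        quench_q=float(q_eq),
        k_obs=float(10.0 ** log10_k),
        ci_n=1.96 * float(np.sqrt(max(pcov[0, 0], 0.0))),
        mode="equilibrium",
        salt_mM=curve.salt_mM,
    )


@dataclass(frozen=True)
class SaltModeVerdict:
    """Whether fitted site sizes across salt conditions indicate one
    DNA-binding mode or a salt-dependent mode transition."""

    verdict: str  # "salt-independent" | "mode transition"
    fits: tuple[BindingFit, ...]
    low_salt_n: float | None = None
    high_salt_n: float | None = None


def compare_salt_modes(fits: list[BindingFit] | tuple[BindingFit, ...]) -> SaltModeVerdict:
    """Compare fitted site sizes across salt conditions.

    Salt-independent if every pair of estimates agrees within the sum of
    their uncertainties; otherwise a mode transition is reported with the
    lowest- and highest-salt estimates.
    """
    fits = tuple(fits)
    if len(fits) < 2:
        raise ValueError("need fits at >= 2 salt conditions")
    for i, a in enumerate(fits):
        for b in fits[i + 1:]:
            if abs(a.site_size_n - b.site_size_n) > a.ci_n + b.ci_n:
                ordered = sorted(
                    fits, key=lambda x: (x.salt_mM if x.salt_mM is not None else 0.0)
                )
                return SaltModeVerdict(
                    verdict="mode transition",
                    fits=fits,
                    low_salt_n=ordered[0].site_size_n,
                    high_salt_n=ordered[-1].site_size_n,
                )
    return SaltModeVerdict(verdict="salt-independent", fits=fits)
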