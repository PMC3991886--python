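"""Melting-temperature extraction, duplex destabilization (dTm) and
thermal-inactivation half-lives.

SSBs bind single-stranded but not double-stranded DNA, so their presence
shifts the duplex<->single-strand equilibrium and lowers the apparent
melting temperature of a duplex followed by UV absorbance (A260). dTm =
Tm(free duplex) - Tm(duplex + SSB) measures that destabilization.

Thermostability is assayed indirectly: the protein is incubated at a fixed
temperature for increasing times, and the fraction of a reference
oligonucleotide still bound afterwards is recorded; the half-life is the
incubation time at which 50% of binding activity remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class NoTransitionError(ValueError):
    """The curve shows no usable melting transition."""


class AlreadyInactivatedError(ValueError):
    """The time course starts below 50% activity."""


@dataclass(frozen=True)
class MeltingCurve:
    """A temperature scan: A260 for UV melting, excess heat capacity for DSC."""

    temperature: tuple[float, ...]
    signal: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        if t.size < 10:
            raise ValueError("need >= 10 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature must increase strictly")
        if t.size != len(self.signal):
            raise ValueError("temperature and signal differ in length")


@dataclass(frozen=True)
class Tm:
    """An extracted melting temperature."""

    value: float
    method: str


def extract_tm(
    curve: MeltingCurve,
    method: str = "midpoint",
    baseline_fraction: float = 0.2,
) -> Tm:
    """Extract the melting temperature of a two-state transition.

    ``"midpoint"`` (default for UV melting): straight baselines are fitted
    to the first and last ``baseline_fraction`` of points, the signal is
    normalized between them, and Tm is where the normalized signal crosses
    0.5 (linear interpolation). Invariant to affine rescaling of the signal.

    ``"derivative"``: Tm is the grid temperature maximizing the centred
    finite difference of the 3-point-smoothed signal.

    ``"dsc-peak"`` (for calorimetry traces): the temperature of the signal
    maximum.

    Raises :class:`NoTransitionError` when the baselines are
    indistinguishable or the normalized signal never crosses 0.5.
    """
    t = np.asarray(curve.temperature, dtype=float)
    y = np.asarray(curve.signal, dtype=float)

    if method == "dsc-peak":
        return Tm(value=float(t[int(np.argmax(y))]), method=method)

    if method == "derivative":
        kernel = np.ones(3) / 3.0
        smooth = np.convolve(y, kernel, mode="same")
        smooth[0], smooth[-1] = y[0], y[-1]
        dy = np.gradient(smooth, t)
        return Tm(value=float(t[int(np.argmax(np.abs(dy)))]), method=method)

    if method != "midpoint":
        raise ValueError(f"unknown method {method!r}")

    # Locate the transition first (derivative peak and width) so the
    # baseline windows exclude it; fixed-fraction windows that clip a
    # transition tail bias the fitted baselines and hence the midpoint.
    nb = max(2, int(round(baseline_fraction * t.size)))
    dy = np.gradient(y, t)
    peak = int(np.argmax(np.abs(dy)))
    amp_rough = abs(y[-1] - y[0])
    dmax = float(np.abs(dy[peak]))
    if dmax > 0 and amp_rough > 0:
        width_est = amp_rough / (4.0 * dmax)  # logistic: max slope = amp/4w
        lo_mask = t <= t[peak] - 5.0 * width_est
        hi_mask = t >= t[peak] + 5.0 * width_est
        if lo_mask.sum() >= 3 and hi_mask.sum() >= 3:
            lo_idx, hi_idx = np.where(lo_mask)[0], np.where(hi_mask)[0]
        else:
            lo_idx, hi_idx = np.arange(nb), np.arange(t.size - nb, t.size)
    else:
        lo_idx, hi_idx = np.arange(nb), np.arange(t.size - nb, t.size)
    lo_fit = np.polyfit(t[lo_idx], y[lo_idx], 1)
    hi_fit = np.polyfit(t[hi_idx], y[hi_idx], 1)
    lower = np.polyval(lo_fit, t)
    upper = np.polyval(hi_fit, t)
    amplitude = upper - lower
    mid_amp = float(amplitude[t.size // 2])
    resid = np.concatenate(
        [y[lo_idx] - lower[lo_idx], y[hi_idx] - upper[hi_idx]]
    )
    noise = float(np.std(resid))
    if abs(mid_amp) < max(4.0 * noise, 1e-12):
        raise NoTransitionError("no transition detected: baselines coincide")
    alpha = (y - lower) / amplitude
    crossing = alpha - 0.5
    for i in range(crossing.size - 1):
        if crossing[i] == 0.0:
            return Tm(value=float(t[i]), method=method)
        if crossing[i] < 0.0 <= crossing[i + 1]:
            frac = -crossing[i] / (crossing[i + 1] - crossing[i])
            return Tm(value=float(t[i] + frac * (t[i + 1] - t[i])), method=method)
    raise NoTransitionError("no transition detected: normalized signal never crosses 0.5")


def delta_tm(tm_free: Tm | float, tm_complex: Tm | float) -> float:
    """Destabilization in deg C: Tm(free duplex) - Tm(duplex with SSB).

    Positive values mean the protein lowered the duplex melting point.
    Antisymmetric under argument swap.
    """
    a = tm_free.value if isinstance(tm_free, Tm) else float(tm_free)
    b = tm_complex.value if isinstance(tm_complex, Tm) else float(tm_complex)
    return a - b


#: Default incubation-time grid of the inactivation assay, in minutes.
DEFAULT_TIME_GRID = (0.0, 1.0, 2.5, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0)


@dataclass(frozen=True)
class TimeCourse:
    """Fraction of reference ssDNA bound after each incubation time."""

    times: tuple[float, ...]
    fraction_bound: tuple[float, ...]
    temperature_label: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fraction_bound, dtype=float)
        if t.size != f.size or t.size < 2:
            raise ValueError("need matching time/fraction series of >= 2 points")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must increase strictly from 0")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("fraction_bound outside [0, 1]")


@dataclass(frozen=True)
class HalfLife:
    """Incubation time (min) at which 50% of binding activity remains.

    ``censored`` marks a curve that never fell to 50% within the observed
    grid; ``value`` is then the last observation time and the string form
    reads e.g. ``">60 min"``.
    """

    value: float
    censored: bool = False

    def __str__(self) -> str:
        if self.censored:
            return f">{self.value:g} min"
        return f"{self.value:g} min"


def half_life(tc: TimeCourse) -> HalfLife:
    """Time of the 50% activity crossing, by linear interpolation.

    The crossing is located between the bracketing observations of the
    first drop through 0.5. Raises :class:`AlreadyInactivatedError` when
    activity starts below 50%; returns a censored value when it never
    reaches 50%.
    """
    t = np.asarray(tc.times, dtype=float)
    f = np.asarray(tc.fraction_bound, dtype=float)
    if f[0] < 0.5:
        raise AlreadyInactivatedError("already inactivated at time zero")
    for i in range(f.size):
        if f[i] == 0.5:
            return HalfLife(value=float(t[i]))
        if i + 1 < f.size and f[i] > 0.5 > f[i + 1]:
            frac = (f[i] - 0.5) / (f[i] - f[i + 1])
            return HalfLife(value=float(t[i] + frac * (t[i + 1] - t[i])))
    return HalfLife(value=float(t[-1]), censored=True)
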