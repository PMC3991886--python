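"""Gel-filtration calibration, native-mass estimation and oligomeric-state
calls.

Size-exclusion (gel-filtration) chromatography separates by hydrodynamic
size: over the resolving range, log10 of molecular mass is linear in
retention time. A calibration line fitted to standards of known mass turns
a sample's retention time into a native mass; the ratio of native to
monomer (sequence-derived) mass then calls the oligomeric state — bacterial
SSBs are expected near 4 (homotetramer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._util import round_half_up


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS fit of log10(mass/kDa) against retention time (min)."""

    standards: tuple[tuple[float, float], ...]  # (mass_kda, retention_min)
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")

    @property
    def retention_range(self) -> tuple[float, float]:
        rts = [rt for _, rt in self.standards]
        return (min(rts), max(rts))


def fit_calibration(
    standards: Sequence[tuple[float, float]]
) -> CalibrationCurve:
    """Fit the standard curve from (mass_kda, retention_min) pairs."""
    if len(standards) < 3:
        raise ValueError("need >= 3 calibration standards")
    rts = np.asarray([rt for _, rt in standards], dtype=float)
    masses = np.asarray([m for m, _ in standards], dtype=float)
    if np.unique(rts).size < 3:
        raise ValueError("need >= 3 distinct retention times")
    if np.any(masses <= 0):
        raise ValueError("standard masses must be positive")
    res = stats.linregress(rts, np.log10(masses))
    return CalibrationCurve(
        standards=tuple((float(m), float(rt)) for m, rt in standards),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


@dataclass(frozen=True)
class MassEstimate:
    """A native-mass read-off; ``extrapolated`` flags retention times
    outside the standards' range."""

    mass_kda: float
    retention_min: float
    extrapolated: bool


def estimate_native_mass(curve: CalibrationCurve, retention: float) -> MassEstimate:
    """Native mass (kDa, 1 dp) at a retention time, via the fitted line."""
    lo, hi = curve.retention_range
    mass = 10.0 ** (curve.slope * retention + curve.intercept)
    return MassEstimate(
        mass_kda=round_half_up(mass, 1),
        retention_min=float(retention),
        extrapolated=not (lo <= retention <= hi),
    )


def retention_for_mass(curve: CalibrationCurve, mass_kda: float) -> float:
    """Inverse read-off: retention time at which a mass would elute."""
    if mass_kda <= 0:
        raise ValueError("mass must be positive")
    return (math.log10(mass_kda) - curve.intercept) / curve.slope


@dataclass(frozen=True)
class OligomerCall:
    """Native/monomer mass ratio and the inferred assembly state."""

    native_mass_kda: float
    monomer_mass_kda: float
    ratio: float
    state_label: str


#: (label, expected ratio) bands checked in order.
_STATES = (("homotetramer", 4.0), ("dimer", 2.0), ("monomer", 1.0))


def oligomer_state(
    native_mass_kda: float, monomer_mass_kda: float, window: float = 0.5
) -> OligomerCall:
    """Call the oligomeric state from the native/monomer mass ratio.

    The ratio (reported at 1 dp) is matched against bands centred on 4, 2
    and 1 with half-width ``window`` (default 0.5, wide enough for the
    modest systematic bias of gel-filtration masses); anything else is
    ``"ambiguous"``. The call is invariant to a common rescaling of both
    masses.
    """
    if native_mass_kda <= 0 or monomer_mass_kda <= 0:
        raise ValueError("masses must be positive")
    ratio = native_mass_kda / monomer_mass_kda
    label = "ambiguous"
    for name, center in _STATES:
        if center - window <= ratio <= center + window:
            label = name
            break
    return OligomerCall(
        native_mass_kda=float(native_mass_kda),
        monomer_mass_kda=float(monomer_mass_kda),
        ratio=round_half_up(ratio, 1),
        state_label=label,
    )
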