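"""Activity and concentration calibration.

Two calibrations are covered: (1) the agar-diffusion bioassay, where zone
of inhibition diameter is linear in log10 of the nisin activity (IU/mL)
over the standard range, and (2) LC-MS quantification against a fixed
internal standard, where analyte concentration is linear in the
analyte/internal-standard intensity ratio over the stated linear range.
Also provides the IU <-> mass conversion (40 IU per ug nisin) and stock
activity arithmetic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .constants import IU_PER_MICROGRAM

#: Standard activities used for the agar-diffusion curve (IU/mL).
DEFAULT_ZONE_STANDARDS_IU = (1000.0, 500.0, 250.0, 200.0, 100.0, 20.0, 5.0)

#: Linear range of the internal-standard LC-MS calibration (ppb).
IS_LINEAR_RANGE_PPB = (10.0, 20000.0)

#: Internal standard (angiotensin II) concentration, ppb.
INTERNAL_STANDARD_PPB = 10.0


@dataclass(frozen=True)
class StandardCurve:
    """y = slope * f(x) + intercept with f = log10 or identity."""

    slope: float
    intercept: float
    x_transform: str  # "log10" or "identity"
    valid_range: tuple[float, float]
    r_squared: float

    def _fx(self, x: float) -> float:
        return math.log10(x) if self.x_transform == "log10" else x

    def predict(self, x: float) -> float:
        return self.slope * self._fx(x) + self.intercept

    def invert(self, y: float) -> float:
        if self.slope == 0:
            raise ZeroDivisionError("cannot invert a flat standard curve")
        fx = (y - self.intercept) / self.slope
        return 10**fx if self.x_transform == "log10" else fx

    def in_range(self, x: float) -> bool:
        lo, hi = self.valid_range
        tol = 1e-9 * max(abs(lo), abs(hi), 1.0)  # float slack at the boundaries
        return lo - tol <= x <= hi + tol


def _fit_line(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    if len(set(x)) < 2:
        raise ValueError("need at least two distinct x values to fit a line")
    fit = stats.linregress(x, y)
    # constant y gives an undefined correlation but a perfect zero-residual fit
    r2 = 1.0 if math.isnan(fit.rvalue) else fit.rvalue**2
    return fit.slope, fit.intercept, r2


def fit_zone_curve(
    standards: Sequence[tuple[float, float]],
    x_transform: str = "log10",
) -> StandardCurve:
    """Least-squares zone diameter (mm) vs log10 activity (IU/mL).

    ``standards`` is a list of (activity IU/mL, zone mm) pairs; the valid
    range is the span of standard activities.
    """
    if len(standards) < 2:
        raise ValueError("need at least two standards")
    concs = [c for c, _ in standards]
    if any(c <= 0 for c in concs) and x_transform == "log10":
        raise ValueError("standard activities must be positive for a log10 curve")
    if x_transform not in ("log10", "identity"):
        raise ValueError(f"unknown x_transform {x_transform!r}")
    x = [math.log10(c) if x_transform == "log10" else c for c in concs]
    y = [z for _, z in standards]
    slope, intercept, r2 = _fit_line(x, y)
    return StandardCurve(slope, intercept, x_transform, (min(concs), max(concs)), r2)


def estimate_activity(curve: StandardCurve, zone_mm: float) -> tuple[float, bool]:
    """Invert the zone curve; returns (activity IU/mL, extrapolated flag)."""
    activity = curve.invert(zone_mm)
    extrapolated = not curve.in_range(activity)
    if extrapolated:
        warnings.warn(
            f"estimated activity {activity:.3g} IU/mL lies outside the standard "
            f"range {curve.valid_range}",
            stacklevel=2,
        )
    return activity, extrapolated


def zone_diameter(horizontal_mm: float, vertical_mm: float | None = None) -> float:
    """Mean of horizontal and vertical caliper readings (or the single one)."""
    if vertical_mm is None:
        return horizontal_mm
    return (horizontal_mm + vertical_mm) / 2.0


def iu_from_mass(micrograms: float) -> float:
    """International units of nisin activity for a given mass (40 IU/ug)."""
    if micrograms < 0:
        raise ValueError("mass must be non-negative")
    return IU_PER_MICROGRAM * micrograms


def mass_from_iu(iu: float) -> float:
    if iu < 0:
        raise ValueError("activity must be non-negative")
    return iu / IU_PER_MICROGRAM


def stock_activity(mass_mg: float, potency_iu_per_g: float, volume_ml: float) -> float:
    """Activity (IU/mL) of a stock made from mass_mg of powder in volume_ml."""
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    if mass_mg < 0 or potency_iu_per_g < 0:
        raise ValueError("mass and potency must be non-negative")
    return (mass_mg / 1000.0) * potency_iu_per_g / volume_ml


@dataclass(frozen=True)
class IsCalibration:
    """Internal-standard LC-MS calibration: conc (ppb) vs analyte/IS ratio."""

    curve: StandardCurve
    internal_standard_conc: float = INTERNAL_STANDARD_PPB
    linear_range: tuple[float, float] = IS_LINEAR_RANGE_PPB


def fit_is_curve(points: Sequence[tuple[float, float]]) -> IsCalibration:
    """Fit conc (ppb) = slope * ratio + intercept from (conc, ratio) pairs."""
    if len(points) < 2:
        raise ValueError("need at least two calibration points")
    lo, hi = IS_LINEAR_RANGE_PPB
    outside = [c for c, _ in points if not lo <= c <= hi]
    if outside:
        warnings.warn(
            f"calibration points {outside} lie outside the linear range {IS_LINEAR_RANGE_PPB}",
            stacklevel=2,
        )
    ratios = [r for _, r in points]
    concs = [c for c, _ in points]
    slope, intercept, r2 = _fit_line(ratios, concs)
    curve = StandardCurve(slope, intercept, "identity", (min(concs), max(concs)), r2)
    return IsCalibration(curve=curve)


def quantify(cal: IsCalibration, ratio: float) -> tuple[float, bool]:
    """Analyte concentration (ppb) for a ratio; flags out-of-linear-range."""
    conc = cal.curve.predict(ratio)
    lo, hi = cal.linear_range
    out_of_range = not lo <= conc <= hi
    if out_of_range:
        warnings.warn(
            f"quantified concentration {conc:.3g} ppb outside linear range {cal.linear_range}",
            stacklevel=2,
        )
    return conc, out_of_range
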