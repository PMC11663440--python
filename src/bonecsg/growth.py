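"""Femur-length growth curve and length-based age estimation.

For immature individuals of unknown age, age at death can be estimated from
maximum intermetaphyseal femur length via a third-order polynomial growth
curve FL(a) = c0 + c1*a + c2*a^2 + c3*a^3 fitted to known-age individuals,
then inverted numerically at the observed length.  The fit is femur length
on age (the growth curve as actually drawn), not the reverse regression; the
inverse is unique whenever the fitted cubic is monotone increasing over the
observed age range, which is checked numerically on a dense grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq


class ExtrapolationError(ValueError):
    """Requested femur length lies outside the calibrated length range."""


@dataclass(frozen=True)
class GrowthCurve:
    """Cubic femur-length-for-age curve, FL in mm and age in years.

    ``coefficients`` are ascending (c0, c1, c2, c3).
    """

    coefficients: tuple[float, float, float, float]
    valid_age_range: tuple[float, float]
    valid_length_range: tuple[float, float]
    monotone: bool = True

    def __call__(self, age_years):
        return np.polynomial.polynomial.polyval(age_years, self.coefficients)

    def check_monotone(self, n_grid: int = 1000) -> bool:
        grid = np.linspace(*self.valid_age_range, n_grid)
        return bool(np.all(np.diff(self(grid)) > 0))


def fit_growth_curve(ages_years, femur_lengths_mm) -> GrowthCurve:
    """Ordinary least-squares cubic of femur length on age.

    Requires at least 4 distinct ages.  Records the observed age and length
    ranges and whether the fitted curve is monotone increasing over them.
    """
    a = np.asarray(ages_years, dtype=float)
    fl = np.asarray(femur_lengths_mm, dtype=float)
    if a.shape != fl.shape or a.ndim != 1:
        raise ValueError("ages and lengths must be 1D arrays of equal length")
    if np.unique(a).size < 4:
        raise ValueError("cubic fit needs >= 4 distinct ages")
    coeffs = np.polynomial.polynomial.polyfit(a, fl, deg=3)
    curve = GrowthCurve(
        coefficients=tuple(float(c) for c in coeffs),
        valid_age_range=(float(a.min()), float(a.max())),
        valid_length_range=(float(fl.min()), float(fl.max())),
    )
    object.__setattr__(curve, "monotone", curve.check_monotone())
    return curve


def estimate_age(
    curve: GrowthCurve,
    femur_length_mm: float,
    slack: float = 0.05,
    report_precision: int | None = 2,
) -> float:
    """Invert the growth curve at a femur length by bisection.

    ``slack`` extends the accepted length range by that fraction of its width
    on either side; lengths beyond it raise :class:`ExtrapolationError`.
    ``report_precision`` rounds the returned age (2 decimals by default, the
    conventional reporting precision); pass ``None`` for full precision.
    """
    lo, hi = curve.valid_length_range
    margin = slack * (hi - lo)
    if not (lo - margin <= femur_length_mm <= hi + margin):
        raise ExtrapolationError(
            f"femur length {femur_length_mm} mm outside calibrated range "
            f"[{lo:.1f}, {hi:.1f}] mm (+/- {margin:.1f} mm slack)"
        )
    if not curve.check_monotone():
        roots = _roots_in_range(curve, femur_length_mm)
        if len(roots) != 1:
            raise ValueError(
                f"growth curve is not monotone: FL = {femur_length_mm} mm has "
                f"roots at ages {[round(r, 3) for r in roots]}"
            )
        age = roots[0]
    else:
        a0, a1 = curve.valid_age_range
        f = lambda a: float(curve(a)) - femur_length_mm
        # lengths inside the slack band may sit just beyond the fitted ends
        width = a1 - a0
        while f(a0) > 0 and a0 > curve.valid_age_range[0] - 0.2 * width:
            a0 -= 0.05 * width
        while f(a1) < 0 and a1 < curve.valid_age_range[1] + 0.2 * width:
            a1 += 0.05 * width
        if f(a0) * f(a1) > 0:
            raise ExtrapolationError(
                f"femur length {femur_length_mm} mm not bracketed by the curve"
            )
        age = brentq(f, a0, a1, xtol=1e-10)
    return round(float(age), report_precision) if report_precision is not None else float(age)


def _roots_in_range(curve: GrowthCurve, femur_length_mm: float) -> list[float]:
    c = np.array(curve.coefficients, dtype=float)
    c[0] -= femur_length_mm
    roots = np.polynomial.polynomial.polyroots(c)
    a0, a1 = curve.valid_age_range
    return sorted(
        float(r.real)
        for r in roots
        if abs(r.imag) < 1e-9 and a0 - 1e-9 <= r.real <= a1 + 1e-9
    )


def fit_age_on_length(ages_years, femur_lengths_mm):
    """Sensitivity variant: direct cubic regression of age on femur length.

    Returns a callable mapping femur length (mm) to age (years).  Not the
    default procedure; provided to gauge how much the regression direction
    matters for length-based age estimates.
    """
    a = np.asarray(ages_years, dtype=float)
    fl = np.asarray(femur_lengths_mm, dtype=float)
    if np.unique(fl).size < 4:
        raise ValueError("cubic fit needs >= 4 distinct lengths")
    coeffs = np.polynomial.polynomial.polyfit(fl, a, deg=3)
    return lambda length: float(np.polynomial.polynomial.polyval(length, coeffs))
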