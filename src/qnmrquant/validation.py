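"""Method-validation statistics: accuracy (relative error), linearity
(ordinary least squares and R^2), precision (Student-t confidence interval
on replicates) and detection/quantitation limits from signal-to-noise.

Conventions
-----------
* Relative error RE = 100 (calculated - weighed) / weighed, the accuracy
  metric for gravimetric reference values.
* Precision: sample standard deviation (n-1 denominator); the two-sided
  Student-t confidence half-width is t(n-1, c) * sd / sqrt(n).
* t quantiles come from numeric inversion of the regularized incomplete
  beta function (no table lookup), accurate to well under 1e-4.
* LOD/LOQ: the masses at which S:N reaches 10 and 150. In the linear mode
  S:N is modelled as k * mass through the origin, so LOQ/LOD = 15 exactly;
  the direct mode instead returns the smallest measured mass meeting each
  threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import betaincinv

from .errors import DivisionGuardError, InvalidParameterError

__all__ = [
    "CalibrationPoint",
    "LinearityResult",
    "PrecisionResult",
    "ValidationReport",
    "relative_error",
    "linearity_fit",
    "t_quantile",
    "precision_report",
    "lod_loq",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One gravimetric calibration point: weighed mass, measured area and
    the mass calculated back from the area."""

    weighted_mass: float  # mg
    area: float
    calculated_mass: float | None = None  # mg

    def __post_init__(self) -> None:
        if self.weighted_mass <= 0:
            raise InvalidParameterError("weighted_mass must be > 0")
        if self.area < 0:
            raise InvalidParameterError("area must be >= 0")


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise InvalidParameterError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class PrecisionResult:
    n: int
    mean: float  # mg
    sd: float  # mg, sample sd (n-1)
    confidence: float
    t_value: float
    ci_half_width: float  # mg
    ci_relative: float  # % of the mean


@dataclass
class ValidationReport:
    """Bundle of the validation statistics for one quantitation signal."""

    accuracy: list[tuple[CalibrationPoint, float]]  # (point, RE %)
    linearity: LinearityResult
    precision: PrecisionResult
    lod: float | None = None  # mg
    loq: float | None = None  # mg


def relative_error(calculated: float, weighted: float) -> float:
    """RE (%) of a calculated mass against the weighed reference mass."""
    if weighted <= 0:
        raise DivisionGuardError("weighted mass must be > 0")
    return 100.0 * (calculated - weighted) / weighted


def linearity_fit(points: Sequence[tuple[float, float]]) -> LinearityResult:
    """Ordinary least squares of calculated mass on weighed mass.

    R^2 is the explained fraction of the total sum of squares. Raises on
    fewer than 3 points or a degenerate (constant-x) design.
    """
    if len(points) < 3:
        raise InvalidParameterError("linearity needs >= 3 calibration points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise InvalidParameterError("degenerate calibration: all weighed masses equal")
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        r2 = 1.0  # constant response fitted exactly by a flat line
    else:
        resid = y - (slope * x + intercept)
        r2 = 1.0 - np.sum(resid**2) / ss_tot
    return LinearityResult(float(slope), float(intercept), float(min(max(r2, 0.0), 1.0)))


def t_quantile(df: int, confidence: float) -> float:
    """Two-sided Student-t critical value by inversion of the regularized
    incomplete beta function.

    For T ~ t(df), P(|T| > t) = I_{df/(df+t^2)}(df/2, 1/2); the quantile
    solves that for tail probability 1 - confidence.
    """
    if df < 1:
        raise InvalidParameterError("degrees of freedom must be >= 1")
    if not 0 < confidence < 1:
        raise InvalidParameterError("confidence must be in (0, 1)")
    z = float(betaincinv(df / 2.0, 0.5, 1.0 - confidence))
    return math.sqrt(df * (1.0 - z) / z)


def precision_report(replicates: Sequence[float], confidence: float = 0.99) -> PrecisionResult:
    """Replicate (tube-to-tube) precision: mean, sample sd and the two-sided
    Student-t confidence half-width, absolute (mg) and relative (%)."""
    if len(replicates) < 2:
        raise InvalidParameterError("precision needs >= 2 replicates")
    arr = np.asarray(replicates, dtype=float)
    n = len(arr)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    t = t_quantile(n - 1, confidence)
    half = t * sd / math.sqrt(n)
    rel = 100.0 * half / mean if mean != 0 else math.inf
    return PrecisionResult(
        n=n, mean=mean, sd=sd, confidence=confidence, t_value=t,
        ci_half_width=half, ci_relative=rel,
    )


def lod_loq(
    sn_points: Sequence[tuple[float, float]],
    lod_threshold: float = 10.0,
    loq_threshold: float = 150.0,
    mode: str = "linear",
) -> tuple[float, float]:
    """Detection and quantitation limits (mg) from (mass, S:N) measurements.

    ``mode="linear"`` fits S:N = k * mass through the origin by least squares
    and inverts it at the thresholds, which forces LOQ/LOD equal to the
    threshold ratio. ``mode="direct"`` returns the smallest measured mass
    whose S:N meets each threshold (``nan`` when none does).
    """
    if len(sn_points) < 2:
        raise InvalidParameterError("need >= 2 (mass, sn) points")
    mass = np.array([p[0] for p in sn_points], dtype=float)
    sn = np.array([p[1] for p in sn_points], dtype=float)
    if len(np.unique(mass)) < 2:
        raise InvalidParameterError("need >= 2 distinct masses")
    order = np.argsort(mass)
    if np.any(np.diff(sn[order]) < 0):
        warnings.warn("S:N is not monotone increasing with mass", stacklevel=2)
    if mode == "linear":
        k = float(np.sum(mass * sn) / np.sum(mass**2))
        if k <= 0:
            raise InvalidParameterError("fitted S:N slope is non-positive")
        return lod_threshold / k, loq_threshold / k
    if mode == "direct":
        def smallest(threshold: float) -> float:
            ok = mass[sn >= threshold]
            return float(ok.min()) if ok.size else math.nan

        return smallest(lod_threshold), smallest(loq_threshold)
    raise InvalidParameterError(f"unknown mode {mode!r}")
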