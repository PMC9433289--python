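"""Region integration, internal-standard area normalization and
signal-to-noise measurement.

Areas are trapezoidal sums over named ppm regions; the optional
``endpoint_linear`` baseline subtracts the chord through the region's
endpoint intensities before integrating (a local first-order baseline).
S:N follows the common spectrometer-software convention: peak height over
twice the noise standard deviation. The source instrument's convention varies, so
the divisor is configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DivisionGuardError, InvalidParameterError, RegionError
from .types import Spectrum

__all__ = [
    "IntegrationRegion",
    "AreaTable",
    "SNResult",
    "integrate_regions",
    "normalize_to_reference",
    "signal_to_noise",
]


@dataclass(frozen=True)
class IntegrationRegion:
    """A labelled ppm interval; bounds are order-insensitive."""

    label: str
    ppm_lo: float
    ppm_hi: float
    baseline_mode: str = "none"  # "none" | "endpoint_linear"

    def __post_init__(self) -> None:
        if self.ppm_lo == self.ppm_hi:
            raise InvalidParameterError(f"region {self.label!r}: zero-width region")
        lo, hi = sorted((self.ppm_lo, self.ppm_hi))
        object.__setattr__(self, "ppm_lo", lo)
        object.__setattr__(self, "ppm_hi", hi)
        if self.baseline_mode not in ("none", "endpoint_linear"):
            raise InvalidParameterError(
                f"region {self.label!r}: unknown baseline_mode {self.baseline_mode!r}"
            )

    def overlaps(self, other: "IntegrationRegion") -> bool:
        return self.ppm_lo < other.ppm_hi and other.ppm_lo < self.ppm_hi


@dataclass
class AreaTable:
    """Raw areas per region label, optionally normalized so the internal
    standard's area is fixed at exactly 1.00."""

    raw: dict[str, float]
    reference_label: str | None = None
    normalized: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not math.isfinite(v) for v in self.raw.values()):
            raise InvalidParameterError("raw areas must be finite")


@dataclass(frozen=True)
class SNResult:
    signal_label: str
    peak_height: float
    noise_sd: float
    sn_ratio: float


def _region_slice(spectrum: Spectrum, region: IntegrationRegion) -> slice:
    """Indices of the (high->low stored) axis falling inside the region."""
    axis = spectrum.ppm_axis
    mask = (axis >= region.ppm_lo) & (axis <= region.ppm_hi)
    idx = np.nonzero(mask)[0]
    if idx.size < 2:
        raise RegionError(
            f"region {region.label!r} [{region.ppm_lo}, {region.ppm_hi}] ppm has "
            f"fewer than 2 axis points in window "
            f"[{axis.min():.3f}, {axis.max():.3f}] ppm"
        )
    return slice(idx[0], idx[-1] + 1)


def integrate_regions(
    spectrum: Spectrum, regions: Sequence[IntegrationRegion]
) -> AreaTable:
    """Trapezoidal areas of each region, evaluated over the exact bounds
    with linearly interpolated endpoint intensities — so integration is
    exactly additive over adjacent regions and insensitive to bound order.
    Areas are positive for positive peaks regardless of axis storage."""
    xs = spectrum.ppm_axis[::-1]  # ascending view
    ys = spectrum.intensities[::-1]
    raw: dict[str, float] = {}
    for region in regions:
        lo, hi = region.ppm_lo, region.ppm_hi
        if lo < xs[0] or hi > xs[-1]:
            raise RegionError(
                f"region {region.label!r} [{lo}, {hi}] ppm outside spectral "
                f"window [{xs[0]:.3f}, {xs[-1]:.3f}] ppm"
            )
        inside = (xs > lo) & (xs < hi)
        x = np.concatenate(([lo], xs[inside], [hi]))
        y = np.concatenate(
            ([np.interp(lo, xs, ys)], ys[inside], [np.interp(hi, xs, ys)])
        )
        if region.baseline_mode == "endpoint_linear":
            y = y - (y[0] + (y[-1] - y[0]) * (x - lo) / (hi - lo))
        raw[region.label] = float(np.trapezoid(y, x))
    return AreaTable(raw=raw)


def normalize_to_reference(areas: AreaTable, reference_label: str) -> AreaTable:
    """Divide every raw area by the internal standard's; the reference
    normalizes to exactly 1.00. Idempotent."""
    if reference_label not in areas.raw:
        raise DivisionGuardError(f"reference label {reference_label!r} not in area table")
    ref = areas.raw[reference_label]
    if ref == 0.0:
        raise DivisionGuardError(f"reference area {reference_label!r} is zero")
    normalized = {label: a / ref for label, a in areas.raw.items()}
    normalized[reference_label] = 1.0
    return AreaTable(raw=dict(areas.raw), reference_label=reference_label,
                     normalized=normalized)


def signal_to_noise(
    spectrum: Spectrum,
    peak_region: IntegrationRegion,
    noise_region: IntegrationRegion,
    divisor: float = 2.0,
) -> SNResult:
    """S:N = peak height / (divisor * noise standard deviation).

    Peak height is the maximum intensity in the peak region minus the median
    of the noise region; the noise region must be signal-free and hold at
    least 32 points. A noiseless spectrum yields an infinite ratio with a
    warning rather than an exception.
    """
    if peak_region.overlaps(noise_region):
        raise InvalidParameterError("peak and noise regions must be disjoint")
    peak_sl = _region_slice(spectrum, peak_region)
    noise_sl = _region_slice(spectrum, noise_region)
    noise = spectrum.intensities[noise_sl]
    if noise.size < 32:
        raise InvalidParameterError(
            f"noise region {noise_region.label!r} has {noise.size} points; >= 32 required"
        )
    baseline = float(np.median(noise))
    height = float(np.max(spectrum.intensities[peak_sl]) - baseline)
    sd = float(np.std(noise, ddof=1))
    if sd == 0.0:
        warnings.warn(
            "noise region has zero standard deviation; S:N reported as infinite",
            stacklevel=2,
        )
        ratio = math.inf
    else:
        ratio = height / (divisor * sd)
    return SNResult(
        signal_label=peak_region.label, peak_height=height, noise_sd=sd, sn_ratio=ratio
    )
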