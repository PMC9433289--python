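"""Core domain types: acquisition parameters, signal/analyte descriptions,
sampled spectra and inversion-recovery series.

Validation happens at construction; every type raises
:class:`~qnmrquant.errors.InvalidParameterError` on invariant violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "AcquisitionParams",
    "SignalSpec",
    "AnalyteSpec",
    "Spectrum",
    "InversionRecoverySeries",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Pulse-acquire acquisition parameters for a 1D proton spectrum.

    Parameters
    ----------
    spectrometer_frequency : float
        Proton Larmor frequency in MHz (default 400.132).
    spectral_width : float
        Spectral width in Hz (default 6410, i.e. ~16 ppm at 400 MHz).
    n_points : int
        Number of real points on the chemical-shift axis.
    flip_angle : float
        Excitation pulse angle in degrees, 0 < alpha <= 180 (default 30).
    acquisition_time : float
        FID acquisition time in seconds.
    relaxation_delay : float
        Inter-scan delay D1 in seconds.
    center_ppm : float
        Chemical shift at the centre of the spectral window (transmitter
        offset), in ppm. Window plumbing, not physics.
    """

    spectrometer_frequency: float = 400.132
    spectral_width: float = 6410.0
    n_points: int = 32768
    flip_angle: float = 30.0
    acquisition_time: float = 2.56
    relaxation_delay: float = 1.0
    center_ppm: float = 7.0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise InvalidParameterError("n_points must be >= 2")
        if self.spectral_width <= 0:
            raise InvalidParameterError("spectral_width must be > 0")
        if not 0 < self.flip_angle <= 180:
            raise InvalidParameterError("flip_angle must be in (0, 180] degrees")
        if self.spectrometer_frequency <= 0:
            raise InvalidParameterError("spectrometer_frequency must be > 0")
        if self.total_recycle_time <= 0:
            raise InvalidParameterError("total recycle time must be > 0")

    @property
    def total_recycle_time(self) -> float:
        """Recycle time TR = acquisition time + relaxation delay, seconds."""
        return self.acquisition_time + self.relaxation_delay

    @property
    def spectral_width_ppm(self) -> float:
        return self.spectral_width / self.spectrometer_frequency


@dataclass(frozen=True)
class SignalSpec:
    """One NMR signal of an analyte: shift, first-order couplings, proton
    count, linewidth and longitudinal relaxation time."""

    label: str
    center_shift: float  # ppm
    couplings: tuple[float, ...] = ()  # Hz; empty = singlet
    n_protons: int = 1
    linewidth: float = 1.0  # Hz, full width at half maximum
    t1: float = 1.0  # s

    def __post_init__(self) -> None:
        object.__setattr__(self, "couplings", tuple(float(j) for j in self.couplings))
        if self.n_protons < 1:
            raise InvalidParameterError(f"{self.label}: n_protons must be >= 1")
        if self.linewidth <= 0:
            raise InvalidParameterError(f"{self.label}: linewidth must be > 0")
        if self.t1 <= 0:
            raise InvalidParameterError(f"{self.label}: t1 must be > 0")
        if any(j < 0 for j in self.couplings):
            raise InvalidParameterError(f"{self.label}: couplings must be >= 0")


@dataclass(frozen=True)
class AnalyteSpec:
    """Chemical description of a compound for simulation and quantitation.

    ``enantiomer_ratio`` is pass-through metadata (e.g. from a chiral GC
    measurement); it plays no role in any computation here.
    """

    name: str
    molecular_weight: float  # g/mol
    purity: float = 1.0  # mass fraction in (0, 1]
    signals: tuple[SignalSpec, ...] = ()
    enantiomer_ratio: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "signals", tuple(self.signals))
        if self.molecular_weight <= 0:
            raise InvalidParameterError(f"{self.name}: molecular_weight must be > 0")
        if not 0 < self.purity <= 1:
            raise InvalidParameterError(f"{self.name}: purity must be in (0, 1]")
        if not self.signals:
            raise InvalidParameterError(f"{self.name}: at least one signal required")
        if self.enantiomer_ratio is not None:
            a, b = self.enantiomer_ratio
            if not np.isclose(a + b, 1.0):
                raise InvalidParameterError(
                    f"{self.name}: enantiomer_ratio fractions must sum to 1"
                )

    def signal(self, label: str) -> SignalSpec:
        for s in self.signals:
            if s.label == label:
                return s
        raise KeyError(f"{self.name} has no signal labelled {label!r}")


@dataclass
class Spectrum:
    """A sampled 1D spectrum: uniform ppm axis (stored high-to-low, the NMR
    display convention) with matching intensities and acquisition metadata.

    ``original_ascending`` records the orientation the data arrived in, so a
    round trip through a file can restore it.
    """

    ppm_axis: np.ndarray
    intensities: np.ndarray
    params: AcquisitionParams = field(default_factory=AcquisitionParams)
    original_ascending: bool = False

    def __post_init__(self) -> None:
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.ppm_axis.shape != self.intensities.shape or self.ppm_axis.ndim != 1:
            raise InvalidParameterError("axis and intensities must be equal-length 1D arrays")
        if len(self.ppm_axis) < 2:
            raise InvalidParameterError("spectrum needs at least 2 points")
        d = np.diff(self.ppm_axis)
        if np.all(d > 0):  # normalize to high->low storage
            self.ppm_axis = self.ppm_axis[::-1].copy()
            self.intensities = self.intensities[::-1].copy()
            self.original_ascending = True
            d = -d[::-1]
        if not np.all(d < 0):
            raise InvalidParameterError("ppm axis must be strictly monotonic")
        step = np.abs(d)
        if not np.allclose(step, step[0], rtol=1e-9, atol=0):
            raise InvalidParameterError("ppm axis must be uniformly spaced")

    @property
    def n_points(self) -> int:
        return len(self.ppm_axis)

    @property
    def step_ppm(self) -> float:
        return float(abs(self.ppm_axis[1] - self.ppm_axis[0]))


@dataclass
class InversionRecoverySeries:
    """Inversion-recovery (180 - tau - 90) intensities versus delay tau."""

    tau_values: np.ndarray
    intensities: np.ndarray
    signal_label: str = ""

    def __post_init__(self) -> None:
        self.tau_values = np.asarray(self.tau_values, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.tau_values.shape != self.intensities.shape or self.tau_values.ndim != 1:
            raise InvalidParameterError("tau and intensities must be equal-length 1D arrays")
        if len(self.tau_values) < 4:
            raise InvalidParameterError(
                "need >= 4 points to fit the 3-parameter recovery model with a residual"
            )
        if not np.all(self.tau_values > 0):
            raise InvalidParameterError("all tau values must be > 0")
        if not np.all(np.diff(self.tau_values) > 0):
            raise InvalidParameterError("tau values must be strictly increasing")
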