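"""Synthetic 1D proton spectra with known ground truth, plus spectrum I/O.

Signals are rendered as sums of Lorentzian lines. Each line

    L(x) = h / (1 + ((x - x0) / (gamma/2))^2)

has analytic area h * pi * gamma / 2, with gamma the full width at half
maximum in ppm (linewidth in Hz divided by the spectrometer frequency).
Peak heights are chosen so the total analytic area of a signal equals

    n_protons * (mass_mg * purity / molecular_weight) * s

i.e. millimoles of observed protons, optionally attenuated by the
steady-state saturation factor s = Mz/M0 of that signal's T1 under the
acquisition scheme (s = 1 when saturation correction is disabled). Any
common proportionality constant cancels in internal-standard area ratios.

First-order multiplets are built by the usual splitting tree: each coupling
J splits every line into two half-intensity lines J/frequency ppm apart.
Noise is iid Gaussian per point — sufficient for signal-to-noise and
detection/quantitation-limit semantics.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError
from .relaxation import SteadyStateQuery, steady_state_mz
from .types import (
    AcquisitionParams,
    AnalyteSpec,
    InversionRecoverySeries,
    SignalSpec,
    Spectrum,
)

__all__ = [
    "multiplet_pattern",
    "simulate_spectrum",
    "simulate_inversion_recovery",
    "read_spectrum",
    "write_spectrum",
    "AcquisitionParams",
    "AnalyteSpec",
    "SignalSpec",
    "Spectrum",
    "InversionRecoverySeries",
]

logger = logging.getLogger(__name__)

_MERGE_TOL_PPM = 1e-9


def multiplet_pattern(
    center_shift: float, couplings: Sequence[float], frequency: float
) -> list[tuple[float, float]]:
    """First-order multiplet line positions (ppm) and relative intensities.

    Applies the splitting tree left to right: each coupling J (Hz) splits
    every line into two lines of half intensity separated by J/frequency ppm,
    centred on the parent. Degenerate lines (within 1e-9 ppm) are merged, so
    two equal couplings yield the familiar 1:2:1 triplet. Intensities always
    sum to 1.
    """
    if frequency <= 0:
        raise InvalidParameterError("spectrometer frequency must be > 0 MHz")
    lines = [(float(center_shift), 1.0)]
    for j in couplings:
        half = 0.5 * j / frequency
        lines = [
            (pos + delta, inten / 2.0)
            for pos, inten in lines
            for delta in (-half, +half)
        ]
    lines.sort()
    merged: list[tuple[float, float]] = []
    for pos, inten in lines:
        if merged and abs(pos - merged[-1][0]) <= _MERGE_TOL_PPM:
            merged[-1] = (merged[-1][0], merged[-1][1] + inten)
        else:
            merged.append((pos, inten))
    return merged


def _lorentzian(x: np.ndarray, x0: float, gamma_ppm: float, area: float) -> np.ndarray:
    half = gamma_ppm / 2.0
    height = area / (np.pi * half)
    return height / (1.0 + ((x - x0) / half) ** 2)


def simulate_spectrum(
    mixture: Sequence[tuple[AnalyteSpec, float]],
    params: AcquisitionParams | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    saturation: bool = False,
) -> Spectrum:
    """Simulate a 1D spectrum of a mixture of analytes at given masses (mg).

    With ``saturation=True`` each signal's area is scaled by the steady-state
    factor Mz/M0 for its T1 under ``params``; the default leaves areas purely
    proportional to moles of protons. Identical arguments (including seed)
    produce identical output. Signals whose centre falls outside the spectral
    window are clipped with a warning.
    """
    params = params or AcquisitionParams()
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    width = params.spectral_width_ppm
    hi = params.center_ppm + width / 2.0
    lo = params.center_ppm - width / 2.0
    axis = np.linspace(hi, lo, params.n_points)  # high -> low storage
    intensities = np.zeros(params.n_points)

    for analyte, mass_mg in mixture:
        if mass_mg < 0:
            raise InvalidParameterError(f"{analyte.name}: mass must be >= 0")
        mmol = mass_mg * analyte.purity / analyte.molecular_weight
        for sig in analyte.signals:
            s = 1.0
            if saturation:
                s = steady_state_mz(
                    SteadyStateQuery(sig.t1, params.total_recycle_time, params.flip_angle)
                )
            signal_area = sig.n_protons * mmol * s
            if not lo <= sig.center_shift <= hi:
                msg = (
                    f"signal {analyte.name}/{sig.label} at {sig.center_shift} ppm "
                    f"outside spectral window [{lo:.2f}, {hi:.2f}]; peak clipped"
                )
                warnings.warn(msg, stacklevel=2)
                logger.warning(msg)
            gamma = sig.linewidth / params.spectrometer_frequency
            for pos, rel in multiplet_pattern(
                sig.center_shift, sig.couplings, params.spectrometer_frequency
            ):
                intensities += _lorentzian(axis, pos, gamma, signal_area * rel)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensities = intensities + rng.normal(0.0, noise_sd, params.n_points)
    return Spectrum(axis, intensities, params=params)


def simulate_inversion_recovery(
    i0: float,
    p: float,
    t1: float,
    tau_values: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    signal_label: str = "",
) -> InversionRecoverySeries:
    """Simulate I(tau) = i0 + p exp(-tau/t1) with optional Gaussian noise."""
    if t1 <= 0:
        raise InvalidParameterError("t1 must be > 0")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    tau = np.asarray(sorted(tau_values), dtype=float)
    y = i0 + p * np.exp(-tau / t1)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, len(tau))
    return InversionRecoverySeries(tau, y, signal_label=signal_label)


# ---------------------------------------------------------------------------
# Spectrum I/O: two-column CSV and a minimal JCAMP-DX XYDATA subset.

def write_spectrum(spectrum: Spectrum, path, format: str = "csv") -> None:
    """Write a spectrum as CSV (``ppm,intensity``, header required) or as a
    minimal JCAMP-DX file with an (X++(Y..Y)) XYDATA table."""
    if format == "csv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("ppm,intensity\n")
            for x, y in zip(spectrum.ppm_axis, spectrum.intensities):
                fh.write(f"{x:.17g},{y:.17g}\n")
    elif format == "jcamp_subset":
        _write_jcamp(spectrum, path)
    else:
        raise InvalidParameterError(f"unknown spectrum format {format!r}")


def read_spectrum(path, format: str = "csv", params: AcquisitionParams | None = None) -> Spectrum:
    """Read a spectrum from CSV or the JCAMP-DX XYDATA subset.

    Either axis orientation is accepted; storage is normalized high-to-low
    with the original orientation recorded on the returned object.
    """
    if format == "csv":
        ppm, inten = _read_csv(path)
    elif format == "jcamp_subset":
        ppm, inten = _read_jcamp(path)
    else:
        raise InvalidParameterError(f"unknown spectrum format {format!r}")
    return Spectrum(ppm, inten, params=params or AcquisitionParams(n_points=max(2, len(ppm))))


def _read_csv(path) -> tuple[np.ndarray, np.ndarray]:
    from .errors import ParseError

    ppm: list[float] = []
    inten: list[float] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if "ppm" not in header or "intensity" not in header:
            raise ParseError(f"{path}:1: expected header 'ppm,intensity'")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two comma-separated columns")
            try:
                ppm.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
    return np.array(ppm), np.array(inten)


def _write_jcamp(spectrum: Spectrum, path) -> None:
    # Store in the on-disk order the object uses internally (high->low).
    x = spectrum.ppm_axis
    y = spectrum.intensities
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##TITLE=qnmrquant simulated spectrum\n")
        fh.write("##JCAMP-DX=5.00\n")
        fh.write("##DATA TYPE=NMR SPECTRUM\n")
        fh.write("##XUNITS=PPM\n##YUNITS=ARBITRARY UNITS\n")
        fh.write("##XFACTOR=1.0\n##YFACTOR=1.0\n")
        fh.write(f"##FIRSTX={x[0]:.17g}\n##LASTX={x[-1]:.17g}\n")
        fh.write(f"##NPOINTS={len(x)}\n")
        fh.write("##XYDATA=(X++(Y..Y))\n")
        # AFFN (free-form numeric) Y values at full precision
        for i in range(0, len(x), 6):
            chunk = y[i : i + 6]
            fh.write(f"{x[i]:.17g} " + " ".join(f"{v:.17e}" for v in chunk) + "\n")
        fh.write("##END=\n")


def _read_jcamp(path) -> tuple[np.ndarray, np.ndarray]:
    from .errors import ParseError

    records: dict[str, str] = {}
    ys: list[float] = []
    in_table = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.strip()
                if key == "XYDATA":
                    if value != "(X++(Y..Y))":
                        raise ParseError(
                            f"{path}:{lineno}: unsupported XYDATA class {value!r}; "
                            "only (X++(Y..Y)) is supported"
                        )
                    in_table = True
                    records[key] = value
                    continue
                if key == "END":
                    in_table = False
                records[key] = value
                continue
            if in_table:
                parts = line.split()
                try:
                    ys.extend(float(v) for v in parts[1:])  # parts[0] is the X check value
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad Y value ({exc})") from exc
    for needed in ("FIRSTX", "LASTX", "NPOINTS"):
        if needed not in records:
            raise ParseError(f"{path}: missing ##{needed}= record")
    if "XYDATA" not in records:
        raise ParseError(f"{path}: no ##XYDATA= table found")
    npoints = int(records["NPOINTS"])
    if len(ys) != npoints:
        raise ParseError(f"{path}: NPOINTS={npoints} but {len(ys)} Y values read")
    xfactor = float(records.get("XFACTOR", "1.0"))
    yfactor = float(records.get("YFACTOR", "1.0"))
    x = np.linspace(float(records["FIRSTX"]), float(records["LASTX"]), npoints) * xfactor
    y = np.asarray(ys) * yfactor
    return x, y
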