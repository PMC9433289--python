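"""Internal-standard mass calculation and content/yield arithmetic.

The core relation converts the area ratio of an analyte signal to the
internal standard's signal into the analyte mass:

    m_F = (A_F * M_F * m_V * P_V * n_V) / (A_V * M_V * P_F * n_F)

where A are integrated areas, M molecular weights (g/mol), m_V the weighed
internal-standard mass (mg), P purities (mass fractions) and n the proton
counts of the two signals (both 1 for the furanone ethylenic protons and the
vanillin aldehyde proton, the defaults). ``purity_mode="none"`` sets both
purities to 1 — the variant that reproduces the published worked values —
while ``"as_printed"`` applies the stated purity factors.

All computation is full precision; rounding happens only in the report
layer (:func:`round_mg`, :func:`round_percent`, :func:`round_sigfig`).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DivisionGuardError, InvalidParameterError

__all__ = [
    "QuantInput",
    "QuantResult",
    "internal_standard_mass",
    "content_percent",
    "extraction_yield",
    "material_content",
    "round_mg",
    "round_percent",
    "round_sigfig",
]


@dataclass(frozen=True)
class QuantInput:
    """Inputs of the internal-standard mass relation (areas, molecular
    weights, reference mass, purities, proton counts)."""

    analyte_area: float  # A_F (dimensionless, internal-standard normalized)
    reference_area: float  # A_V, fixed at 1.00 by convention
    analyte_mw: float  # M_F, g/mol
    reference_mw: float  # M_V, g/mol
    reference_mass: float  # m_V, mg
    reference_purity: float = 1.0  # P_V
    analyte_purity: float = 1.0  # P_F
    analyte_protons: int = 1  # n_F
    reference_protons: int = 1  # n_V
    purity_mode: str = "as_printed"  # "as_printed" | "none"

    def __post_init__(self) -> None:
        if self.analyte_area < 0:
            raise InvalidParameterError("analyte area must be >= 0")
        for name in ("analyte_mw", "reference_mw", "reference_mass"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        for name in ("reference_purity", "analyte_purity"):
            if not 0 < getattr(self, name) <= 1:
                raise InvalidParameterError(f"{name} must be in (0, 1]")
        if self.analyte_protons < 1 or self.reference_protons < 1:
            raise InvalidParameterError("proton counts must be >= 1")
        if self.purity_mode not in ("as_printed", "none"):
            raise InvalidParameterError(f"unknown purity_mode {self.purity_mode!r}")


@dataclass(frozen=True)
class QuantResult:
    """Calculated analyte mass (mg) and, given an extract mass, its content."""

    calculated_mass: float  # m_F, mg, full precision
    content_percent: float | None = None

    def __post_init__(self) -> None:
        if self.calculated_mass < 0:
            raise InvalidParameterError("calculated mass must be >= 0")


def internal_standard_mass(q: QuantInput) -> float:
    """Analyte mass (mg) from the internal-standard area ratio.

    Full-precision result; use :func:`round_mg` for the 2-decimal display
    convention of the reports.
    """
    if q.reference_area == 0:
        raise DivisionGuardError("reference area A_V is zero")
    pv, pf = (q.reference_purity, q.analyte_purity) if q.purity_mode == "as_printed" else (1.0, 1.0)
    return (
        q.analyte_area * q.analyte_mw * q.reference_mass * pv * q.reference_protons
    ) / (q.reference_area * q.reference_mw * pf * q.analyte_protons)


def content_percent(mass_mg: float, extract_mass_mg: float) -> float:
    """Analyte content of the extract, percent by mass."""
    if extract_mass_mg <= 0:
        raise DivisionGuardError("extract mass must be > 0")
    return 100.0 * mass_mg / extract_mass_mg


def extraction_yield(extract_mass_g: float, material_mass_g: float) -> float:
    """Extraction yield, percent w:w of fresh plant material."""
    if material_mass_g <= 0:
        raise DivisionGuardError("material mass must be > 0")
    return 100.0 * extract_mass_g / material_mass_g


def material_content(extract_yield_pct: float, content_pct: float) -> float:
    """Analyte content of the raw material (%), from the extraction yield (%)
    and the analyte content of the extract (%)."""
    for v in (extract_yield_pct, content_pct):
        if not 0 <= v <= 100:
            raise InvalidParameterError("percentages must be in [0, 100]")
    return extract_yield_pct * content_pct / 100.0


# --- display rounding helpers (report layer only) ---------------------------

def round_mg(value: float) -> float:
    """Masses are reported at 2 decimals (0.01 mg)."""
    return round(value, 2)


def round_percent(value: float) -> float:
    """Percentages are reported at 2 decimals."""
    return round(value, 2)


def round_sigfig(value: float, sigfigs: int = 2) -> float:
    """Round to significant figures (leaf-content style: 1.7%)."""
    if value == 0:
        return 0.0
    from math import floor, log10

    return round(value, -int(floor(log10(abs(value)))) + (sigfigs - 1))
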