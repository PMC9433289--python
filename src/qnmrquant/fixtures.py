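"""Published worked-example fixtures: the furanone and vanillin analyte
descriptions, the accuracy/precision tables and the extract quantitation
inputs, loaded from the checked-in ``data/study_fixtures.json``.

The furanone's J coupling constants are invented, configurable defaults
(the source states only multiplicities); nothing quantitative depends on
them. Tests and pipelines load these fixtures rather than retyping values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Any

from .types import AcquisitionParams, AnalyteSpec, SignalSpec
from .validation import CalibrationPoint

__all__ = ["StudyFixtures", "load_fixtures"]


@dataclass(frozen=True)
class StudyFixtures:
    """Typed view of the worked-example data set."""

    furanone: AnalyteSpec
    vanillin: AnalyteSpec
    acquisition: AcquisitionParams
    accuracy: dict[str, list[CalibrationPoint]]
    accuracy_printed_re: dict[str, list[float]]
    accuracy_vanillin_mass: float
    precision_replicates: dict[str, list[float]]
    precision_weighted_mass: float
    extract: dict[str, Any]
    extraction: dict[str, float]
    relaxation: dict[str, float]
    lod_loq: dict[str, float]
    raw: dict[str, Any]


def _analyte(d: dict[str, Any]) -> AnalyteSpec:
    return AnalyteSpec(
        name=d["name"],
        molecular_weight=d["molecular_weight"],
        purity=d["purity"],
        signals=tuple(
            SignalSpec(
                label=s["label"],
                center_shift=s["center_shift"],
                couplings=tuple(s["couplings"]),
                n_protons=s["n_protons"],
                linewidth=s["linewidth"],
                t1=s["t1"],
            )
            for s in d["signals"]
        ),
        enantiomer_ratio=tuple(d["enantiomer_ratio"]) if d.get("enantiomer_ratio") else None,
    )


def load_fixtures() -> StudyFixtures:
    """Load and type the checked-in worked-example data."""
    raw = json.loads(
        resources.files("qnmrquant.data").joinpath("study_fixtures.json").read_text()
    )
    acq = raw["acquisition"]
    accuracy = {
        sig: [
            CalibrationPoint(
                weighted_mass=row["weighted_mass"],
                area=row["area"],
                calculated_mass=row["calculated_mass"],
            )
            for row in rows
        ]
        for sig, rows in raw["accuracy_table"].items()
        if isinstance(rows, list)
    }
    printed_re = {
        sig: [row["printed_re"] for row in rows]
        for sig, rows in raw["accuracy_table"].items()
        if isinstance(rows, list)
    }
    return StudyFixtures(
        furanone=_analyte(raw["analytes"]["furanone"]),
        vanillin=_analyte(raw["analytes"]["vanillin"]),
        acquisition=AcquisitionParams(
            spectrometer_frequency=acq["spectrometer_frequency"],
            spectral_width=acq["spectral_width"],
            flip_angle=acq["flip_angle"],
            acquisition_time=acq["acquisition_time"],
            relaxation_delay=acq["relaxation_delay"],
        ),
        accuracy=accuracy,
        accuracy_printed_re=printed_re,
        accuracy_vanillin_mass=raw["accuracy_table"]["vanillin_mass_mg"],
        precision_replicates={
            sig: list(raw["precision_table"][sig]["calculated_masses"])
            for sig in ("H2", "H3")
        },
        precision_weighted_mass=raw["precision_table"]["weighted_mass_mg"],
        extract=raw["extract_quantitation"],
        extraction=raw["extraction"],
        relaxation=raw["relaxation"],
        lod_loq=raw["lod_loq"],
        raw=raw,
    )
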