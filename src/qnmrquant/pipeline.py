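"""End-to-end pipelines: the extract quantitation worked example and the
full validation battery, producing structured records plus human-readable
reports with embedded seed, config hash and software version.

Display convention: masses and percentages are rounded to 2 decimals in
reports, and the extract content is computed from the *reported* (2 dp)
mass — the convention that matches the published worked example. Leaf-level
content is reported at 2 significant figures.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

from . import __version__
from .errors import InvalidParameterError
from .fixtures import StudyFixtures, load_fixtures
from .quantitation import (
    QuantInput,
    content_percent,
    extraction_yield,
    internal_standard_mass,
    material_content,
    round_mg,
    round_percent,
    round_sigfig,
)
from .validation import (
    ValidationReport,
    linearity_fit,
    lod_loq,
    precision_report,
    relative_error,
)

__all__ = ["QuantReport", "run_extract_quantitation", "run_validation_pipeline", "config_hash"]


def config_hash(config: dict[str, Any]) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(config: dict[str, Any], seed: int | None) -> dict[str, Any]:
    return {
        "software_version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
    }


@dataclass
class QuantReport:
    """Per-signal quantitation of the analyte in the extract."""

    header: dict[str, Any]
    purity_mode: str
    extract_mass_mg: float
    per_signal: dict[str, dict[str, float]]  # label -> {area, mass_mg, content_pct}
    extract_yield_pct: float | None = None
    leaf_content_pct: float | None = None
    lines: list[str] = field(default_factory=list)

    def text(self) -> str:
        return "\n".join(self.lines)


def run_extract_quantitation(
    fixtures: StudyFixtures | None = None,
    purity_mode: str = "none",
    seed: int | None = None,
) -> QuantReport:
    """Quantify the furanone in the extract from each ethylenic signal.

    For each signal: analyte mass via the internal-standard relation, then
    extract content from the reported (2 dp) mass; finally the leaf-level
    content from the extraction yield.
    """
    fx = fixtures or load_fixtures()
    ex = fx.extract
    config = {"purity_mode": purity_mode, "extract": ex}
    per_signal: dict[str, dict[str, float]] = {}
    lines = [
        f"qnmrquant v{__version__}  extract quantitation  "
        f"(config {config_hash(config)}, seed {seed})",
        f"extract mass: {ex['extract_mass_mg']} mg; internal standard "
        f"{fx.vanillin.name} {ex['vanillin_mass_mg']} mg; purity_mode={purity_mode}",
    ]
    for label, area in ex["areas"].items():
        mass = internal_standard_mass(
            QuantInput(
                analyte_area=area,
                reference_area=1.00,
                analyte_mw=fx.furanone.molecular_weight,
                reference_mw=fx.vanillin.molecular_weight,
                reference_mass=ex["vanillin_mass_mg"],
                reference_purity=fx.vanillin.purity,
                analyte_purity=fx.furanone.purity,
                purity_mode=purity_mode,
            )
        )
        mass_disp = round_mg(mass)
        content = round_percent(content_percent(mass_disp, ex["extract_mass_mg"]))
        per_signal[label] = {
            "area": area,
            "mass_mg": mass_disp,
            "mass_mg_full": mass,
            "content_pct": content,
        }
        lines.append(
            f"  signal {label}: A_F={area:.2f}  m_F={mass_disp:.2f} mg  "
            f"content={content:.2f} %"
        )

    yld = round_percent(
        extraction_yield(
            fx.extraction["dichloromethane_extract_g"], fx.extraction["fresh_leaves_g"]
        )
    )
    mean_content = sum(s["content_pct"] for s in per_signal.values()) / len(per_signal)
    leaf = round_sigfig(material_content(yld, mean_content), 2)
    lines.append(f"  extraction yield: {yld:.2f} %  leaf content: {leaf} %")
    return QuantReport(
        header=_header(config, seed),
        purity_mode=purity_mode,
        extract_mass_mg=ex["extract_mass_mg"],
        per_signal=per_signal,
        extract_yield_pct=yld,
        leaf_content_pct=leaf,
        lines=lines,
    )


def run_validation_pipeline(
    fixtures: StudyFixtures | None = None,
    confidence: float = 0.99,
    signal: str = "H2",
    sn_points: list[tuple[float, float]] | None = None,
    seed: int | None = None,
) -> ValidationReport:
    """Accuracy, linearity and precision statistics for one quantitation
    signal of the calibration tables; LOD/LOQ when S:N data are supplied.

    Accuracy rows keep only self-consistent table rows: those whose printed
    relative error matches the error recomputed from the printed masses at
    2 decimals (the others were evidently pre-rounded upstream).
    """
    fx = fixtures or load_fixtures()
    points = fx.accuracy[signal]
    if len(points) < 3:
        raise InvalidParameterError("need >= 3 calibration points")
    printed = fx.accuracy_printed_re[signal]
    accuracy = []
    for pt, printed_re in zip(points, printed):
        re = relative_error(pt.calculated_mass, pt.weighted_mass)
        if round(re, 2) == round(printed_re, 2):
            accuracy.append((pt, re))
    lin = linearity_fit([(p.weighted_mass, p.calculated_mass) for p in points])
    prec = precision_report(fx.precision_replicates[signal], confidence)
    lod = loq = None
    if sn_points:
        lod, loq = lod_loq(
            sn_points,
            lod_threshold=fx.lod_loq["lod_sn_threshold"],
            loq_threshold=fx.lod_loq["loq_sn_threshold"],
        )
    return ValidationReport(
        accuracy=accuracy, linearity=lin, precision=prec, lod=lod, loq=loq
    )


def format_validation_report(
    report: ValidationReport, confidence: float = 0.99, seed: int | None = None
) -> str:
    """Human-readable rendering of a :class:`ValidationReport`."""
    cfg = {"confidence": confidence}
    lines = [
        f"qnmrquant v{__version__}  method validation  "
        f"(config {config_hash(cfg)}, seed {seed})",
        "accuracy (self-consistent rows):",
    ]
    for pt, re in report.accuracy:
        lines.append(
            f"  weighed {pt.weighted_mass:6.2f} mg  calculated "
            f"{pt.calculated_mass:6.2f} mg  RE {re:+.2f} %"
        )
    lin = report.linearity
    lines.append(
        f"linearity: slope {lin.slope:.4f}  intercept {lin.intercept:.4f}  "
        f"R^2 {lin.r_squared:.5f} (rounds to {round(lin.r_squared, 2):.2f})"
    )
    p = report.precision
    lines.append(
        f"precision: n={p.n}  mean {p.mean:.3f} mg  sd {p.sd:.4f} mg  "
        f"{100 * p.confidence:.0f}% CI half-width {p.ci_half_width:.4f} mg "
        f"({p.ci_relative:.2f} % of mean)"
    )
    if report.lod is not None:
        lines.append(f"LOD {report.lod:.3f} mg  LOQ {report.loq:.3f} mg")
    return "\n".join(lines)
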