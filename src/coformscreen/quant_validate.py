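"""Calibration, standard-addition quantitation and SANTE-style validation.

Quantitation follows the validated workflow for direct dilute-and-shoot
analysis of formulations: unweighted ordinary-least-squares calibration
(solvent or standard-addition), matrix effect as the relative slope
difference between matrix-matched and solvent curves (|ME| < 20% is
negligible), interday precision as %RSD of replicate responses, and an
operational LOQ — the lowest calibration level with S/N >= 10 and
back-calculated accuracy within 20% — scaled by the sample dilution
factor into formulation units (g/L for liquids, mg/g for solids).

Standard addition extrapolates the fitted line to the x-intercept:
the analyte concentration in the injected extract is intercept/slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "ValidationReport",
    "QuantResult",
    "fit_calibration",
    "standard_addition_quant",
    "matrix_effect",
    "interday_rsd",
    "estimate_loq",
    "quantify_sample",
    "build_validation_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted linear response model.

    ``kind`` is "solvent", "matrix-matched" or "standard-addition";
    levels are concentrations in μg/L, responses are peak areas.
    """

    levels: tuple
    responses: tuple
    slope: float
    intercept: float
    r_squared: float
    kind: str = "solvent"

    _KINDS = ("solvent", "matrix-matched", "standard-addition")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def predict(self, level: float) -> float:
        return self.slope * level + self.intercept

    def back_calculate(self, response: float) -> float:
        return (response - self.intercept) / self.slope


def fit_calibration(
    levels: Sequence[float], responses: Sequence[float], kind: str = "solvent"
) -> CalibrationCurve:
    """Unweighted OLS fit of response vs concentration level."""
    lv = np.asarray(levels, dtype=float)
    rp = np.asarray(responses, dtype=float)
    if lv.size != rp.size or lv.size < 2:
        raise ValueError("need >= 2 paired (level, response) points")
    if np.unique(lv).size < 2:
        raise ValueError("all calibration levels are identical")
    if lv.size == 2:
        logger.warning("two-point calibration: R^2 = 1 is degenerate")
    res = stats.linregress(lv, rp)
    r2 = float(res.rvalue ** 2)
    if res.slope < 0:
        logger.warning("negative calibration slope (%.3g): check responses", res.slope)
    return CalibrationCurve(
        levels=tuple(lv), responses=tuple(rp),
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=min(r2, 1.0), kind=kind)


def standard_addition_quant(curve: CalibrationCurve) -> float:
    """Analyte concentration in the injected extract: |x-intercept| = b/m."""
    if curve.kind != "standard-addition":
        raise ValueError("curve is not a standard-addition curve")
    if curve.slope <= 0:
        raise ValueError("standard addition requires a positive slope")
    return curve.intercept / curve.slope


def matrix_effect(matrix_slope: float, solvent_slope: float) -> float:
    """Matrix effect in %: (matrix slope / solvent slope - 1) x 100."""
    if solvent_slope == 0:
        raise ValueError("solvent slope must be non-zero")
    return (matrix_slope / solvent_slope - 1.0) * 100.0


def interday_rsd(replicate_responses: Sequence[float]) -> float:
    """Relative standard deviation (%) of replicate responses."""
    r = np.asarray(replicate_responses, dtype=float)
    if r.size < 3:
        raise ValueError("need >= 3 replicates")
    mean = r.mean()
    if mean == 0:
        raise ValueError("mean response is zero")
    return 100.0 * float(r.std(ddof=1)) / float(mean)


def estimate_loq(
    curve: CalibrationCurve,
    snr_per_level: Optional[Sequence[float]] = None,
    dilution_factor: float = 1.0,
    solid_mass_per_volume: Optional[float] = None,
    min_snr: float = 10.0,
    max_accuracy_error: float = 20.0,
) -> float:
    """Method LOQ in formulation units.

    The lowest calibration level whose S/N is >= ``min_snr`` (taken as
    passing when no S/N values are supplied) and whose back-calculated
    concentration is accurate within ``max_accuracy_error`` %, scaled by
    the dilution factor. Returned in g/L for liquids, or mg/g for solids
    when ``solid_mass_per_volume`` (g/mL of the initial dissolution) is
    given.
    """
    order = np.argsort(curve.levels)
    snrs = None if snr_per_level is None else np.asarray(snr_per_level, float)[order]
    for rank, idx in enumerate(order):
        level = curve.levels[idx]
        if level <= 0:
            continue
        if snrs is not None and snrs[rank] < min_snr:
            continue
        back = curve.back_calculate(curve.responses[idx])
        if abs(back - level) / level * 100.0 > max_accuracy_error:
            continue
        extract_ug_l = level * dilution_factor          # μg/L in the formulation
        if solid_mass_per_volume is not None:
            return extract_ug_l / (solid_mass_per_volume * 1000.0) * 1e-3  # mg/g
        return extract_ug_l * 1e-6                      # g/L
    raise ValueError("no calibration level satisfies the LOQ criteria")


@dataclass(frozen=True)
class QuantResult:
    """A quantified co-formulant concentration with propagated units."""

    extract_conc: float          # μg/L in the injected extract
    formulation_conc: Optional[float]
    units: str                   # "g/L", "ug/g" or "<LOQ"
    below_loq: bool = False
    extrapolated: bool = False


def quantify_sample(
    response: float,
    curve: CalibrationCurve,
    dilution_factor: float = 1.0,
    solid_mass_per_volume: Optional[float] = None,
    loq_extract: Optional[float] = None,
) -> QuantResult:
    """Back-calculate a sample response to a formulation concentration.

    ``loq_extract`` (μg/L, extract scale) marks results as "<LOQ".
    Responses outside 0.5x-1.5x of the calibrated response range are
    flagged as extrapolated rather than rejected.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero")
    extract = curve.back_calculate(response)
    rmin, rmax = min(curve.responses), max(curve.responses)
    extrapolated = not (0.5 * rmin <= response <= 1.5 * rmax)
    if extrapolated:
        logger.warning("response %.3g outside 0.5x-1.5x of the calibrated range", response)
    if loq_extract is not None and extract < loq_extract:
        return QuantResult(extract_conc=extract, formulation_conc=None,
                           units="<LOQ", below_loq=True, extrapolated=extrapolated)
    scaled = extract * dilution_factor                   # μg/L in the formulation
    if solid_mass_per_volume is not None:
        conc = scaled / (solid_mass_per_volume * 1000.0)  # μg/g
        return QuantResult(extract, conc, "ug/g", extrapolated=extrapolated)
    return QuantResult(extract, scaled * 1e-6, "g/L", extrapolated=extrapolated)


@dataclass(frozen=True)
class ValidationReport:
    """SANTE-style validation summary for one analyte/formulation pair."""

    compound: str
    matrix_effect_pct: float
    interday_rsd_pct: float
    r_squared: float
    loq: float
    loq_units: str
    rt_shift: float
    pass_flags: Dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.pass_flags.values())


def build_validation_report(
    compound: str,
    solvent_curve: CalibrationCurve,
    matrix_curve: CalibrationCurve,
    replicate_responses: Sequence[float],
    rt_shift: float,
    dilution_factor: float = 1.0,
    solid_mass_per_volume: Optional[float] = None,
    snr_per_level: Optional[Sequence[float]] = None,
    me_max: float = 20.0,
    rsd_max: float = 20.0,
    r2_min: float = 0.99,
    rt_max: float = 0.1,
) -> ValidationReport:
    """Assemble the validation metrics and their pass/fail booleans."""
    me = matrix_effect(matrix_curve.slope, solvent_curve.slope)
    rsd = interday_rsd(replicate_responses)
    loq = estimate_loq(solvent_curve, snr_per_level, dilution_factor,
                       solid_mass_per_volume)
    flags = {
        "matrix_effect": abs(me) < me_max,
        "interday_rsd": rsd <= rsd_max,
        "linearity": solvent_curve.r_squared >= r2_min,
        "rt_stability": rt_shift < rt_max,
    }
    return ValidationReport(
        compound=compound, matrix_effect_pct=me, interday_rsd_pct=rsd,
        r_squared=solvent_curve.r_squared, loq=loq,
        loq_units="mg/g" if solid_mass_per_volume is not None else "g/L",
        rt_shift=rt_shift, pass_flags=flags)
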