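"""Regulatory and toxicological flagging of quantified co-formulants.

EU plant-protection regulation tolerates unacceptable (banned)
co-formulants only as unintentional impurities below 0.1% w/w. This
module converts quantified concentrations to % w/w (assuming density
1 g/mL for liquid formulations unless supplied — the assumption is
carried on the flag), tests banned compounds against that threshold,
and compares oral reference doses (RfD, mg/kg/day) between compounds
as fold ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence

from .quant_validate import QuantResult
from .suspect_screen import SuspectEntry

__all__ = [
    "BANNED_THRESHOLD_PCT",
    "RiskFlag",
    "percent_w_w",
    "flag_banned",
    "rfd_fold",
]

#: maximum % w/w of a banned co-formulant tolerated as an impurity
BANNED_THRESHOLD_PCT = 0.1


@dataclass(frozen=True)
class RiskFlag:
    """Risk assessment of one quantified compound."""

    compound: str
    concentration: float
    units: str
    percent_w_w: float
    banned_eu: bool
    banned_spain: bool
    exceeds_threshold: bool
    rfd: Optional[float] = None
    density_assumed: bool = False

    def __post_init__(self) -> None:
        expected = (self.percent_w_w >= BANNED_THRESHOLD_PCT
                    and (self.banned_eu or self.banned_spain))
        if self.exceeds_threshold != expected:
            raise ValueError("exceeds_threshold inconsistent with its definition")


def percent_w_w(concentration: float, units: str, density_g_ml: float = 1.0) -> float:
    """Convert a formulation concentration to % w/w.

    Supported units: "g/L" (divided by density in g/mL, i.e. g per 100 g),
    "ug/g", "mg/g" and "g/kg".
    """
    if units == "g/L":
        return concentration / (density_g_ml * 1000.0) * 100.0
    if units in ("ug/g", "µg/g"):
        return concentration * 1e-6 * 100.0
    if units == "mg/g":
        return concentration * 1e-3 * 100.0
    if units == "g/kg":
        return concentration * 1e-3 * 100.0
    raise ValueError(f"cannot convert units {units!r} to % w/w")


def flag_banned(
    quant_results: Dict[str, QuantResult],
    db: Sequence[SuspectEntry],
    density_g_ml: Optional[float] = None,
) -> List[RiskFlag]:
    """One risk flag per quantified banned compound.

    ``quant_results`` maps compound name to its :class:`QuantResult`.
    Liquid concentrations assume density 1 g/mL unless ``density_g_ml``
    is given; the flag records whether the assumption was used.
    """
    by_name = {e.name: e for e in db}
    flags: List[RiskFlag] = []
    for name, qr in quant_results.items():
        entry = by_name.get(name)
        if entry is None or not (entry.banned_eu or entry.banned_spain):
            continue
        if qr.below_loq or qr.formulation_conc is None:
            continue
        assumed = qr.units == "g/L" and density_g_ml is None
        pct = percent_w_w(qr.formulation_conc, qr.units,
                          density_g_ml if density_g_ml is not None else 1.0)
        flags.append(RiskFlag(
            compound=name,
            concentration=qr.formulation_conc,
            units=qr.units,
            percent_w_w=pct,
            banned_eu=entry.banned_eu,
            banned_spain=entry.banned_spain,
            exceeds_threshold=pct >= BANNED_THRESHOLD_PCT,
            rfd=entry.rfd,
            density_assumed=assumed))
    return flags


def rfd_fold(rfd_reference: float, rfd_other: float) -> tuple[int, float]:
    """How many times larger one oral RfD is than another.

    Returns (fold rounded half-up to an integer for reporting, exact
    unrounded ratio).
    """
    if rfd_reference <= 0 or rfd_other <= 0:
        raise ValueError("RfD values must be positive")
    exact = rfd_reference / rfd_other
    rounded = int(Decimal(repr(exact)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return rounded, exact
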