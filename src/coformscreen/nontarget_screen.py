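"""Unknown (non-target) analysis: feature filtering, homolog-series
detection and formula-based candidate proposal against a local table.

The filter chain mirrors the classic non-target workflow on untargeted
features: blank subtraction, a minimum peak area (1e6 counts by
default), and molecular-formula assignment over CHNOPS within 5 ppm —
features for which no formula can be generated are discarded.

Homolog-series detection targets polyethoxylate surfactants: within one
averaged apex spectrum, co-eluting ions spaced by the ethylene oxide
repeat unit (C2H4O, 44.02621 Da) form bell-shaped ladders that identify
the polymer family at a glance. The repeat unit is configurable (e.g.
CH2 = 14.01565 Da for alkyl homologs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chemmass import (
    DEFAULT_ELEMENT_BOUNDS,
    ElementalFormula,
    enumerate_formulas,
    monoisotopic_mass,
    parse_formula,
)
from .feature_extraction import (
    DEFAULT_PPM_TOL,
    DEFAULT_RT_TOL,
    Feature,
    detect_peaks,
    extract_eic,
    subtract_blank,
)
from .ms_io import MsRun
from .suspect_screen import averaged_apex_spectrum

__all__ = [
    "HomologSeries",
    "ETHOXYLATE_REPEAT_DA",
    "apply_unknown_filters",
    "detect_homolog_series",
    "load_candidate_table",
    "propose_candidates",
]

logger = logging.getLogger(__name__)

#: exact mass of the C2H4O ethylene oxide repeat unit, Da
ETHOXYLATE_REPEAT_DA = round(monoisotopic_mass(parse_formula("C2H4O")), 5)

DEFAULT_MIN_AREA = 1e6


@dataclass(frozen=True)
class HomologSeries:
    """A ladder of co-eluting ions spaced by one repeat-unit mass."""

    member_mz: Tuple[float, ...]
    repeat_unit: float
    apex_rt: float
    base_formula: Optional[ElementalFormula] = None

    def __post_init__(self) -> None:
        if len(self.member_mz) < 3:
            raise ValueError("a homolog series needs at least 3 members")
        diffs = np.diff(self.member_mz)
        tol = max(m for m in self.member_mz) * 20e-6 + 1e-3
        if np.any(diffs <= 0) or np.any(np.abs(diffs - self.repeat_unit) > tol):
            raise ValueError("member m/z must ascend in repeat-unit steps")

    @property
    def n_members(self) -> int:
        return len(self.member_mz)


def apply_unknown_filters(
    features: Sequence[Feature],
    blank_features: Sequence[Feature],
    element_bounds: Optional[Mapping[str, Tuple[int, int]]] = None,
    min_area: float = DEFAULT_MIN_AREA,
    tol_ppm: float = DEFAULT_PPM_TOL,
    adduct: str = "[M+H]+",
) -> List[Tuple[Feature, List[ElementalFormula]]]:
    """Blank-subtract, area-filter and formula-annotate untargeted features.

    Each surviving feature is annotated with its candidate molecular
    formulas from exhaustive CHNOPS enumeration within ``tol_ppm``;
    features with no candidate formula are dropped.
    """
    bounds = DEFAULT_ELEMENT_BOUNDS if element_bounds is None else element_bounds
    survivors = subtract_blank(features, blank_features, tol_ppm, DEFAULT_RT_TOL)
    n_blank = len(features) - len(survivors)
    out: List[Tuple[Feature, List[ElementalFormula]]] = []
    n_area = n_formula = 0
    for f in survivors:
        if f.area < min_area:
            n_area += 1
            continue
        candidates = enumerate_formulas(f.mz, adduct, tol_ppm, bounds)
        if not candidates:
            n_formula += 1
            continue
        out.append((f, candidates))
    logger.info(
        "unknown filters: %d in -> %d blank-matched, %d below area %.0g, "
        "%d without formula -> %d out",
        len(features), n_blank, n_area, min_area, n_formula, len(out))
    return out


def detect_homolog_series(
    run: MsRun,
    feature: Feature,
    repeat_unit: float = ETHOXYLATE_REPEAT_DA,
    tol_ppm: float = DEFAULT_PPM_TOL,
    min_members: int = 3,
    min_rel_intensity: float = 0.01,
    coelution_tol: float = 0.05,
) -> List[HomologSeries]:
    """Find repeat-unit ladders in the averaged apex spectrum of a feature.

    Starting from the feature's own m/z, the ladder is greedily extended
    up and down in ``repeat_unit`` steps: the next rung must hold a
    centroid within ``tol_ppm`` (ties broken toward the more intense
    centroid) whose own EIC apex co-elutes with the seed within
    ``coelution_tol`` minutes. Ladders shorter than ``min_members`` are
    discarded.
    """
    spec = averaged_apex_spectrum(run, feature)
    if spec.mz.size == 0:
        return []
    floor = float(spec.intensity.max()) * min_rel_intensity

    def rung_at(mz: float) -> Optional[float]:
        half = mz * tol_ppm * 1e-6
        lo = np.searchsorted(spec.mz, mz - half, "left")
        hi = np.searchsorted(spec.mz, mz + half, "right")
        if hi <= lo:
            return None
        seg = slice(lo, hi)
        best = int(np.argmax(spec.intensity[seg])) + lo
        if spec.intensity[best] < floor:
            return None
        return float(spec.mz[best])

    def coelutes(mz: float) -> bool:
        eic = extract_eic(run, mz, tol_ppm)
        peaks = detect_peaks(eic, min_height=max(floor, 1.0), min_snr=1.0)
        return any(abs(p.apex_rt - feature.apex_rt) <= coelution_tol for p in peaks)

    seed = rung_at(feature.mz)
    if seed is None:
        return []
    ladder = [seed]
    step = repeat_unit
    mz = seed + step
    while True:
        nxt = rung_at(mz)
        if nxt is None or not coelutes(nxt):
            break
        ladder.append(nxt)
        mz = nxt + step
    mz = seed - step
    while mz > 0:
        nxt = rung_at(mz)
        if nxt is None or not coelutes(nxt):
            break
        ladder.insert(0, nxt)
        mz = nxt - step
    if len(ladder) < min_members:
        return []
    return [HomologSeries(member_mz=tuple(ladder), repeat_unit=repeat_unit,
                          apex_rt=feature.apex_rt)]


def load_candidate_table(path) -> pd.DataFrame:
    """Read the local formula -> compound candidate table.

    Columns: formula, name, rank (smaller = more cited / more likely).
    Stands in for online compound libraries.
    """
    df = pd.read_csv(path)
    required = {"formula", "name", "rank"}
    if not required.issubset(df.columns):
        raise ValueError(f"candidate table must have columns {sorted(required)}")
    df["formula"] = df["formula"].map(lambda s: str(parse_formula(s)))
    return df


def propose_candidates(
    candidate_formulas: Sequence[ElementalFormula],
    candidate_table: pd.DataFrame,
) -> List[Tuple[str, str, int]]:
    """Named candidates whose formula matches an enumerated formula.

    Returns (name, formula, rank) tuples ordered by rank; an empty list
    means the feature stays unnamed and is ruled out downstream.
    """
    wanted = {str(f) for f in candidate_formulas}
    hits = candidate_table[candidate_table["formula"].isin(wanted)]
    hits = hits.sort_values(["rank", "name"], kind="stable")
    return [(r["name"], r["formula"], int(r["rank"])) for _, r in hits.iterrows()]
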