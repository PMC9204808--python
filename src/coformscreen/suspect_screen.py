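"""Suspect screening: characteristic-ion search, isotope-pattern and ddMS2
fragment verification, confidence-level assignment, standard confirmation.

The screen walks a suspect database (name, formula, allowed adducts,
theoretical fragments, regulatory flags, RfD) against a sample run:

1. extract an EIC at each theoretical adduct m/z (5 ppm) and detect peaks;
2. drop candidates that also appear in the blank or elute with a poor
   Gaussian shape;
3. verify the predicted isotopologue pattern in the averaged apex
   spectrum (30% relative intensity tolerance) — a missing Cl/S/Br M+2
   refutes the candidate outright;
4. match ddMS2 fragment ions against the entry's theoretical fragment
   list; at least two matched fragments are required for a putative
   identification (SANTE guidance);
5. assign a confidence level on the 1-5 scale used for HRMS
   identifications (1 = confirmed by reference standard, 5 = exact mass
   only).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chemmass import (
    ElementalFormula,
    TheoreticalFragment,
    adduct_mz,
    parse_formula,
    ppm_error,
    simulate_isotope_pattern,
)
from .feature_extraction import (
    DEFAULT_PPM_TOL,
    DEFAULT_RT_TOL,
    Feature,
    detect_peaks,
    extract_eic,
)
from .ms_io import CentroidSpectrum, MsRun, ms2_events_near

__all__ = [
    "SuspectEntry",
    "IdentificationRecord",
    "load_suspect_db",
    "averaged_apex_spectrum",
    "screen_suspects",
    "verify_isotope_pattern",
    "match_fragments",
    "assign_level",
    "confirm_with_standard",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

#: elements whose characteristic M+2 isotopologue refutes a match when absent
_M2_ELEMENTS = ("Cl", "Br", "S")


@dataclass(frozen=True)
class SuspectEntry:
    """One suspect-database compound."""

    name: str
    formula: ElementalFormula
    adducts: Tuple[str, ...] = ("[M+H]+",)
    fragments: Tuple[TheoreticalFragment, ...] = ()
    banned_eu: bool = False
    banned_spain: bool = False
    rfd: Optional[float] = None    # oral reference dose, mg/kg/day

    def __post_init__(self) -> None:
        if not self.adducts:
            raise ValueError(f"{self.name}: at least one allowed adduct required")


@dataclass(frozen=True)
class IdentificationRecord:
    """A suspect candidate with its accumulated evidence."""

    entry: SuspectEntry
    adduct: str
    feature: Feature
    mass_error_ppm: float
    level: int = 5
    isotope_verified: Optional[bool] = None    # None = not yet checked
    fragments_matched: int = 0
    fragment_errors_ppm: Tuple[float, ...] = ()
    ms2_available: Optional[bool] = None
    rt_standard_delta: Optional[float] = None
    rejected: bool = False
    reject_reason: str = ""

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3, 4, 5):
            raise ValueError("confidence level must be 1-5")
        if self.level == 1 and not (
            self.rt_standard_delta is not None and self.rt_standard_delta < DEFAULT_RT_TOL
        ):
            raise ValueError("level 1 requires a standard RT delta below 0.1 min")

    @property
    def theoretical_mz(self) -> float:
        return adduct_mz(self.entry.formula, self.adduct)


# ---------------------------------------------------------------------------
# Database I/O
# ---------------------------------------------------------------------------


def load_suspect_db(path) -> List[SuspectEntry]:
    """Read a suspect database CSV.

    Columns: name, formula, adducts (;-separated), fragment_formulas
    (;-separated), banned_eu, banned_spain, rfd (blank if unknown).
    """
    entries: List[SuspectEntry] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            frags = tuple(
                TheoreticalFragment.from_formula(tok.strip())
                for tok in (row.get("fragment_formulas") or "").split(";")
                if tok.strip()
            )
            adducts = tuple(
                tok.strip() for tok in (row.get("adducts") or "[M+H]+").split(";")
                if tok.strip()
            )
            rfd_raw = (row.get("rfd") or "").strip()
            entries.append(SuspectEntry(
                name=row["name"].strip(),
                formula=parse_formula(row["formula"]),
                adducts=adducts,
                fragments=frags,
                banned_eu=(row.get("banned_eu") or "").strip().lower() in ("1", "true", "yes"),
                banned_spain=(row.get("banned_spain") or "").strip().lower() in ("1", "true", "yes"),
                rfd=float(rfd_raw) if rfd_raw else None,
            ))
    if not entries:
        raise ValueError(f"suspect database {path} is empty")
    return entries


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


def averaged_apex_spectrum(
    run: MsRun, feature: Feature, n_scans: int = 3, merge_da: float = 0.01
) -> CentroidSpectrum:
    """Average the ``n_scans`` MS1 scans nearest the feature apex.

    Centroids within ``merge_da`` are merged (intensity-weighted m/z);
    intensities are divided by the number of averaged scans.
    """
    ms1 = run.ms1_spectra()
    if not ms1:
        raise ValueError("run has no MS1 scans")
    order = sorted(range(len(ms1)), key=lambda i: abs(ms1[i].rt - feature.apex_rt))
    chosen = sorted(order[:n_scans])
    allmz = np.concatenate([ms1[i].mz for i in chosen])
    allin = np.concatenate([ms1[i].intensity for i in chosen])
    if allmz.size == 0:
        raise ValueError("apex scans contain no centroids")
    srt = np.argsort(allmz)
    allmz, allin = allmz[srt], allin[srt]
    out_mz: List[float] = []
    out_in: List[float] = []
    for m, i in zip(allmz, allin):
        if out_mz and m - out_mz[-1] <= merge_da:
            tot = out_in[-1] + i
            out_mz[-1] = (out_mz[-1] * out_in[-1] + m * i) / tot
            out_in[-1] = tot
        else:
            out_mz.append(float(m))
            out_in.append(float(i))
    rt = ms1[min(chosen, key=lambda i: abs(ms1[i].rt - feature.apex_rt))].rt
    return CentroidSpectrum(rt=rt, mz=np.array(out_mz),
                            intensity=np.array(out_in) / len(chosen), ms_level=1)


def screen_suspects(
    run: MsRun,
    blank: Optional[MsRun],
    db: Sequence[SuspectEntry],
    tol_ppm: float = DEFAULT_PPM_TOL,
    min_shape: float = 0.8,
    min_height: float = 1000.0,
    min_snr: float = 3.0,
) -> List[IdentificationRecord]:
    """Search every suspect x allowed adduct by its characteristic ion.

    Emits level-5 records (exact mass only) for features that pass the
    height/S/N thresholds, show an acceptable peak shape and are not
    present in the blank. Evidence upgrades happen downstream.
    """
    if not db:
        raise ValueError("suspect database is empty")
    records: List[IdentificationRecord] = []
    for entry in db:
        for adduct in entry.adducts:
            theo = adduct_mz(entry.formula, adduct)
            eic = extract_eic(run, theo, tol_ppm)
            peaks = detect_peaks(eic, min_height, min_snr, run_id=run.run_id)
            if not peaks:
                continue
            blank_peaks: List[Feature] = []
            if blank is not None:
                blank_peaks = detect_peaks(
                    extract_eic(blank, theo, tol_ppm), min_height, min_snr,
                    run_id=blank.run_id)
            for f in peaks:
                if f.shape < min_shape:
                    logger.debug("%s %s at %.2f min: shape %.2f below %.2f",
                                 entry.name, adduct, f.apex_rt, f.shape, min_shape)
                    continue
                if any(abs(f.apex_rt - b.apex_rt) <= DEFAULT_RT_TOL for b in blank_peaks):
                    logger.debug("%s %s: present in blank, dropped", entry.name, adduct)
                    continue
                err = ppm_error(f.mz, theo)
                if abs(err) > tol_ppm:
                    continue
                records.append(IdentificationRecord(
                    entry=entry, adduct=adduct, feature=f, mass_error_ppm=err))
    return records


def verify_isotope_pattern(
    run: MsRun,
    record: IdentificationRecord,
    intensity_tol: float = 30.0,
    tol_ppm: float = DEFAULT_PPM_TOL,
    min_rel: float = 5.0,
) -> IdentificationRecord:
    """Compare the averaged apex spectrum with the predicted isotope pattern.

    Verified iff every predicted isotopologue at >= ``min_rel`` % relative
    abundance is present within ``tol_ppm`` and its relative abundance is
    within ±``intensity_tol`` % (relative) of the prediction. A predicted
    Cl/S/Br M+2 that is absent refutes the record.
    """
    pattern = simulate_isotope_pattern(record.entry.formula, record.adduct,
                                       min_rel=min_rel)
    spec = averaged_apex_spectrum(run, record.feature)
    base_pred_mz = pattern.base_mz
    # locate the observed base peak
    obs_base = _nearest_intensity(spec, base_pred_mz, tol_ppm)
    if obs_base == 0:
        return replace(record, isotope_verified=False, rejected=True,
                       reject_reason="base isotopologue not found at apex")
    ok = True
    has_m2_elements = any(record.entry.formula[el] for el in _M2_ELEMENTS)
    for pmz, prel in pattern.peaks:
        obs = _nearest_intensity(spec, pmz, tol_ppm)
        if obs == 0:
            ok = False
            continue
        obs_rel = 100.0 * obs / obs_base
        if abs(obs_rel - prel) > intensity_tol / 100.0 * prel:
            ok = False
    if not ok and has_m2_elements:
        # check specifically whether the diagnostic M+2 is missing
        m2 = [p for p in pattern.peaks if p[0] - base_pred_mz > 1.5]
        if m2 and all(_nearest_intensity(spec, pmz, tol_ppm) == 0 for pmz, _ in m2):
            return replace(record, isotope_verified=False, rejected=True,
                           reject_reason="predicted Cl/S/Br M+2 absent")
    return replace(record, isotope_verified=ok)


def _nearest_intensity(spec: CentroidSpectrum, mz: float, tol_ppm: float) -> float:
    half = mz * tol_ppm * 1e-6
    lo = np.searchsorted(spec.mz, mz - half, side="left")
    hi = np.searchsorted(spec.mz, mz + half, side="right")
    if hi <= lo:
        return 0.0
    return float(spec.intensity[lo:hi].max())


def match_fragments(
    run: MsRun,
    record: IdentificationRecord,
    tol_ppm: float = DEFAULT_PPM_TOL,
    mz_tol: float = 2.5,
    rt_tol: float = 0.2,
) -> IdentificationRecord:
    """Count theoretical ddMS2 fragments found near the record's precursor.

    A record whose suspect carries fragments but matches none of them in
    available MS2 data is flagged rejected (structural-isomer rule-out);
    without any nearby MS2 event the record is marked "MS2 unavailable".
    """
    events = ms2_events_near(run, record.theoretical_mz, record.feature.apex_rt,
                             mz_tol, rt_tol)
    if not events:
        return replace(record, ms2_available=False)
    matched = 0
    errors: List[float] = []
    for frag in record.entry.fragments:
        best: Optional[float] = None
        for ev in events:
            half = frag.expected_mz * tol_ppm * 1e-6
            lo = np.searchsorted(ev.mz, frag.expected_mz - half, "left")
            hi = np.searchsorted(ev.mz, frag.expected_mz + half, "right")
            for m in ev.mz[lo:hi]:
                err = ppm_error(float(m), frag.expected_mz)
                if best is None or abs(err) < abs(best):
                    best = err
        if best is not None:
            matched += 1
            errors.append(best)
    rec = replace(record, ms2_available=True, fragments_matched=matched,
                  fragment_errors_ppm=tuple(errors))
    if record.entry.fragments and matched == 0:
        rec = replace(rec, rejected=True,
                      reject_reason="no theoretical ddMS2 fragment matched")
    return rec


def assign_level(record: IdentificationRecord) -> IdentificationRecord:
    """Map accumulated evidence to a 1-5 confidence level.

    5 = exact mass only; 4 = isotope-verified formula; 3 = >= 2 matched
    fragments; 2 = >= 2 fragments and isotope verified; 1 = confirmed by
    reference standard (RT delta < 0.1 min, fragment rule holds).
    Rejected records keep level 5 and the rejected flag.
    """
    if record.rejected:
        return replace(record, level=5)
    two_frags = record.fragments_matched >= 2
    iso = record.isotope_verified is True
    std = (record.rt_standard_delta is not None
           and record.rt_standard_delta < DEFAULT_RT_TOL)
    if std and two_frags:
        level = 1
    elif two_frags and iso:
        level = 2
    elif two_frags:
        level = 3
    elif iso:
        level = 4
    else:
        level = 5
    return replace(record, level=level)


def confirm_with_standard(
    record: IdentificationRecord,
    standard_run: MsRun,
    tol_ppm: float = DEFAULT_PPM_TOL,
    min_height: float = 1000.0,
    min_snr: float = 3.0,
) -> IdentificationRecord:
    """Compare the sample feature with an analytical-standard injection.

    Sets the RT delta against the most intense standard peak and upgrades
    to level 1 iff the delta is below 0.1 min and >= 2 fragments matched.
    """
    eic = extract_eic(standard_run, record.theoretical_mz, tol_ppm)
    peaks = detect_peaks(eic, min_height, min_snr, run_id=standard_run.run_id)
    if not peaks:
        raise ValueError(
            f"{record.entry.name}: analyte not detected in standard run "
            f"{standard_run.run_id}")
    std_peak = max(peaks, key=lambda f: f.height)
    delta = abs(record.feature.apex_rt - std_peak.apex_rt)
    rec = replace(record, rt_standard_delta=delta)
    return assign_level(rec)


def records_to_frame(records: Sequence[IdentificationRecord]) -> pd.DataFrame:
    """Flatten identification records to a report table."""
    rows = []
    for r in records:
        rows.append({
            "compound": r.entry.name,
            "formula": str(r.entry.formula),
            "adduct": r.adduct,
            "theoretical_mz": r.theoretical_mz,
            "observed_mz": r.feature.mz,
            "mass_error_ppm": r.mass_error_ppm,
            "apex_rt": r.feature.apex_rt,
            "area": r.feature.area,
            "snr": r.feature.snr,
            "shape": r.feature.shape,
            "isotope_verified": r.isotope_verified,
            "fragments_matched": r.fragments_matched,
            "ms2_available": r.ms2_available,
            "rt_standard_delta": r.rt_standard_delta,
            "level": r.level,
            "rejected": r.rejected,
            "reject_reason": r.reject_reason,
        })
    return pd.DataFrame(rows)
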