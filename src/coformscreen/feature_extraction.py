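"""EIC extraction, chromatographic peak detection and blank subtraction.

Peak detection follows the usual centroid-data recipe: local maxima with
boundaries at the surrounding minima, trapezoidal area, a robust
(MAD-based) signal-to-noise estimate on the off-peak segments of the
trace, and a Gaussian-fit shape score in [0, 1]. The untargeted stage
groups centroids into m/z traces (5 ppm gap tolerance, >= 5 consecutive
scans) before running the same detector per trace.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .ms_io import MsRun

__all__ = [
    "EIC",
    "Feature",
    "extract_eic",
    "detect_peaks",
    "shape_score",
    "detect_features",
    "subtract_blank",
]

logger = logging.getLogger(__name__)

#: default m/z tolerance (ppm) — the 5-ppm mass-accuracy match criterion
DEFAULT_PPM_TOL = 5.0
#: default retention-time match tolerance in minutes
DEFAULT_RT_TOL = 0.1


@dataclass
class EIC:
    """Extracted ion chromatogram: one intensity point per MS1 scan."""

    target_mz: float
    tol_ppm: float
    rt: np.ndarray
    intensity: np.ndarray
    #: intensity-weighted mean m/z of the matched centroids per scan (nan if none)
    mz: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.size > 1 and np.any(np.diff(self.rt) <= 0):
            raise ValueError("EIC retention times must be strictly increasing")
        if self.mz is not None:
            self.mz = np.asarray(self.mz, dtype=float)


@dataclass(frozen=True)
class Feature:
    """A detected chromatographic peak of one m/z trace."""

    mz: float                 # intensity-weighted mean m/z across the peak
    apex_rt: float
    area: float               # counts x min
    height: float
    snr: float
    shape: float              # Gaussian-fit shape score in [0, 1]
    run_id: str = ""
    rt_start: float = float("nan")
    rt_end: float = float("nan")

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("feature area must be > 0")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if not (0.0 <= self.shape <= 1.0):
            raise ValueError("shape score must lie in [0, 1]")


def extract_eic(run: MsRun, mz: float, tol_ppm: float = DEFAULT_PPM_TOL) -> EIC:
    """Sum centroid intensities within +/- tol ppm of ``mz`` per MS1 scan."""
    if tol_ppm <= 0:
        raise ValueError("tolerance must be > 0")
    half = mz * tol_ppm * 1e-6
    rts, ints, mzs = [], [], []
    any_in_range = False
    for s in run.ms1_spectra():
        lo = np.searchsorted(s.mz, mz - half, side="left")
        hi = np.searchsorted(s.mz, mz + half, side="right")
        if s.mz.size and s.mz[0] <= mz <= s.mz[-1]:
            any_in_range = True
        tot = float(s.intensity[lo:hi].sum())
        rts.append(s.rt)
        ints.append(tot)
        mzs.append(float(np.average(s.mz[lo:hi], weights=s.intensity[lo:hi]))
                   if tot > 0 else np.nan)
    if rts and not any_in_range and all(i == 0 for i in ints):
        logger.warning("m/z %.5f outside the measured range of run %s", mz, run.run_id)
    return EIC(target_mz=mz, tol_ppm=tol_ppm,
               rt=np.array(rts), intensity=np.array(ints), mz=np.array(mzs))


def _peak_bounds(y: np.ndarray, apex: int) -> Tuple[int, int]:
    """Walk down from the apex to the surrounding minima (or zero signal)."""
    left = apex
    while left > 0 and y[left - 1] < y[left] and y[left - 1] > 0:
        left -= 1
    right = apex
    while right < y.size - 1 and y[right + 1] < y[right] and y[right + 1] > 0:
        right += 1
    return left, right


def _mad_noise(y: np.ndarray) -> float:
    """Robust noise scale: 1.4826 x median absolute deviation."""
    if y.size == 0:
        return 0.0
    med = np.median(y)
    return 1.4826 * float(np.median(np.abs(y - med)))


def shape_score(eic: EIC, lo: int, hi: int) -> float:
    """Coefficient of determination of a Gaussian fit over points lo..hi.

    Clamped to [0, 1]; spans shorter than 4 points score 0.
    """
    x = eic.rt[lo:hi + 1]
    y = eic.intensity[lo:hi + 1]
    if x.size < 4:
        logger.warning("peak span of %d points is too short for a shape fit", x.size)
        return 0.0

    def gauss(t, a, mu, sigma):
        return a * np.exp(-0.5 * ((t - mu) / sigma) ** 2)

    apex = int(np.argmax(y))
    p0 = (float(y[apex]), float(x[apex]), max((x[-1] - x[0]) / 4.0, 1e-4))
    try:
        popt, _ = curve_fit(gauss, x, y, p0=p0, maxfev=2000)
    except RuntimeError:
        return 0.0
    resid = y - gauss(x, *popt)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return float(min(1.0, max(0.0, 1.0 - ss_res / ss_tot)))


def detect_peaks(
    eic: EIC,
    min_height: float = 1000.0,
    min_snr: float = 3.0,
    run_id: str = "",
) -> List[Feature]:
    """Local-maximum peaks of an EIC passing height and S/N thresholds.

    S/N = apex height / MAD-based noise of the off-peak part of the trace;
    a noiseless trace (zero MAD) gives infinite S/N.
    """
    if min_height <= 0 or min_snr <= 0:
        raise ValueError("thresholds must be > 0")
    y = eic.intensity
    x = eic.rt
    if y.size == 0 or y.max() <= 0:
        return []

    # candidate apexes: strict local maxima (plateau-tolerant) above threshold
    candidates = []
    for i in range(y.size):
        if y[i] < min_height:
            continue
        left_ok = i == 0 or y[i - 1] < y[i]
        j = i
        while j < y.size - 1 and y[j + 1] == y[i]:
            j += 1
        right_ok = j == y.size - 1 or y[j + 1] < y[i]
        if left_ok and right_ok:
            candidates.append(i)

    features: List[Feature] = []
    spans = []
    for apex in candidates:
        lo, hi = _peak_bounds(y, apex)
        if hi - lo + 1 < 2:
            continue
        spans.append((apex, lo, hi))

    off_peak = np.ones(y.size, dtype=bool)
    for _, lo, hi in spans:
        off_peak[lo:hi + 1] = False
    # when every off-peak point is identical (e.g. an all-zero clipped
    # baseline between dense bumps) fall back to the whole-trace MAD
    noise = _mad_noise(y[off_peak]) or _mad_noise(y)

    for apex, lo, hi in spans:
        height = float(y[apex])
        snr = math.inf if noise == 0 else height / noise
        if snr < min_snr:
            continue
        area = float(np.trapezoid(y[lo:hi + 1], x[lo:hi + 1]))
        if area <= 0:
            continue
        if eic.mz is not None:
            seg_mz = eic.mz[lo:hi + 1]
            seg_in = y[lo:hi + 1]
            ok = ~np.isnan(seg_mz) & (seg_in > 0)
            mz = float(np.average(seg_mz[ok], weights=seg_in[ok])) if ok.any() else eic.target_mz
        else:
            mz = eic.target_mz
        features.append(Feature(
            mz=mz, apex_rt=float(x[apex]), area=area, height=height,
            snr=snr, shape=shape_score(eic, lo, hi), run_id=run_id,
            rt_start=float(x[lo]), rt_end=float(x[hi])))
    features.sort(key=lambda f: f.apex_rt)
    return features


def _trace_groups(run: MsRun, gap_ppm: float, min_scans: int):
    """Group MS1 centroids into m/z traces by a ppm gap criterion."""
    ms1 = run.ms1_spectra()
    all_mz, all_in, all_scan = [], [], []
    for si, s in enumerate(ms1):
        all_mz.append(s.mz)
        all_in.append(s.intensity)
        all_scan.append(np.full(s.mz.size, si))
    if not all_mz or sum(a.size for a in all_mz) == 0:
        return ms1, []
    mz = np.concatenate(all_mz)
    inten = np.concatenate(all_in)
    scan = np.concatenate(all_scan)
    order = np.argsort(mz)
    mz, inten, scan = mz[order], inten[order], scan[order]

    groups = []
    start = 0
    for i in range(1, mz.size + 1):
        if i == mz.size or (mz[i] - mz[i - 1]) / mz[i - 1] * 1e6 > gap_ppm:
            sl = slice(start, i)
            scans = np.unique(scan[sl])
            # require a run of >= min_scans consecutive scan indices
            if scans.size >= min_scans:
                breaks = np.where(np.diff(scans) > 1)[0]
                run_lens = np.diff(np.concatenate(([-1], breaks, [scans.size - 1])))
                if run_lens.max() >= min_scans:
                    groups.append(sl)
            start = i
    return ms1, [(mz[g], inten[g], scan[g]) for g in groups]


def detect_features(
    run: MsRun,
    min_height: float = 1000.0,
    min_snr: float = 3.0,
    gap_ppm: float = DEFAULT_PPM_TOL,
    min_scans: int = 5,
) -> List[Feature]:
    """Untargeted feature finding over all MS1 centroids of a run.

    Centroids are grouped into m/z traces (sorted-m/z gaps above
    ``gap_ppm`` split traces; traces must cover >= ``min_scans``
    consecutive scans), each trace is turned into an EIC and passed to
    :func:`detect_peaks`, and near-duplicate features (within 5 ppm and
    0.1 min) are collapsed keeping the larger area.
    """
    ms1, groups = _trace_groups(run, gap_ppm, min_scans)
    rts = np.array([s.rt for s in ms1])
    features: List[Feature] = []
    for gmz, gin, gscan in groups:
        inten = np.zeros(rts.size)
        wmz = np.zeros(rts.size)
        np.add.at(inten, gscan, gin)
        np.add.at(wmz, gscan, gin * gmz)
        with np.errstate(invalid="ignore"):
            mz_per_scan = np.where(inten > 0, wmz / np.maximum(inten, 1e-300), np.nan)
        center = float(np.average(gmz, weights=gin))
        eic = EIC(target_mz=center, tol_ppm=gap_ppm, rt=rts,
                  intensity=inten, mz=mz_per_scan)
        features.extend(detect_peaks(eic, min_height, min_snr, run_id=run.run_id))

    # deduplicate: same ion found through overlapping traces
    features.sort(key=lambda f: -f.area)
    kept: List[Feature] = []
    for f in features:
        dup = any(abs(f.mz - k.mz) / k.mz * 1e6 <= DEFAULT_PPM_TOL
                  and abs(f.apex_rt - k.apex_rt) <= DEFAULT_RT_TOL
                  for k in kept)
        if not dup:
            kept.append(f)
    kept.sort(key=lambda f: (f.mz, f.apex_rt))
    return kept


def subtract_blank(
    features: Sequence[Feature],
    blank_features: Sequence[Feature],
    mz_tol_ppm: float = DEFAULT_PPM_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> List[Feature]:
    """Drop every feature that matches a blank feature in both m/z and rt."""
    if mz_tol_ppm <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be > 0")
    out = []
    for f in features:
        hit = any(abs(f.mz - b.mz) / b.mz * 1e6 <= mz_tol_ppm
                  and abs(f.apex_rt - b.apex_rt) <= rt_tol
                  for b in blank_features)
        if not hit:
            out.append(f)
    return out
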