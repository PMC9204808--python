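"""Synthetic LC-HRMS run generator with known ground truth.

Emulates a 30-min reversed-phase run on a Q-Orbitrap: full-scan MS1 over
m/z 50-750 on a fixed cycle, Gaussian chromatographic elution of spiked
compounds (including their isotopologues and, for polyethoxylate
surfactants, whole homolog ladders within one peak), ppm-scale mass
jitter, random noise centroids, and top-N data-dependent MS2 triggering
with dynamic exclusion. Every planted ion is reported in a ground-truth
table so downstream feature detection, screening and quantitation can be
scored exactly.

What it does not emulate: electrospray ionization response factors,
peak tailing, detector saturation, or retention-time drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chemmass import (
    ADDUCTS,
    ElementalFormula,
    IsotopePattern,
    TheoreticalFragment,
    adduct_mz,
    parse_formula,
    simulate_isotope_pattern,
)
from .ms_io import CentroidSpectrum, MsRun

__all__ = [
    "HomologSpec",
    "SpikeSpec",
    "SyntheticRunConfig",
    "generate_run",
    "generate_blank",
    "generate_calibration_series",
]

#: ethylene oxide repeat unit of alkyl ethoxylates
ETHOXYLATE_UNIT = parse_formula("C2H4O")


@dataclass(frozen=True)
class HomologSpec:
    """A polymer ladder attached to a spike: base formula + n repeat units.

    ``abundance_profile`` maps member n to relative abundance; the default
    is a discretized Gaussian over [n_min, n_max], reproducing the
    bell-shaped single-spectrum ladders of technical ethoxylate mixtures.
    """

    repeat_unit: ElementalFormula = ETHOXYLATE_UNIT
    n_min: int = 4
    n_max: int = 11
    abundance_profile: Optional[Dict[int, float]] = None

    def profile(self) -> Dict[int, float]:
        if self.abundance_profile is not None:
            return dict(self.abundance_profile)
        center = 0.5 * (self.n_min + self.n_max)
        width = max((self.n_max - self.n_min) / 4.0, 1.0)
        prof = {n: math.exp(-0.5 * ((n - center) / width) ** 2)
                for n in range(self.n_min, self.n_max + 1)}
        top = max(prof.values())
        return {n: v / top for n, v in prof.items()}


@dataclass(frozen=True)
class SpikeSpec:
    """One planted compound: chromatography, adducts, MS2 fragments.

    ``adducts`` maps adduct name to relative response (1.0 = full
    ``apex_intensity``). ``fragments`` lists (TheoreticalFragment,
    relative intensity) pairs emitted when ddMS2 fires on this compound.
    A ``homolog`` spec expands the spike into a co-eluting ladder.
    """

    name: str
    formula: ElementalFormula
    apex_rt: float
    apex_intensity: float
    peak_sigma: float = 0.05
    adducts: Dict[str, float] = field(default_factory=lambda: {"[M+H]+": 1.0})
    fragments: Tuple[Tuple[TheoreticalFragment, float], ...] = ()
    homolog: Optional[HomologSpec] = None

    def __post_init__(self) -> None:
        if self.peak_sigma <= 0:
            raise ValueError("peak sigma must be > 0")
        if self.apex_intensity <= 0:
            raise ValueError("apex intensity must be > 0")
        for a in self.adducts:
            if a not in ADDUCTS:
                raise ValueError(f"unknown adduct {a!r}")


@dataclass(frozen=True)
class SyntheticRunConfig:
    """Acquisition settings of the simulated instrument.

    Defaults follow a 30-min gradient method: MS1 every 2 s over m/z
    50-750, top-5 ddMS2 with 10-s dynamic exclusion. ``seed`` fixes all
    randomness.
    """

    run_length: float = 30.0          # minutes
    ms1_cycle: float = 2.0            # seconds
    mz_range: Tuple[float, float] = (50.0, 750.0)
    mass_jitter_ppm: float = 1.0      # sd of the multiplicative m/z error
    noise_rate: float = 20.0          # mean noise centroids per MS1 scan
    noise_intensity_mean: float = 300.0   # lognormal scale of noise counts
    noise_intensity_sigma: float = 1.0    # lognormal shape
    top_n: int = 5
    ms2_floor: float = 1e4            # minimum precursor intensity to trigger
    dynamic_exclusion: float = 10.0   # seconds
    isotope_min_rel: float = 0.5      # % relative; isotopologues below are dropped
    seed: int = 0

    def __post_init__(self) -> None:
        if self.run_length <= 0 or self.ms1_cycle <= 0:
            raise ValueError("run length and MS1 cycle must be > 0")
        if self.noise_rate < 0 or self.mass_jitter_ppm < 0:
            raise ValueError("rates must be >= 0")


@dataclass(frozen=True)
class _PlantedIon:
    compound: str
    adduct: str
    member_n: Optional[int]
    pattern: IsotopePattern       # theoretical isotopologue m/z + rel %
    apex_intensity: float         # of the monoisotopic peak
    fragments: Tuple[Tuple[TheoreticalFragment, float], ...]


def _expand_spikes(config: SyntheticRunConfig, spikes: Sequence[SpikeSpec]) -> List[Tuple[SpikeSpec, _PlantedIon]]:
    lo, hi = config.mz_range
    ions: List[Tuple[SpikeSpec, _PlantedIon]] = []
    for spike in spikes:
        if not (0 <= spike.apex_rt <= config.run_length):
            raise ValueError(f"{spike.name}: apex rt {spike.apex_rt} outside the run")
        members: List[Tuple[Optional[int], ElementalFormula, float]] = []
        if spike.homolog is None:
            members.append((None, spike.formula, 1.0))
        else:
            for n, rel in sorted(spike.homolog.profile().items()):
                members.append((n, spike.formula + n * spike.homolog.repeat_unit, rel))
        for member_n, formula, member_rel in members:
            for adduct, adduct_rel in spike.adducts.items():
                pattern = simulate_isotope_pattern(
                    formula, adduct, min_rel=config.isotope_min_rel)
                mono = pattern.peaks[0][0]
                if not (lo <= mono <= hi):
                    raise ValueError(
                        f"{spike.name}: {adduct} m/z {mono:.5f} outside the scan range")
                ions.append((spike, _PlantedIon(
                    compound=spike.name, adduct=adduct, member_n=member_n,
                    pattern=pattern,
                    apex_intensity=spike.apex_intensity * adduct_rel * member_rel,
                    fragments=spike.fragments)))
    return ions


def _jitter(rng: np.random.Generator, mz: np.ndarray, ppm_sd: float) -> np.ndarray:
    if ppm_sd == 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, ppm_sd * 1e-6, size=np.shape(mz)))


def _assemble_spectrum(mz: np.ndarray, inten: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Sort by m/z and sum intensities of coincident centroids."""
    order = np.argsort(mz)
    mz, inten = mz[order], inten[order]
    if mz.size:
        keep_mz: List[float] = []
        keep_in: List[float] = []
        for m, i in zip(mz, inten):
            if keep_mz and m - keep_mz[-1] <= 1e-9:
                keep_in[-1] += i
            else:
                keep_mz.append(m)
                keep_in.append(i)
        mz, inten = np.array(keep_mz), np.array(keep_in)
    return mz, inten


def generate_run(
    config: SyntheticRunConfig,
    spikes: Sequence[SpikeSpec],
    run_id: str = "synthetic",
    role: str = "sample",
    dilution_factor: float = 1.0,
) -> Tuple[MsRun, pd.DataFrame]:
    """Simulate one LC-HRMS injection.

    Returns the run plus a ground-truth table with one row per planted ion:
    compound, adduct, homolog member, theoretical monoisotopic m/z, apex rt,
    apex height and the analytic Gaussian area (counts x min).
    """
    rng = np.random.default_rng(config.seed)
    ions = _expand_spikes(config, spikes)
    cycle_min = config.ms1_cycle / 60.0
    n_scans = int(math.floor(config.run_length / cycle_min)) + 1
    scan_rts = np.arange(n_scans) * cycle_min
    lo, hi = config.mz_range

    last_fragmented: Dict[float, float] = {}   # precursor key -> rt of last MS2
    spectra: List[CentroidSpectrum] = []

    for rt in scan_rts:
        mz_list: List[float] = []
        in_list: List[float] = []
        origin: List[int] = []            # index into ions, -1 = noise
        for idx, (spike, ion) in enumerate(ions):
            g = math.exp(-0.5 * ((rt - spike.apex_rt) / spike.peak_sigma) ** 2)
            height = ion.apex_intensity * g
            if height < 1.0:
                continue
            for iso_i, (iso_mz, rel) in enumerate(ion.pattern.peaks):
                inten = height * rel / 100.0
                if inten < 1.0:
                    continue
                mz_list.append(iso_mz)
                in_list.append(inten)
                origin.append(idx if iso_i == 0 else -2)  # only mono triggers ddMS2
        n_noise = rng.poisson(config.noise_rate) if config.noise_rate > 0 else 0
        if n_noise:
            nmz = rng.uniform(lo, hi, n_noise)
            nin = rng.lognormal(math.log(config.noise_intensity_mean),
                                config.noise_intensity_sigma, n_noise)
            mz_list.extend(nmz)
            in_list.extend(np.maximum(nin, 1.0))
            origin.extend([-1] * n_noise)

        mz_arr = _jitter(rng, np.asarray(mz_list, dtype=float), config.mass_jitter_ppm)
        in_arr = np.asarray(in_list, dtype=float)
        origin_arr = np.asarray(origin, dtype=int)
        order = np.argsort(mz_arr)
        mz_arr, in_arr, origin_arr = mz_arr[order], in_arr[order], origin_arr[order]
        smz, sin = _assemble_spectrum(mz_arr, in_arr)
        if smz.size != mz_arr.size:      # coincident centroids merged: re-derive origins
            origin_arr = origin_arr[np.searchsorted(mz_arr, smz)]
        spectra.append(CentroidSpectrum(rt=rt, mz=smz, intensity=sin, ms_level=1))

        # top-N data-dependent MS2 with dynamic exclusion
        cand = [(i, smz[i], sin[i], origin_arr[i]) for i in range(smz.size)
                if sin[i] >= config.ms2_floor]
        cand.sort(key=lambda t: -t[2])
        fired = 0
        for _, pmz, pint, oidx in cand:
            if fired >= config.top_n:
                break
            key = round(pmz, 2)
            last = last_fragmented.get(key)
            if last is not None and (rt - last) * 60.0 < config.dynamic_exclusion:
                continue
            last_fragmented[key] = rt
            fired += 1
            ms2_rt = rt + cycle_min * fired / (config.top_n + 1)
            if oidx >= 0 and ions[oidx][1].fragments:
                frag_mz = np.array([f.expected_mz for f, _ in ions[oidx][1].fragments])
                frag_in = np.array([pint * rel for _, rel in ions[oidx][1].fragments])
            else:
                k = int(rng.integers(1, 4))
                frag_mz = rng.uniform(lo, min(pmz + 5.0, hi), k)
                frag_in = rng.lognormal(math.log(config.noise_intensity_mean),
                                        config.noise_intensity_sigma, k)
            frag_mz = _jitter(rng, frag_mz, config.mass_jitter_ppm)
            frag_mz, frag_in = _assemble_spectrum(frag_mz, np.maximum(frag_in, 1.0))
            spectra.append(CentroidSpectrum(
                rt=ms2_rt, mz=frag_mz, intensity=frag_in, ms_level=2,
                precursor_mz=float(pmz), isolation_half_width=2.5,
                collision_energy=30.0))

    spectra.sort(key=lambda s: s.rt)
    run = MsRun(run_id=run_id, spectra=spectra, role=role,
                dilution_factor=dilution_factor,
                metadata={"generator": "coformscreen.synthetic_data",
                          "seed": str(config.seed)})

    truth_rows = []
    for spike, ion in ions:
        truth_rows.append({
            "compound": ion.compound,
            "adduct": ion.adduct,
            "member_n": ion.member_n,
            "mz": ion.pattern.peaks[0][0],
            "apex_rt": spike.apex_rt,
            "apex_height": ion.apex_intensity,
            "true_area": ion.apex_intensity * spike.peak_sigma * math.sqrt(2 * math.pi),
        })
    truth = pd.DataFrame(truth_rows, columns=[
        "compound", "adduct", "member_n", "mz", "apex_rt", "apex_height", "true_area"])
    return run, truth


def generate_blank(
    config: SyntheticRunConfig,
    contaminants: Sequence[SpikeSpec] = (),
    run_id: str = "blank",
) -> MsRun:
    """A noise-only injection (optionally carrying contaminant spikes)."""
    run, _ = generate_run(config, list(contaminants), run_id=run_id, role="blank")
    return run


def generate_calibration_series(
    compound: str,
    levels: Sequence[float],
    response_per_unit: float,
    noise_cv: float = 0.0,
    baseline_conc: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a calibration (or standard-addition) response table.

    response = slope x (baseline + level) x (1 + delta), delta ~ N(0, cv).
    A non-zero ``baseline_conc`` models the analyte already present in the
    extract, as in standard addition. The true slope and baseline are
    carried in ``DataFrame.attrs`` for recovery tests.
    """
    levels = list(levels)
    if len(set(levels)) < 2:
        raise ValueError("need at least 2 distinct levels")
    if any(l < 0 for l in levels):
        raise ValueError("levels must be non-negative")
    rng = np.random.default_rng(seed)
    lv = np.asarray(levels, dtype=float)
    delta = rng.normal(0.0, noise_cv / 100.0, lv.size) if noise_cv > 0 else np.zeros(lv.size)
    resp = response_per_unit * (baseline_conc + lv) * (1.0 + delta)
    df = pd.DataFrame({"compound": compound, "level": lv, "response": resp})
    df.attrs["true_slope"] = response_per_unit
    df.attrs["true_baseline_conc"] = baseline_conc
    return df
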