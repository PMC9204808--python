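"""End-to-end orchestration of the screening and quantitation stages.

Each pipeline logs a per-stage funnel (records in / out of every filter)
so a screening narrative remains auditable, and is deterministic for
fixed inputs and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import feature_extraction as fx
from . import nontarget_screen as nts
from . import quant_validate as qv
from . import risk_screen as rs
from . import suspect_screen as ss
from .ms_io import MsRun, read_run

__all__ = [
    "PipelineConfig",
    "run_suspect_pipeline",
    "run_unknown_pipeline",
    "run_quant",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File paths, tolerances and filter thresholds for one analysis."""

    sample_paths: List[str] = field(default_factory=list)
    blank_path: Optional[str] = None
    database_path: Optional[str] = None
    candidate_table_path: Optional[str] = None

    ppm_tol: float = 5.0
    rt_tol: float = 0.1
    intensity_tol_pct: float = 30.0
    min_height: float = 1000.0
    min_snr: float = 3.0
    min_area: float = 1e6
    min_shape: float = 0.8
    repeat_unit: float = nts.ETHOXYLATE_REPEAT_DA
    min_series_members: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ppm_tol", "rt_tol", "intensity_tol_pct", "min_height", "min_snr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def require_files(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            paths = value if isinstance(value, list) else [value]
            for p in paths:
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p!r} does not exist")


def _load_runs(config: PipelineConfig) -> Tuple[List[MsRun], Optional[MsRun]]:
    samples = [read_run(p) for p in config.sample_paths]
    blank = read_run(config.blank_path, role="blank") if config.blank_path else None
    return samples, blank


def run_suspect_pipeline(
    config: PipelineConfig,
    runs: Optional[Sequence[MsRun]] = None,
    blank: Optional[MsRun] = None,
    db: Optional[Sequence[ss.SuspectEntry]] = None,
    standard_runs: Optional[Dict[str, MsRun]] = None,
) -> pd.DataFrame:
    """Characteristic-ion screen -> isotope check -> ddMS2 check -> level.

    Runs, blank and database may be passed in memory; otherwise they are
    read from the configured paths. ``standard_runs`` maps compound name
    to an analytical-standard injection for level-1 confirmation.
    """
    if runs is None:
        config.require_files("sample_paths")
        runs, blank = _load_runs(config)
    if db is None:
        config.require_files("database_path")
        db = ss.load_suspect_db(config.database_path)
    if not db:
        raise ValueError("suspect database is empty")

    frames = []
    for run in runs:
        records = ss.screen_suspects(
            run, blank, db, tol_ppm=config.ppm_tol, min_shape=config.min_shape,
            min_height=config.min_height, min_snr=config.min_snr)
        logger.info("%s: %d level-5 candidates after the characteristic-ion screen",
                    run.run_id, len(records))
        out = []
        for rec in records:
            rec = ss.verify_isotope_pattern(run, rec, config.intensity_tol_pct,
                                            config.ppm_tol)
            rec = ss.match_fragments(run, rec, config.ppm_tol)
            rec = ss.assign_level(rec)
            if standard_runs and rec.entry.name in standard_runs and not rec.rejected:
                rec = ss.confirm_with_standard(rec, standard_runs[rec.entry.name],
                                               config.ppm_tol, config.min_height,
                                               config.min_snr)
            out.append(rec)
        n_rej = sum(r.rejected for r in out)
        logger.info("%s: %d records (%d rejected by isotope/fragment evidence)",
                    run.run_id, len(out), n_rej)
        frame = ss.records_to_frame(out)
        if not frame.empty:
            frame.insert(0, "run_id", run.run_id)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_unknown_pipeline(
    config: PipelineConfig,
    runs: Optional[Sequence[MsRun]] = None,
    blank: Optional[MsRun] = None,
    candidate_table: Optional[pd.DataFrame] = None,
) -> Dict[str, pd.DataFrame]:
    """Untargeted features -> blank/area/formula filters -> homolog series
    -> named candidates. Returns {"features", "series", "candidates"}."""
    if runs is None:
        config.require_files("sample_paths")
        runs, blank = _load_runs(config)
    if candidate_table is None and config.candidate_table_path:
        candidate_table = nts.load_candidate_table(config.candidate_table_path)

    feat_rows, series_rows, cand_rows = [], [], []
    for run in runs:
        features = fx.detect_features(run, config.min_height, config.min_snr,
                                      config.ppm_tol)
        blank_features = (fx.detect_features(blank, config.min_height,
                                             config.min_snr, config.ppm_tol)
                          if blank is not None else [])
        logger.info("%s: %d untargeted features (%d in blank)",
                    run.run_id, len(features), len(blank_features))
        kept = nts.apply_unknown_filters(features, blank_features,
                                         min_area=config.min_area,
                                         tol_ppm=config.ppm_tol)
        logger.info("%s: %d features after unknown-analysis filters",
                    run.run_id, len(kept))
        for f, formulas in kept:
            feat_rows.append({
                "run_id": run.run_id, "mz": f.mz, "apex_rt": f.apex_rt,
                "area": f.area, "height": f.height, "snr": f.snr,
                "shape": f.shape,
                "formulas": ";".join(str(x) for x in formulas[:5]),
            })
            for series in nts.detect_homolog_series(
                    run, f, config.repeat_unit, config.ppm_tol,
                    config.min_series_members):
                series_rows.append({
                    "run_id": run.run_id, "apex_rt": series.apex_rt,
                    "repeat_unit": series.repeat_unit,
                    "n_members": series.n_members,
                    "member_mz": ";".join(f"{m:.5f}" for m in series.member_mz),
                })
            if candidate_table is not None:
                for name, formula, rank in nts.propose_candidates(formulas,
                                                                  candidate_table):
                    cand_rows.append({
                        "run_id": run.run_id, "mz": f.mz, "apex_rt": f.apex_rt,
                        "candidate": name, "formula": formula, "rank": rank,
                    })
    return {
        "features": pd.DataFrame(feat_rows),
        "series": pd.DataFrame(series_rows).drop_duplicates(
            subset=["run_id", "member_mz"]) if series_rows else pd.DataFrame(),
        "candidates": pd.DataFrame(cand_rows),
    }


def run_quant(
    config: PipelineConfig,
    response_table: pd.DataFrame,
    db: Optional[Sequence[ss.SuspectEntry]] = None,
    dilution_factor: float = 1.0,
    solid_mass_per_volume: Optional[float] = None,
    rt_shifts: Optional[Dict[str, float]] = None,
) -> Dict[str, object]:
    """Fit curves, validate, quantify samples and raise risk flags.

    ``response_table`` columns: compound, kind (solvent | matrix-matched |
    standard-addition | replicate | sample), level (μg/L; NaN for
    replicate/sample rows), response.
    """
    if db is None and config.database_path:
        db = ss.load_suspect_db(config.database_path)
    required = {"compound", "kind", "level", "response"}
    if not required.issubset(response_table.columns):
        raise ValueError(f"response table must have columns {sorted(required)}")

    quant: Dict[str, qv.QuantResult] = {}
    quant_rows, validations = [], []
    for compound, grp in response_table.groupby("compound", sort=True):
        solvent = grp[grp["kind"] == "solvent"]
        if solvent.empty:
            raise ValueError(f"{compound}: no solvent calibration rows")
        curve = qv.fit_calibration(solvent["level"], solvent["response"], "solvent")

        matrix = grp[grp["kind"] == "matrix-matched"]
        stdadd = grp[grp["kind"] == "standard-addition"]
        reps = grp[grp["kind"] == "replicate"]["response"]
        samples = grp[grp["kind"] == "sample"]["response"]

        if not matrix.empty and len(reps) >= 3:
            mcurve = qv.fit_calibration(matrix["level"], matrix["response"],
                                        "matrix-matched")
            validations.append(qv.build_validation_report(
                compound, curve, mcurve, reps,
                rt_shift=(rt_shifts or {}).get(compound, 0.0),
                dilution_factor=dilution_factor,
                solid_mass_per_volume=solid_mass_per_volume))

        if not stdadd.empty:
            sa_curve = qv.fit_calibration(stdadd["level"], stdadd["response"],
                                          "standard-addition")
            extract = qv.standard_addition_quant(sa_curve)
            result = qv.quantify_sample(curve.predict(extract), curve,
                                        dilution_factor, solid_mass_per_volume)
        elif len(samples):
            result = qv.quantify_sample(float(samples.iloc[0]), curve,
                                        dilution_factor, solid_mass_per_volume)
        else:
            continue
        quant[compound] = result
        quant_rows.append({
            "compound": compound, "extract_ug_L": result.extract_conc,
            "formulation_conc": result.formulation_conc, "units": result.units,
            "r_squared": curve.r_squared, "below_loq": result.below_loq,
        })
        logger.info("%s: %s %s (R^2 %.4f)", compound,
                    "<LOQ" if result.below_loq else f"{result.formulation_conc:.4g}",
                    result.units, curve.r_squared)

    flags = rs.flag_banned(quant, db) if db else []
    return {
        "quant": pd.DataFrame(quant_rows),
        "validation": validations,
        "risk_flags": flags,
    }
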