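"""Table I/O, validation and pipeline orchestration.

CSV schemas (headers required, UTF-8, '.' decimal separator):

* ``foods.csv``: food, roast_day, replicate, concentration_mg_per_kg
* ``assays.csv``: assay_id, food, roast_day, c_iv_mg_per_L, c_av_mg_per_L,
  v_iv_L, t_s_mg_per_kg, m_s_kg, dilution_ratio, teer_ok
* ``intake_survey.csv``: person_id, group, food, intake_kg_per_day
* ``populations.yaml``: population blocks (ir per food with median/min/max,
  bw, at, ef, ed, rfd)

Every output CSV starts with '#'-prefixed header comments recording the
tool version, the seed and SHA-256 checksums of the inputs, so identical
inputs and seed reproduce identical files.  RBA appears in CSVs as percent
(columns suffixed ``_percent``); internally it is always a fraction.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bioavailability import (
    BioavailabilityResult,
    TransportAssay,
    summarize_bioavailability,
)
from .exposure import (
    DEFAULT_POPULATIONS,
    FoodConcentrationRecord,
    exposure_parameters,
    hazard_index,
    ir_max,
    point_estimate,
)
from .fitting import FAMILIES, FittedDistribution, fit_mle, select_distribution
from .montecarlo import ScenarioSpec, SimulationConfig, simulate_hi, simulate_hq

logger = logging.getLogger("fluorisk")

__all__ = [
    "RunConfig",
    "ReportBundle",
    "ValidationError",
    "read_foods",
    "read_assays",
    "read_survey",
    "read_populations",
    "run_pipeline",
    "write_report",
]

FOODS_COLUMNS = ["food", "roast_day", "replicate", "concentration_mg_per_kg"]
ASSAY_COLUMNS = [
    "assay_id",
    "food",
    "roast_day",
    "c_iv_mg_per_L",
    "c_av_mg_per_L",
    "v_iv_L",
    "t_s_mg_per_kg",
    "m_s_kg",
    "dilution_ratio",
    "teer_ok",
]
SURVEY_COLUMNS = ["person_id", "group", "food", "intake_kg_per_day"]


class ValidationError(ValueError):
    """Input table failed schema or content validation."""


@dataclass(frozen=True)
class RunConfig:
    """Paths and knobs for one pipeline run."""

    foods_path: Path
    assays_path: Optional[Path] = None
    survey_path: Optional[Path] = None
    populations_path: Optional[Path] = None
    out_dir: Path = Path("results")
    seed: int = 0
    n_iter: int = 10_000
    truncate_negative: bool = False
    hq_target: float = 1.0


@dataclass
class ReportBundle:
    """All tables a pipeline run produces, before rounding/writing."""

    bioavailability: Optional[pd.DataFrame]
    risk_point: pd.DataFrame
    fits: Optional[pd.DataFrame]
    mc_risk: Optional[pd.DataFrame]
    irmax: pd.DataFrame
    shares: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    numeric = [c for c in required if c not in
               ("food", "group", "assay_id", "person_id", "dilution_ratio", "teer_ok")]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad:
            rows = [int(i) + 2 for i in bad[:5]]  # 1-based incl. header
            raise ValidationError(
                f"{path.name}: non-numeric values in column {col!r} at rows {rows}"
            )
        df[col] = coerced
    if df.empty:
        logger.warning("%s: file contains a header but no rows", path.name)
    return df


def read_foods(path: Path) -> list[FoodConcentrationRecord]:
    df = _read_csv(path, FOODS_COLUMNS)
    dup = df.duplicated(subset=["food", "roast_day", "replicate"])
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup][:5]]
        raise ValidationError(
            f"{Path(path).name}: duplicate (food, roast_day, replicate) keys at rows {rows}"
        )
    logger.info("read %d concentration records from %s", len(df), path)
    return [
        FoodConcentrationRecord(
            food=str(r.food),
            roast_day=int(r.roast_day),
            replicate=int(r.replicate),
            concentration=float(r.concentration_mg_per_kg),
        )
        for r in df.itertuples()
    ]


def read_assays(path: Path) -> list[TransportAssay]:
    df = _read_csv(path, ASSAY_COLUMNS)
    logger.info("read %d assay records from %s", len(df), path)
    return [
        TransportAssay(
            assay_id=str(r.assay_id),
            food=str(r.food),
            roast_day=int(r.roast_day),
            c_iv=float(r.c_iv_mg_per_L),
            c_av=float(r.c_av_mg_per_L),
            v_iv=float(r.v_iv_L),
            t_s=float(r.t_s_mg_per_kg),
            m_s=float(r.m_s_kg),
            dilution_ratio=str(r.dilution_ratio),
            teer_ok=bool(r.teer_ok),
        )
        for r in df.itertuples()
    ]


def read_survey(path: Path) -> pd.DataFrame:
    df = _read_csv(path, SURVEY_COLUMNS)
    logger.info("read %d survey records from %s", len(df), path)
    return df


def read_populations(path: Optional[Path]) -> dict:
    if path is None:
        return DEFAULT_POPULATIONS
    with open(path) as fh:
        populations = yaml.safe_load(fh)
    for group, block in populations.items():
        for key in ("ir", "bw", "at", "ef", "ed"):
            if key not in block:
                raise ValidationError(f"population {group!r} missing key {key!r}")
    return populations


def _checksum(path: Optional[Path]) -> str:
    if path is None or not Path(path).exists():
        return "-"
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _header_lines(config: RunConfig) -> list[str]:
    return [
        f"# fluorisk {__version__}",
        f"# seed: {config.seed}",
        f"# inputs: foods={_checksum(config.foods_path)} "
        f"assays={_checksum(config.assays_path)} "
        f"survey={_checksum(config.survey_path)}",
    ]


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(config)) + "\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute bioavailability -> point risk -> fits -> Monte Carlo -> IR_max.

    Assay and survey inputs are optional: without assays the
    bioavailability table (and RBA-corrected intake limits) are skipped;
    without a survey the Monte Carlo stage falls back to a point-estimate
    only report.
    """
    populations = read_populations(config.populations_path)
    records = read_foods(config.foods_path)
    if not records:
        raise ValidationError("foods table is empty")

    foods = sorted({r.food for r in records})
    days = sorted({r.roast_day for r in records})
    groups = sorted(populations)

    conc_df = pd.DataFrame(
        [(r.food, r.roast_day, r.concentration) for r in records],
        columns=["food", "roast_day", "c"],
    )
    stage_stats = (
        conc_df.groupby(["food", "roast_day"])["c"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .fillna({"std": 0.0})
    )

    # --- bioavailability -------------------------------------------------
    bio_df = None
    rba_by_key: dict[tuple[str, int], float] = {}
    if config.assays_path is not None:
        assays = read_assays(config.assays_path)
        results = summarize_bioavailability(assays, records)
        bio_df = pd.DataFrame(
            [
                {
                    "food": b.food,
                    "roast_day": b.roast_day,
                    "rba_percent": b.rba * 100.0,
                    "absorbed_mg_per_kg": b.absorbed_mg_per_kg,
                    "n_assays": b.n_assays,
                }
                for b in results
            ]
        )
        rba_by_key = {(b.food, b.roast_day): b.rba for b in results}
    else:
        logger.info("no assays provided; bioavailability stage skipped")

    # --- deterministic point risk ----------------------------------------
    point_rows = []
    estimates_by_stage: dict[tuple[str, int], list] = {}
    for row in stage_stats.itertuples():
        for group in groups:
            p = exposure_parameters(group, row.food, populations=populations)
            est = point_estimate(row.food, int(row.roast_day), row.mean, p)
            estimates_by_stage.setdefault((group, int(row.roast_day)), []).append(est)
            point_rows.append(
                {
                    "food": row.food,
                    "roast_day": int(row.roast_day),
                    "group": group,
                    "c_mg_per_kg": row.mean,
                    "add": est.add,
                    "hq": est.hq,
                    "at_risk": est.at_risk,
                }
            )
    risk_point = pd.DataFrame(point_rows)

    share_rows = []
    for (group, day), ests in sorted(estimates_by_stage.items()):
        hi = hazard_index(ests)
        if hi <= 0:
            continue
        for est in ests:
            share_rows.append(
                {
                    "group": group,
                    "roast_day": day,
                    "food": est.food,
                    "weighting": "total",
                    "share": est.hq / hi,
                    "hi": hi,
                }
            )
        if rba_by_key:
            weighted = {
                e.food: e.hq * rba_by_key.get((e.food, day), 0.0) for e in ests
            }
            total = sum(weighted.values())
            if total > 0:
                for food, w in weighted.items():
                    share_rows.append(
                        {
                            "group": group,
                            "roast_day": day,
                            "food": food,
                            "weighting": "absorbed",
                            "share": w / total,
                            "hi": total,
                        }
                    )
    shares = pd.DataFrame(share_rows)

    # --- intake distribution fits ----------------------------------------
    fits_df = None
    best_fit: dict[tuple[str, str], FittedDistribution] = {}
    if config.survey_path is not None:
        survey = read_survey(config.survey_path)
        fit_rows = []
        for (group, food), sub in survey.groupby(["group", "food"]):
            ranked = select_distribution(
                sub["intake_kg_per_day"].to_numpy(), FAMILIES
            )
            best_fit[(str(group), str(food))] = ranked[0]
            for rank, fit in enumerate(ranked, start=1):
                names = list(fit.params)
                fit_rows.append(
                    {
                        "group": group,
                        "food": food,
                        "family": fit.family,
                        "param1_name": names[0],
                        "param1": fit.params[names[0]],
                        "param2_name": names[1],
                        "param2": fit.params[names[1]],
                        "loglik": fit.loglik,
                        "ad_stat": fit.ad_stat,
                        "rank": rank,
                        "converged": fit.converged,
                    }
                )
        fits_df = pd.DataFrame(fit_rows)
    else:
        logger.info("no survey provided; distribution fitting and Monte Carlo skipped")

    # --- Monte Carlo -------------------------------------------------------
    mc_df = None
    if best_fit:
        sim = SimulationConfig(
            seed=config.seed,
            n_iter=config.n_iter,
            truncate_negative=config.truncate_negative,
        )
        mc_rows = []
        for group in groups:
            for day in days:
                scenarios = []
                for food in foods:
                    stage = stage_stats[
                        (stage_stats.food == food) & (stage_stats.roast_day == day)
                    ]
                    if stage.empty or (group, food) not in best_fit:
                        continue
                    c_dist = FittedDistribution(
                        family="normal",
                        params={
                            "loc": float(stage["mean"].iloc[0]),
                            "scale": float(stage["std"].iloc[0]),
                        },
                        n=int(stage["count"].iloc[0]),
                        loglik=float("nan"),
                        ad_stat=float("nan"),
                        converged=True,
                    )
                    p = exposure_parameters(group, food, populations=populations)
                    scenarios.append(
                        ScenarioSpec(
                            food=food,
                            roast_day=int(day),
                            group=group,
                            c_dist=c_dist,
                            ir_dist=best_fit[(group, food)],
                            params=p,
                        )
                    )
                if not scenarios:
                    continue
                summaries = [simulate_hq(s, sim) for s in scenarios]
                summaries.append(simulate_hi(scenarios, sim))
                for s in summaries:
                    mc_rows.append(
                        {
                            "food": s.food,
                            "roast_day": s.roast_day,
                            "group": s.group,
                            "mean": s.mean,
                            "p05": s.p05,
                            "p95": s.p95,
                            "prob_hq_gt_1": s.prob_hq_above_1,
                            "n_iter": s.n_iter,
                            "seed": s.seed,
                        }
                    )
        mc_df = pd.DataFrame(mc_rows)

    # --- maximum allowable intakes ----------------------------------------
    irmax_rows = []
    for row in stage_stats.itertuples():
        if row.mean <= 0:
            continue
        for group in groups:
            p = exposure_parameters(group, row.food, populations=populations)
            base = ir_max(row.mean, p, config.hq_target)
            rba = rba_by_key.get((row.food, int(row.roast_day)))
            irmax_rows.append(
                {
                    "food": row.food,
                    "roast_day": int(row.roast_day),
                    "group": group,
                    "ir_max_kg_per_day": base,
                    "ir_max_rba_kg_per_day": (
                        ir_max(row.mean, p, config.hq_target, rba=rba)
                        if rba
                        else float("nan")
                    ),
                    "rba_percent_used": rba * 100.0 if rba else float("nan"),
                }
            )
    irmax_df = pd.DataFrame(irmax_rows)

    return ReportBundle(
        bioavailability=bio_df,
        risk_point=risk_point,
        fits=fits_df,
        mc_risk=mc_df,
        irmax=irmax_df,
        shares=shares,
        metadata={
            "seed": config.seed,
            "n_iter": config.n_iter,
            "version": __version__,
            "foods": foods,
            "days": days,
            "groups": groups,
        },
    )


def write_report(bundle: ReportBundle, config: RunConfig) -> list[Path]:
    """Write the bundle's tables (report rounding applied here only):
    HQ/HI and shares to 2 d.p. is a display choice in the text summary;
    CSVs keep full precision."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "bioavailability.csv": bundle.bioavailability,
        "risk_point.csv": bundle.risk_point,
        "fits.csv": bundle.fits,
        "mc_risk.csv": bundle.mc_risk,
        "irmax.csv": bundle.irmax,
        "contribution_shares.csv": bundle.shares,
    }
    for name, df in tables.items():
        if df is None:
            continue
        path = out / name
        _write_table(df, path, config)
        written.append(path)

    summary = out / "summary.txt"
    with open(summary, "w") as fh:
        fh.write(f"fluorisk {__version__} run summary (seed {config.seed})\n\n")
        if bundle.mc_risk is not None and not bundle.mc_risk.empty:
            fh.write("Monte Carlo HQ/HI (mean / 5th / 95th percentile):\n")
            for r in bundle.mc_risk.itertuples():
                fh.write(
                    f"  {r.food:>6s} day {r.roast_day:>2d} {r.group:<8s} "
                    f"{r.mean:8.2f} {r.p05:8.2f} {r.p95:8.2f}\n"
                )
        elif bundle.risk_point is not None:
            fh.write("Point-estimate HQ (no Monte Carlo stage run):\n")
            for r in bundle.risk_point.itertuples():
                fh.write(
                    f"  {r.food:>6s} day {r.roast_day:>2d} {r.group:<8s} "
                    f"HQ {r.hq:8.2f}\n"
                )
    written.append(summary)
    return written
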