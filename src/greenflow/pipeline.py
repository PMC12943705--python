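"""End-to-end campaign orchestration.

Runs the full quality-by-design workflow on the virtual rig (or on
ingested real records): generate the screening design, convert conditions
to operating parameters, execute the campaign, fit and reduce the yield
model, map the design-space risk, select the green optimum, account its
emissions and run the sensitivity analysis. Every stage's inputs and
outputs are persisted as plain CSV/JSON artifacts, the whole run is a pure
function of (config, seed), and a timestamped log records each stage with
the SHA-256 of what it wrote.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import doe, emissions, rig, risk, rsm, sensitivity
from .config import CampaignConfig, ProcessConditions
from .flow import check_mass_balance

__all__ = ["CampaignReport", "PipelineError", "run_full_pipeline", "ingest_external_records"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class CampaignReport:
    """Aggregated results of one campaign."""

    design: pd.DataFrame
    records: pd.DataFrame
    model: rsm.QuadraticModel
    riskmap_summary: dict
    selected_conditions: ProcessConditions
    selected_emission: float
    selected_risk: float
    sensitivity: pd.DataFrame
    scorecard: emissions.GreennessScorecard | None = None
    artifacts: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "design": self.design.to_dict(orient="records"),
            "records": self.records.to_dict(orient="records"),
            "model": self.model.to_dict(),
            "riskmap_summary": self.riskmap_summary,
            "selected_conditions": self.selected_conditions.model_dump(),
            "selected_emission_kg_per_kg": self.selected_emission,
            "selected_risk": self.selected_risk,
            "sensitivity": self.sensitivity.to_dict(orient="records"),
            "artifacts": self.artifacts,
        }
        if self.scorecard is not None:
            d["greenness"] = {"scores": list(self.scorecard.scores), "total": self.scorecard.total}
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_logger(out_dir: Path) -> logging.Logger:
    logger = logging.getLogger(f"greenflow.pipeline.{out_dir}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(out_dir / "pipeline.log", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s", datefmt="%Y-%m-%dT%H:%M:%S%z"))
    logger.addHandler(handler)
    logger.propagate = False
    return logger


def run_full_pipeline(
    config: CampaignConfig | None = None,
    records: Sequence[rig.ExperimentRecord] | None = None,
    greenness_scores: Sequence[float] | None = None,
) -> CampaignReport:
    """Execute the whole workflow; returns the report and writes all artifacts.

    ``records`` replaces the virtual rig with ingested real measurements.
    Stage seeds derive deterministically from ``config.seed``.
    """
    config = config or CampaignConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _stage_logger(out)
    artifacts: dict[str, str] = {}

    def persist(name: str, path: Path, stage: str) -> None:
        artifacts[name] = path.name  # dir-independent, so equal-seed reports compare equal
        log.info("stage=%s wrote %s sha256=%s", stage, path.name, _sha256(path))

    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("design", "campaign", "risk", "sensitivity"),
            np.random.SeedSequence(config.seed).spawn(4),
        )
    }

    # --- design -----------------------------------------------------------
    try:
        table = doe.generate_dsd(config.factors, seed=seeds["design"])
        design_df = doe.write_design_csv(table, out / "design.csv")
        persist("design", out / "design.csv", "design")
    except Exception as e:  # noqa: BLE001 - stage tagging
        raise PipelineError("design", e) from e

    # --- convert + execute ------------------------------------------------
    try:
        if records is None:
            records = rig.simulate_campaign(
                table,
                seed=seeds["campaign"],
                mp=config.materials,
                hw=config.hardware,
                k=config.emission_constants,
            )
        records_df = rig.write_records_csv(records, out / "records.csv")
        persist("records", out / "records.csv", "execute")
        for r in records:
            resid = check_mass_balance(r.operating, r.conditions, config.materials, config.hardware)
            if resid.max_abs > 1e-6:
                raise ValueError(f"mass balance violated at run {r.run_id}: {resid}")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("execute", e) from e

    # --- fit ----------------------------------------------------------------
    try:
        coded = np.vstack([doe.encode_levels(r.conditions, config.factors) for r in records])
        y = np.array([r.lanosterol_yield for r in records])
        model = rsm.backward_eliminate(coded, y, alpha=0.10)
        model.to_json(out / "model.json")
        persist("model", out / "model.json", "fit")
        model.anova.to_csv(out / "anova.csv", index=False)
        persist("anova", out / "anova.csv", "fit")
    except Exception as e:
        raise PipelineError("fit", e) from e

    # --- risk map + selection ----------------------------------------------
    try:
        settings = config.risk.model_copy(update={"seed": seeds["risk"]})
        grid = risk.GridSpec.from_factors(config.factors)
        riskmap = risk.exhaustive_risk_map(model, grid, settings, config.factors)
        riskmap.table.to_csv(out / "riskmap.csv", index=False)
        persist("riskmap", out / "riskmap.csv", "risk")
        selected = risk.select_conditions(riskmap)
        sel_df = pd.DataFrame(
            [
                {
                    "temperature_C": selected.T,
                    "time_min": selected.t0,
                    "lanolin_mass_fraction": selected.wi,
                    "alkali_kg_per_kg": selected.lam_a,
                }
            ]
        )
        sel_df.to_csv(out / "selected_conditions.csv", index=False)
        persist("selected_conditions", out / "selected_conditions.csv", "risk")
        sel_mask = (
            np.isclose(riskmap.table["temperature"], selected.T)
            & np.isclose(riskmap.table["time"], selected.t0)
            & np.isclose(riskmap.table["mass_fraction"], selected.wi)
            & np.isclose(riskmap.table["alkali"], selected.lam_a)
        )
        selected_risk = float(riskmap.table.loc[sel_mask, "risk"].iloc[0])
        riskmap_summary = {
            "n_points": int(len(riskmap.table)),
            "n_feasible": int(riskmap.table["feasible"].sum()),
            "min_risk": float(riskmap.table["risk"].min()),
        }
    except Exception as e:
        raise PipelineError("risk", e) from e

    # --- emissions + sensitivity --------------------------------------------
    try:
        selected_emission = emissions.carbon_emission(
            selected, config.materials, config.emission_constants
        )
        sampling = config.sampling.model_copy(update={"seed": seeds["sensitivity"]})
        sens = sensitivity.sensitivity_table(sampling, config.materials, config.emission_constants)
        sensitivity.write_sensitivity_csv(sens, out / "sensitivity.csv")
        persist("sensitivity", out / "sensitivity.csv", "sensitivity")
    except Exception as e:
        raise PipelineError("sensitivity", e) from e

    scorecard = emissions.greenness_total(greenness_scores) if greenness_scores is not None else None

    report = CampaignReport(
        design=design_df,
        records=records_df,
        model=model,
        riskmap_summary=riskmap_summary,
        selected_conditions=selected,
        selected_emission=selected_emission,
        selected_risk=selected_risk,
        sensitivity=sens,
        scorecard=scorecard,
        artifacts=artifacts,
    )
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True), encoding="utf-8"
    )
    persist("report", out / "report.json", "report")
    return report


def ingest_external_records(path: str | Path) -> list[rig.ExperimentRecord]:
    """Load and validate a ``records.csv`` written by this package or by hand."""
    df = pd.read_csv(path, dtype={"timestamp": str})
    missing = [c for c in rig.RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records file {path} lacks columns: {missing}")
    bad = df[(df["lanosterol_yield"] < 0) | (df["lanosterol_yield"] > 1)
             | (df["cholesterol_yield"] < 0) | (df["cholesterol_yield"] > 1)]
    if not bad.empty:
        raise ValueError(f"yields outside [0, 1] in rows {bad.index.tolist()} of {path}")
    out = []
    from .flow import OperatingParameters

    for _, r in df.iterrows():
        out.append(
            rig.ExperimentRecord(
                run_id=int(r["run_id"]),
                conditions=ProcessConditions(
                    T=r["temperature_C"],
                    t0=r["time_min"],
                    wi=r["lanolin_mass_fraction"],
                    lam_a=r["alkali_kg_per_kg"],
                ),
                operating=OperatingParameters(
                    Q1=r["Q1_mL_min"],
                    Q2=r["Q2_mL_min"],
                    Q3=r["Q3_mL_min"],
                    t1=r["t1_min"],
                    t2=r["t2_min"],
                    bath_setpoint=r["bath_C"],
                ),
                lanosterol_yield=float(r["lanosterol_yield"]),
                cholesterol_yield=float(r["cholesterol_yield"]),
                co2_kg_per_kg=float(r["co2_kg_per_kg"]),
                timestamp="" if pd.isna(r["timestamp"]) else str(r["timestamp"]),
            )
        )
    return out
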