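"""Synthetic microreactor rig: a ground-truth yield surface plus noise.

Stands in for the wet-lab campaign so every pipeline stage is testable
without hardware. The lanosterol yield follows a hierarchical quadratic
surface in coded factors with Gaussian measurement noise (SD 0.045, the
study-scale repeatability); cholesterol esters saponify essentially
completely under all conditions, so the cholesterol channel is modelled as
1 minus a small one-sided noise. The truth coefficients are a synthetic
calibration — chosen so the design-point yields span roughly 0.53-0.92,
the (70 degC, 5 min, wi 0.25) anchor evaluates to 0.67, and alkali dosage
has no effect — not values fitted to any real campaign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import (
    EmissionConstants,
    FactorSpec,
    HardwareConfig,
    MaterialProperties,
    ProcessConditions,
)
from .doe import DesignTable, encode_levels
from .emissions import carbon_emission
from .flow import OperatingParameters, compute_operating_parameters

__all__ = [
    "TrueResponse",
    "ExperimentRecord",
    "default_truth",
    "simulate_run",
    "simulate_campaign",
    "records_to_frame",
    "write_records_csv",
]

#: simulated campaign clock: fixed epoch, one slot per run (keeps replays identical)
_CAMPAIGN_EPOCH = datetime(2025, 1, 1, 8, 0, 0, tzinfo=timezone.utc)
_RUN_SLOT_MIN = 17.0  # nominal minutes per run slot in the simulated log


@dataclass
class TrueResponse:
    """Ground-truth yield polynomial in coded units, plus noise level.

    Coefficient order: intercept, linear (T, t, w, alkali), then the
    temperature x mass-fraction interaction. The alkali coefficient is zero:
    within its narrow dosing band alkali does not move the yield.
    """

    intercept: float = 0.765
    temperature: float = 0.05
    time: float = 0.045
    mass_fraction: float = 0.10
    t_by_w: float = -0.04
    alkali: float = 0.0
    noise_sd: float = 0.045
    seed: int = 0

    def evaluate(self, coded: np.ndarray) -> np.ndarray:
        """Noise-free yield at coded points (rows: T, t, w, alkali)."""
        c = np.atleast_2d(np.asarray(coded, dtype=float))
        y = (
            self.intercept
            + self.temperature * c[:, 0]
            + self.time * c[:, 1]
            + self.mass_fraction * c[:, 2]
            + self.alkali * c[:, 3]
            + self.t_by_w * c[:, 0] * c[:, 2]
        )
        return y if y.size > 1 else float(y[0])


def default_truth() -> TrueResponse:
    return TrueResponse()


@dataclass
class ExperimentRecord:
    """One executed run: conditions, operating parameters and assay results."""

    run_id: int
    conditions: ProcessConditions
    operating: OperatingParameters
    lanosterol_yield: float
    cholesterol_yield: float
    co2_kg_per_kg: float
    timestamp: str = ""

    def __post_init__(self):
        for name in ("lanosterol_yield", "cholesterol_yield"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1] for run {self.run_id}")


def simulate_run(
    pc: ProcessConditions,
    truth: TrueResponse,
    seed: int,
    factors: Sequence[FactorSpec],
    mp: MaterialProperties | None = None,
    hw: HardwareConfig | None = None,
    k: EmissionConstants | None = None,
    run_id: int = 1,
    timestamp: str = "",
) -> ExperimentRecord:
    """Execute one virtual run: truth polynomial + seeded measurement noise."""
    mp = mp or MaterialProperties()
    hw = hw or HardwareConfig()
    k = k or EmissionConstants()
    coded = encode_levels(pc, factors)
    if np.any(np.abs(coded) > 1 + 1e-9):
        import warnings

        warnings.warn(
            f"conditions {pc} lie outside the coded design range; extrapolating the truth surface",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    lano = float(np.clip(truth.evaluate(coded) + rng.normal(0.0, truth.noise_sd), 0.0, 1.0))
    chol = float(np.clip(1.0 - abs(rng.normal(0.0, 0.01)), 0.0, 1.0))
    return ExperimentRecord(
        run_id=run_id,
        conditions=pc,
        operating=compute_operating_parameters(pc, mp, hw),
        lanosterol_yield=lano,
        cholesterol_yield=chol,
        co2_kg_per_kg=carbon_emission(pc, mp, k),
        timestamp=timestamp,
    )


def simulate_campaign(
    design: DesignTable,
    truth: TrueResponse | None = None,
    seed: int = 0,
    mp: MaterialProperties | None = None,
    hw: HardwareConfig | None = None,
    k: EmissionConstants | None = None,
) -> list[ExperimentRecord]:
    """Run the whole design in its execution order (ascending temperature).

    Per-run seeds derive deterministically from the campaign seed, so a
    campaign replays identically; timestamps come from a simulated clock.
    """
    truth = truth or default_truth()
    children = np.random.SeedSequence(seed).spawn(design.n_runs)
    records = []
    for slot, row in enumerate(design.run_order):
        stamp = (_CAMPAIGN_EPOCH + timedelta(minutes=slot * _RUN_SLOT_MIN)).isoformat()
        records.append(
            simulate_run(
                design.conditions(int(row)),
                truth,
                seed=int(children[int(row)].generate_state(1)[0] % (2**31)),
                factors=design.factors,
                mp=mp,
                hw=hw,
                k=k,
                run_id=int(design.physical["run_id"].iloc[int(row)]),
                timestamp=stamp,
            )
        )
    return records


RECORD_COLUMNS = [
    "run_id",
    "timestamp",
    "temperature_C",
    "time_min",
    "lanolin_mass_fraction",
    "alkali_kg_per_kg",
    "Q1_mL_min",
    "Q2_mL_min",
    "Q3_mL_min",
    "t1_min",
    "t2_min",
    "bath_C",
    "lanosterol_yield",
    "cholesterol_yield",
    "co2_kg_per_kg",
]


def records_to_frame(records: Sequence[ExperimentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "run_id": r.run_id,
                "timestamp": r.timestamp,
                "temperature_C": r.conditions.T,
                "time_min": r.conditions.t0,
                "lanolin_mass_fraction": r.conditions.wi,
                "alkali_kg_per_kg": r.conditions.lam_a,
                "Q1_mL_min": r.operating.Q1,
                "Q2_mL_min": r.operating.Q2,
                "Q3_mL_min": r.operating.Q3,
                "t1_min": r.operating.t1,
                "t2_min": r.operating.t2,
                "bath_C": r.operating.bath_setpoint,
                "lanosterol_yield": r.lanosterol_yield,
                "cholesterol_yield": r.cholesterol_yield,
                "co2_kg_per_kg": r.co2_kg_per_kg,
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records_csv(records: Sequence[ExperimentRecord], path: str | Path) -> pd.DataFrame:
    df = records_to_frame(records)
    df.to_csv(path, index=False)
    return df
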