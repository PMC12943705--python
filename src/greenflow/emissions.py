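"""Carbon-emission accounting and the green-chemistry scorecard.

Emissions are attributed to natural-gas heating of the process streams from
the 25 degC reference to the reaction temperature. Per kg of processed
lanolin the heated mass is the full diluted lanolin solution plus the
alkali solution, ``1/wi + lam_a/wj`` kg, so

    m_CO2 = (1/wi + lam_a/wj) * c_spec * (T - 25) * EF / 1e6   [kg CO2 / kg lanolin]

with ``EF = C_fuel * eta * (M_CO2/M_C) / LHv`` the fuel emission factor in
kg CO2 per MJ of delivered heat (0.14245 kg/MJ for the default natural-gas
constants) and ``c_spec`` an effective specific heat in J/(kg*degC).
Emissions are independent of reaction time and alkali dosage enters only
through the small alkali-solution mass — which is why the sensitivity
analysis finds temperature and lanolin mass fraction to be the drivers.

The greenness scorecard is the 12-principle green-chemistry rubric: each
principle scored on [0, 10], 120 points maximum. Only the arithmetic and
validation live here; scores themselves are expert judgements supplied by
the user.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import EmissionConstants, MaterialProperties, ProcessConditions

__all__ = [
    "GreennessScorecard",
    "emission_factor",
    "heated_mass",
    "carbon_emission",
    "carbon_emission_arrays",
    "greenness_total",
]


def emission_factor(k: EmissionConstants) -> float:
    """Fuel emission factor in kg CO2 per MJ of heat.

    ``C_fuel/LHv`` is t C per GJ = kg C per MJ; multiplying by the
    oxidation rate and the CO2/C molar-mass ratio converts to kg CO2/MJ.
    """
    return k.C_fuel * k.eta * (k.M_CO2 / k.M_C) / k.LHv


def heated_mass(pc: ProcessConditions, mp: MaterialProperties) -> float:
    """Heated stream mass per kg of processed lanolin: 1/wi + lam_a/wj."""
    if pc.wi <= 0 or mp.wj <= 0:
        raise ValueError("wi and wj must be positive")
    return 1.0 / pc.wi + pc.lam_a / mp.wj


def carbon_emission(pc: ProcessConditions, mp: MaterialProperties, k: EmissionConstants) -> float:
    """Carbon emission in kg CO2 per kg of processed lanolin.

    Linear in (T - 25) and in ``c_spec``; zero at the reference
    temperature; independent of reaction time.
    """
    if pc.T < k.T_ref:
        raise ValueError(
            f"below-reference temperature: T={pc.T} degC < reference {k.T_ref} degC "
            "(the heating model only covers T >= 25)"
        )
    return float(carbon_emission_arrays(pc.T, pc.wi, pc.lam_a, mp, k))


def carbon_emission_arrays(T, wi, lam_a, mp: MaterialProperties, k: EmissionConstants):
    """Vectorised emission kernel over arrays of T, wi and lam_a."""
    T = np.asarray(T, dtype=float)
    wi = np.asarray(wi, dtype=float)
    lam_a = np.asarray(lam_a, dtype=float)
    mass = 1.0 / wi + lam_a / mp.wj  # kg heated per kg lanolin
    heat_mj = mass * k.c_spec * (T - k.T_ref) / 1e6  # J -> MJ
    return heat_mj * emission_factor(k)


@dataclass
class GreennessScorecard:
    """Scores against the twelve principles of green chemistry."""

    scores: tuple[float, ...]
    total: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"principle": range(1, 13), "score": self.scores})


def greenness_total(scores: Sequence[float]) -> GreennessScorecard:
    """Validate twelve per-principle scores in [0, 10] and sum them (max 120)."""
    scores = tuple(float(s) for s in scores)
    if len(scores) != 12:
        raise ValueError(f"exactly 12 principle scores required, got {len(scores)}")
    bad = [(i + 1, s) for i, s in enumerate(scores) if not 0.0 <= s <= 10.0]
    if bad:
        raise ValueError(f"scores outside [0, 10]: {bad}")
    return GreennessScorecard(scores=scores, total=sum(scores))


def read_scorecard_csv(path: str | Path) -> GreennessScorecard:
    """Read a scorecard CSV with columns ``principle`` (1-12) and ``score``."""
    df = pd.read_csv(path)
    if not {"principle", "score"} <= set(df.columns):
        raise ValueError(f"scorecard file {path} needs columns 'principle' and 'score'")
    df = df.sort_values("principle")
    if list(df["principle"]) != list(range(1, 13)):
        raise ValueError("scorecard must list principles 1..12 exactly once each")
    return greenness_total(df["score"].tolist())
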