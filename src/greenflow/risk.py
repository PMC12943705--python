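"""Design-space identification by exhaustive grid + Monte-Carlo risk.

The fitted yield model's coefficients are uncertain; their estimated
multivariate-normal distribution (mean = OLS estimates, covariance =
sigma^2 (X'X)^-1) is sampled, and at every candidate operating point the
*risk* is the fraction of coefficient draws whose mean predicted yield
falls outside the quality band (lanosterol yield 55-70 %, which bounds the
product's lanosterol content to the pharmacopoeial 10-13 %). Points with
risk at or below the acceptable level (0.2) form the design space.

Among feasible points the green optimum is chosen lexicographically:
minimum alkali dosage (waste), then minimum reaction time (efficiency),
then minimum temperature (emissions), and finally the lanolin mass
fraction with the greatest margin to infeasibility (robustness), ties
resolving to the higher mass fraction (lower emissions).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import FactorSpec, ProcessConditions, RiskSettings, default_factors
from .rsm import QuadraticModel, build_model_matrix

__all__ = [
    "GridSpec",
    "RiskMap",
    "draw_coefficients",
    "risk_at_point",
    "exhaustive_risk_map",
    "select_conditions",
]

#: default grid steps per factor (physical units)
DEFAULT_STEPS = {"temperature": 1.0, "time": 1.0, "mass_fraction": 0.01, "alkali": 0.001}


@dataclass
class GridSpec:
    """Ordered physical candidate levels per factor (canonical factor order)."""

    levels: dict[str, np.ndarray]

    def __post_init__(self):
        for name, lv in self.levels.items():
            lv = np.asarray(lv, dtype=float)
            if lv.ndim != 1 or len(lv) == 0 or np.any(np.diff(lv) <= 0):
                raise ValueError(f"levels for {name} must be a non-empty strictly increasing 1-D array")
            self.levels[name] = lv

    @classmethod
    def from_factors(
        cls, factors: Sequence[FactorSpec] | None = None, steps: dict[str, float] | None = None
    ) -> "GridSpec":
        factors = list(factors) if factors is not None else default_factors()
        steps = {**DEFAULT_STEPS, **(steps or {})}
        levels = {}
        for f in factors:
            n = int(round((f.high - f.low) / steps[f.name])) + 1
            levels[f.name] = np.round(np.linspace(f.low, f.high, n), 10)
        return cls(levels=levels)

    def points(self) -> pd.DataFrame:
        """All grid combinations as a DataFrame in canonical factor order."""
        names = list(self.levels)
        combos = list(itertools.product(*(self.levels[n] for n in names)))
        return pd.DataFrame(combos, columns=names)


@dataclass
class RiskMap:
    """Grid of candidate conditions with Monte-Carlo failure probabilities."""

    table: pd.DataFrame  # factor columns + risk + feasible
    settings: RiskSettings
    metadata: dict = field(default_factory=dict)

    @property
    def feasible(self) -> pd.DataFrame:
        return self.table[self.table["feasible"]]


def draw_coefficients(model: QuadraticModel, n: int, seed: int) -> np.ndarray:
    """Sample ``n`` coefficient vectors from the fitted coefficient distribution."""
    cov = np.asarray(model.coef_covariance, dtype=float)
    cov = 0.5 * (cov + cov.T)
    eigmin = float(np.linalg.eigvalsh(cov).min()) if cov.size else 0.0
    scale = max(1.0, float(np.abs(cov).max()))
    if eigmin < -1e-10 * scale:
        raise ValueError(f"coefficient covariance is not positive semidefinite (min eigenvalue {eigmin:.3e})")
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(model.coefficients, cov, size=n, method="svd")


def _prediction_risk(preds: np.ndarray, settings: RiskSettings, rng=None, sigma=0.0) -> np.ndarray:
    if rng is not None and sigma > 0:
        preds = preds + rng.normal(0.0, sigma, size=preds.shape)
    bad = (preds < settings.yield_low) | (preds > settings.yield_high)
    return bad.mean(axis=-1)


def risk_at_point(
    model: QuadraticModel,
    coded_point: np.ndarray,
    settings: RiskSettings,
    draws: np.ndarray | None = None,
    predictive: bool = False,
) -> float:
    """Probability that the predicted mean yield misses the quality band.

    ``predictive=True`` additionally draws residual noise per simulation
    (predictive-distribution mode) instead of pure coefficient uncertainty.
    """
    if draws is None:
        draws = draw_coefficients(model, settings.n_sims, settings.seed)
    x = build_model_matrix(np.atleast_2d(np.asarray(coded_point, dtype=float)), model.terms)
    preds = (draws @ x.T).ravel()
    rng = np.random.default_rng(settings.seed + 1) if predictive else None
    return float(_prediction_risk(preds, settings, rng, np.sqrt(model.sigma2)))


def exhaustive_risk_map(
    model: QuadraticModel,
    grid: GridSpec,
    settings: RiskSettings,
    factors: Sequence[FactorSpec] | None = None,
    shared_draws: bool = True,
    predictive: bool = False,
) -> RiskMap:
    """Monte-Carlo risk at every grid point.

    One shared coefficient-draw set is used across the whole grid by
    default (common random numbers give a smooth map); per-point fresh
    draws are available with ``shared_draws=False``.
    """
    factors = list(factors) if factors is not None else default_factors()
    pts = grid.points()
    if pts.empty:
        raise ValueError("empty risk grid")
    coded = np.column_stack(
        [f.encode(pts[f.name].to_numpy()) for f in factors]
    )
    x = build_model_matrix(coded, model.terms)
    if shared_draws:
        draws = draw_coefficients(model, settings.n_sims, settings.seed)
        preds = x @ draws.T  # (n_points, n_sims)
        rng = np.random.default_rng(settings.seed + 1) if predictive else None
        risk = _prediction_risk(preds, settings, rng, np.sqrt(model.sigma2))
    else:
        risk = np.empty(len(pts))
        for i in range(len(pts)):
            risk[i] = risk_at_point(
                model, coded[i], settings.model_copy(update={"seed": settings.seed + i}),
                predictive=predictive,
            )
    out = pts.copy()
    out["risk"] = risk
    out["feasible"] = risk <= settings.acceptable_risk
    return RiskMap(table=out, settings=settings, metadata={"n_points": len(pts), "predictive": predictive})


def select_conditions(
    riskmap: RiskMap,
    emissions_fn: Callable[[ProcessConditions], float] | None = None,
) -> ProcessConditions:
    """Lexicographic green optimum over the feasible design space.

    Priority order: feasibility, minimum alkali dosage, minimum reaction
    time, minimum temperature, then the mass-fraction level with the
    greatest distance to the nearest infeasible mass fraction at the same
    (alkali, time, temperature); remaining ties go to the larger mass
    fraction (lower heated mass, hence lower emissions — ``emissions_fn``
    can be supplied to audit that choice but does not alter the rule).
    """
    feas = riskmap.feasible
    if feas.empty:
        raise ValueError("no design space: every grid point exceeds the acceptable risk")
    for col in ("alkali", "time", "temperature"):
        feas = feas[np.isclose(feas[col], feas[col].min())]
    lam_a, t0, temp = (float(feas[c].iloc[0]) for c in ("alkali", "time", "temperature"))

    same_combo = riskmap.table[
        np.isclose(riskmap.table["alkali"], lam_a)
        & np.isclose(riskmap.table["time"], t0)
        & np.isclose(riskmap.table["temperature"], temp)
    ]
    infeasible_w = same_combo.loc[~same_combo["feasible"], "mass_fraction"].to_numpy()
    # the region beyond the explored grid is uncertified: treat one grid step
    # past each end as infeasible, so a one-sided feasible band still selects
    # an interior (robust) mass fraction rather than the range edge
    w_levels = np.sort(same_combo["mass_fraction"].unique())
    if len(w_levels) > 1:
        step = float(np.min(np.diff(w_levels)))
        infeasible_w = np.concatenate(
            [infeasible_w, [w_levels[0] - step, w_levels[-1] + step]]
        )

    def margin(w: float) -> float:
        return float(np.min(np.abs(infeasible_w - w))) if infeasible_w.size else np.inf

    best_w = max(sorted(feas["mass_fraction"].unique()), key=lambda w: (margin(w), w))
    return ProcessConditions(T=temp, t0=t0, wi=float(best_w), lam_a=lam_a)
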