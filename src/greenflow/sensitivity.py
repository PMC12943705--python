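"""Global sensitivity of carbon emissions to the process parameters.

Parameters are drawn by simple random (uniform) sampling over their study
ranges, the emission model is evaluated for each draw, and each
parameter's influence is summarised by its Pearson correlation with the
emission, with a two-sided t-test for significance and a three-way grading
of |r|: extremely sensitive (> 0.5), weakly sensitive (0.2-0.5) and
insensitive (< 0.2). Boundary values go to the higher grade.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import EmissionConstants, MaterialProperties, SamplingRanges
from .emissions import carbon_emission_arrays

__all__ = [
    "SensitivityRow",
    "sample_parameter_space",
    "pearson_with_test",
    "grade",
    "sensitivity_table",
]

#: reporting order of the four process parameters
TABLE_ORDER = [
    ("alkali", "Alkali consumption (kg/kg lanolin)"),
    ("time", "Reaction time (min)"),
    ("temperature", "Reaction temperature (degC)"),
    ("mass_fraction", "Lanolin solution mass fraction"),
]


@dataclass
class SensitivityRow:
    parameter: str
    r: float
    p: float
    significance: str  # "Significant" | "Not significant"
    grade: str  # "Extremely sensitive" | "Weakly sensitive" | "Insensitive"


def sample_parameter_space(ranges: SamplingRanges) -> pd.DataFrame:
    """Independent uniform draws for each parameter over its range."""
    rng = np.random.default_rng(ranges.seed)
    return pd.DataFrame(
        {
            name: rng.uniform(*getattr(ranges, name), size=ranges.n_samples)
            for name in ("temperature", "time", "mass_fraction", "alkali")
        }
    )


def pearson_with_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided t-test p-value.

    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays with at least 3 points")
    for name, arr in (("x", x), ("y", y)):
        if np.ptp(arr) == 0:
            raise ValueError(f"zero variance in {name}: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    n = len(x)
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def grade(r: float, p: float, alpha: float = 0.05) -> tuple[str, str]:
    """Significance and sensitivity labels for a correlation result."""
    significance = "Significant" if p < alpha else "Not significant"
    a = abs(r)
    if a >= 0.5:
        level = "Extremely sensitive"
    elif a >= 0.2:
        level = "Weakly sensitive"
    else:
        level = "Insensitive"
    return significance, level


def sensitivity_table(
    ranges: SamplingRanges | None = None,
    mp: MaterialProperties | None = None,
    k: EmissionConstants | None = None,
) -> pd.DataFrame:
    """One sensitivity row per process parameter, in reporting order.

    Reaction time does not enter the emission model and alkali only through
    the small alkali-solution mass, so both grade Insensitive; temperature
    and lanolin mass fraction are the drivers.
    """
    ranges = ranges or SamplingRanges()
    mp = mp or MaterialProperties()
    k = k or EmissionConstants()
    draws = sample_parameter_space(ranges)
    emission = carbon_emission_arrays(
        draws["temperature"].to_numpy(),
        draws["mass_fraction"].to_numpy(),
        draws["alkali"].to_numpy(),
        mp,
        k,
    )
    rows = []
    for name, label in TABLE_ORDER:
        r, p = pearson_with_test(draws[name].to_numpy(), emission)
        sig, level = grade(r, p)
        rows.append(
            {"parameter": label, "r": r, "p": p, "significance": sig, "grade": level}
        )
    return pd.DataFrame(rows)


def write_sensitivity_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
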