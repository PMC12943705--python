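"""Definitive screening design (DSD) construction and run scheduling.

A DSD for ``m`` factors is built from an order-``m`` conference matrix
``C`` (zero diagonal, +/-1 off-diagonal, ``C.T @ C = (m-1) I``): the runs
are the fold-over pairs ``{c_k, -c_k}`` of its rows plus a centre run, so
every factor is exercised at three levels while main effects stay
orthogonal to each other and to all quadratic effects. Here the four
process factors are augmented with two *fake* factors (columns generated
but never assigned, then dropped), which buys pure-error degrees of
freedom; with two extra centre replicates the campaign is 15 runs.

Runs are scheduled in ascending order of temperature so the oil bath only
ever heats up, minimising temperature transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import FactorSpec, ProcessConditions, default_factors

__all__ = [
    "DesignTable",
    "build_conference_matrix",
    "generate_dsd",
    "decode_levels",
    "encode_levels",
    "order_runs",
    "write_design_csv",
]

#: design.csv column names, in writing order
DESIGN_COLUMNS = [
    "run_id",
    "exec_order",
    "coded_T",
    "coded_t",
    "coded_w",
    "coded_alk",
    "temperature_C",
    "time_min",
    "lanolin_mass_fraction",
    "alkali_kg_per_kg",
]


@dataclass
class DesignTable:
    """A screening design: coded matrix, physical conditions and schedule.

    ``coded`` holds the real-factor columns only (entries in {-1, 0, +1},
    canonical factor order temperature/time/mass_fraction/alkali);
    ``physical`` the decoded conditions, one row per run; ``run_order`` the
    execution permutation (``run_order[k]`` = design row executed k-th).
    """

    coded: np.ndarray
    physical: pd.DataFrame
    factors: list[FactorSpec]
    run_order: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    def conditions(self, row: int) -> ProcessConditions:
        r = self.physical.iloc[row]
        return ProcessConditions(
            T=r["temperature_C"],
            t0=r["time_min"],
            wi=r["lanolin_mass_fraction"],
            lam_a=r["alkali_kg_per_kg"],
        )


def _paley_conference_matrix(order: int) -> np.ndarray:
    """Symmetric conference matrix of order q+1 for a prime q = 1 (mod 4)."""
    q = order - 1
    # quadratic-residue character chi on GF(q)
    residues = {(x * x) % q for x in range(1, q)}
    chi = np.zeros(q, dtype=int)
    for a in range(1, q):
        chi[a] = 1 if a in residues else -1
    jacobsthal = np.empty((q, q), dtype=int)
    for i in range(q):
        for j in range(q):
            jacobsthal[i, j] = chi[(i - j) % q]
    c = np.zeros((order, order), dtype=int)
    c[0, 1:] = 1
    c[1:, 0] = 1
    c[1:, 1:] = jacobsthal
    return c


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    return all(n % d for d in range(2, int(n**0.5) + 1))


def build_conference_matrix(order: int, seed: int = 0) -> np.ndarray:
    """Return a seeded order-``order`` conference matrix.

    A Paley-style base matrix is randomised by a simultaneous row/column
    permutation and independent row and column sign flips — operations
    that preserve the zero diagonal, the one-zero-per-line pattern and the
    defining identity ``C.T @ C = (order-1) I``, which is re-validated
    before returning. The same seed always yields the same matrix.
    """
    if order % 2 != 0:
        raise ValueError(f"no conference matrix of odd order {order}")
    q = order - 1
    if not (_is_prime(q) and q % 4 == 1):
        raise ValueError(
            f"unsupported conference-matrix order {order}: "
            "only orders q+1 with q prime and q = 1 (mod 4) are constructed (e.g. 6, 14, 18)"
        )
    c = _paley_conference_matrix(order)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(order)
    c = c[np.ix_(perm, perm)]  # conjugation keeps the diagonal zero
    row_signs = rng.choice([-1, 1], size=order)
    col_signs = rng.choice([-1, 1], size=order)
    c = row_signs[:, None] * c * col_signs[None, :]
    _validate_conference(c)
    return c


def _validate_conference(c: np.ndarray) -> None:
    n = c.shape[0]
    if c.shape != (n, n) or np.any(np.diag(c) != 0):
        raise AssertionError("conference matrix must be square with zero diagonal")
    off = c[~np.eye(n, dtype=bool)]
    if np.any(np.abs(off) != 1):
        raise AssertionError("off-diagonal entries must be +/-1")
    if not np.array_equal(c.T @ c, (n - 1) * np.eye(n, dtype=int)):
        raise AssertionError("C.T @ C != (n-1) I")


def generate_dsd(
    factors: Sequence[FactorSpec] | None = None,
    n_fake: int = 2,
    center_reps: int = 2,
    seed: int = 0,
) -> DesignTable:
    """Build the definitive screening design for the four process factors.

    The (n_real + n_fake)-column DSD is assembled as fold-over pairs of the
    conference-matrix rows plus one centre run; the fake columns are then
    dropped and ``center_reps`` extra centre runs appended. With the
    defaults (2 fake factors, 2 extra centres) the table has
    2*(4+2) + 1 + 2 = 15 rows and every real factor takes exactly the three
    levels {-1, 0, +1}.
    """
    factors = list(factors) if factors is not None else default_factors()
    if n_fake < 0 or center_reps < 0:
        raise ValueError("n_fake and center_reps must be non-negative")
    n_real = len(factors)
    order = n_real + n_fake
    conference = build_conference_matrix(order, seed=seed)  # raises for unsupported sizes

    full = np.vstack(
        [
            conference,
            -conference,
            np.zeros((1 + center_reps, order), dtype=int),
        ]
    )
    coded = full[:, :n_real]  # the trailing n_fake columns are dropped

    physical = pd.DataFrame(
        {
            "run_id": np.arange(1, coded.shape[0] + 1),
            "temperature_C": [factors[0].decode(v) for v in coded[:, 0]],
            "time_min": [factors[1].decode(v) for v in coded[:, 1]],
            "lanolin_mass_fraction": [factors[2].decode(v) for v in coded[:, 2]],
            "alkali_kg_per_kg": [factors[3].decode(v) for v in coded[:, 3]],
        }
    )
    table = DesignTable(
        coded=coded,
        physical=physical,
        factors=factors,
        run_order=np.arange(coded.shape[0]),
        metadata={
            "n_real": n_real,
            "n_fake": n_fake,
            "center_reps": center_reps,
            "seed": seed,
            "coded_full": full,
        },
    )
    return order_runs(table)


def decode_levels(coded_row: Sequence[float], factors: Sequence[FactorSpec]) -> ProcessConditions:
    """Map one coded row (entries in {-1, 0, +1}) to physical conditions."""
    vals = []
    for j, (v, f) in enumerate(zip(coded_row, factors)):
        if v not in (-1, 0, 1):
            raise ValueError(f"coded entry {v!r} in column {j} ({f.name}): must be -1, 0 or +1")
        vals.append(f.decode(v))
    t, t0, wi, lam_a = vals
    return ProcessConditions(T=t, t0=t0, wi=wi, lam_a=lam_a)


def encode_levels(pc: ProcessConditions, factors: Sequence[FactorSpec]) -> np.ndarray:
    """Inverse of :func:`decode_levels` (exact on the three design levels)."""
    phys = (pc.T, pc.t0, pc.wi, pc.lam_a)
    return np.array([f.encode(v) for f, v in zip(factors, phys)])


def order_runs(table: DesignTable) -> DesignTable:
    """Schedule runs in ascending temperature, ties keeping design order."""
    temps = table.physical["temperature_C"].to_numpy()
    order = np.argsort(temps, kind="stable")
    return DesignTable(
        coded=table.coded,
        physical=table.physical,
        factors=table.factors,
        run_order=order,
        metadata=dict(table.metadata),
    )


def write_design_csv(table: DesignTable, path: str | Path) -> pd.DataFrame:
    """Write ``design.csv`` (one row per run, in design order)."""
    exec_order = np.empty(table.n_runs, dtype=int)
    exec_order[table.run_order] = np.arange(1, table.n_runs + 1)
    df = pd.DataFrame(
        {
            "run_id": table.physical["run_id"],
            "exec_order": exec_order,
            "coded_T": table.coded[:, 0],
            "coded_t": table.coded[:, 1],
            "coded_w": table.coded[:, 2],
            "coded_alk": table.coded[:, 3],
            "temperature_C": table.physical["temperature_C"],
            "time_min": table.physical["time_min"],
            "lanolin_mass_fraction": table.physical["lanolin_mass_fraction"],
            "alkali_kg_per_kg": table.physical["alkali_kg_per_kg"],
        }
    )
    df.to_csv(path, index=False)
    return df


def read_design_csv(path: str | Path, factors: Sequence[FactorSpec] | None = None) -> DesignTable:
    """Reconstruct a :class:`DesignTable` from ``design.csv``."""
    factors = list(factors) if factors is not None else default_factors()
    df = pd.read_csv(path)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design file {path} lacks columns: {missing}")
    coded = df[["coded_T", "coded_t", "coded_w", "coded_alk"]].to_numpy()
    run_order = np.argsort(df["exec_order"].to_numpy(), kind="stable")
    physical = df[
        ["run_id", "temperature_C", "time_min", "lanolin_mass_fraction", "alkali_kg_per_kg"]
    ].copy()
    return DesignTable(coded=coded, physical=physical, factors=factors, run_order=run_order)
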