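"""Quadratic response-surface modelling with backward stepwise elimination.

The lanosterol yield Y is modelled on coded (-1..1) factor levels as a full
second-order polynomial

    Y = a0 + sum_i a_i X_i + sum_i a_ii X_i^2 + sum_{i<j} a_ij X_i X_j

fitted by ordinary least squares and reduced by backward stepwise
elimination: at each step the eligible term with the largest drop-one
(partial F) p-value above the significance threshold (default 0.10) is
removed. Model hierarchy is enforced — a linear term cannot leave while a
retained quadratic or interaction term contains it — and the intercept is
never removed. When the starting model is over-parameterised for the
design (a 15-term full quadratic on a 13-point screening design is rank
deficient), aliased terms are pruned first, latest-declared first, until
the model is estimable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelTerm",
    "QuadraticModel",
    "full_quadratic_terms",
    "build_model_matrix",
    "fit_quadratic",
    "backward_eliminate",
    "predict",
]


@dataclass(frozen=True)
class ModelTerm:
    """One polynomial term: intercept, linear X_i, quadratic X_i^2 or interaction X_i X_j."""

    kind: str  # intercept | linear | quadratic | interaction
    indices: tuple[int, ...] = ()

    def __post_init__(self):
        if self.kind not in ("intercept", "linear", "quadratic", "interaction"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        n_expected = {"intercept": 0, "linear": 1, "quadratic": 1, "interaction": 2}[self.kind]
        if len(self.indices) != n_expected:
            raise ValueError(f"{self.kind} term needs {n_expected} factor indices, got {self.indices}")
        if self.kind == "interaction" and self.indices[0] == self.indices[1]:
            raise ValueError("interaction requires two distinct factors")

    def label(self, names: Sequence[str] | None = None) -> str:
        def nm(i):
            return names[i] if names is not None else f"X{i + 1}"

        if self.kind == "intercept":
            return "1"
        if self.kind == "linear":
            return nm(self.indices[0])
        if self.kind == "quadratic":
            return f"{nm(self.indices[0])}^2"
        return f"{nm(self.indices[0])}*{nm(self.indices[1])}"

    def column(self, coded: np.ndarray) -> np.ndarray:
        if self.kind == "intercept":
            return np.ones(coded.shape[0])
        if self.kind == "linear":
            return coded[:, self.indices[0]].astype(float)
        if self.kind == "quadratic":
            return coded[:, self.indices[0]].astype(float) ** 2
        i, j = self.indices
        return coded[:, i].astype(float) * coded[:, j].astype(float)


def full_quadratic_terms(n_factors: int) -> list[ModelTerm]:
    """Intercept, linear, quadratic then interaction terms, in declaration order."""
    terms = [ModelTerm("intercept")]
    terms += [ModelTerm("linear", (i,)) for i in range(n_factors)]
    terms += [ModelTerm("quadratic", (i,)) for i in range(n_factors)]
    terms += [
        ModelTerm("interaction", (i, j)) for i in range(n_factors) for j in range(i + 1, n_factors)
    ]
    return terms


def build_model_matrix(coded: np.ndarray, terms: Sequence[ModelTerm]) -> np.ndarray:
    coded = np.asarray(coded, dtype=float)
    if coded.ndim == 1:
        coded = coded[None, :]
    return np.column_stack([t.column(coded) for t in terms])


@dataclass
class QuadraticModel:
    """A fitted (possibly reduced) quadratic model on coded levels."""

    terms: list[ModelTerm]
    coefficients: np.ndarray
    coef_covariance: np.ndarray
    sigma2: float
    R2: float
    R2_adj: float
    CV_percent: float
    SD: float
    anova: pd.DataFrame  # per-term partial F/p plus a whole-model row
    n_obs: int
    factor_names: tuple[str, ...] = ("temperature", "time", "mass_fraction", "alkali")
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def term_pvalue(self, term: ModelTerm) -> float:
        row = self.anova[self.anova["term"] == term.label(self.factor_names)]
        return float(row["p"].iloc[0])

    def to_dict(self) -> dict:
        return {
            "terms": [{"kind": t.kind, "indices": list(t.indices)} for t in self.terms],
            "term_labels": [t.label(self.factor_names) for t in self.terms],
            "coefficients": self.coefficients.tolist(),
            "coef_covariance": self.coef_covariance.tolist(),
            "sigma2": self.sigma2,
            "R2": self.R2,
            "R2_adj": self.R2_adj,
            "CV_percent": self.CV_percent,
            "SD": self.SD,
            "n_obs": self.n_obs,
            "factor_names": list(self.factor_names),
            "anova": self.anova.to_dict(orient="records"),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticModel":
        return cls(
            terms=[ModelTerm(t["kind"], tuple(t["indices"])) for t in d["terms"]],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            coef_covariance=np.asarray(d["coef_covariance"], dtype=float),
            sigma2=d["sigma2"],
            R2=d["R2"],
            R2_adj=d["R2_adj"],
            CV_percent=d["CV_percent"],
            SD=d["SD"],
            anova=pd.DataFrame(d["anova"]),
            n_obs=d["n_obs"],
            factor_names=tuple(d["factor_names"]),
        )


def _aliased_terms(coded: np.ndarray, terms: Sequence[ModelTerm]) -> list[ModelTerm]:
    """Terms whose column lies in the span of the remaining columns."""
    x = build_model_matrix(coded, terms)
    full_rank = np.linalg.matrix_rank(x)
    if full_rank == x.shape[1]:
        return []
    out = []
    for k, t in enumerate(terms):
        rest = np.delete(x, k, axis=1)
        if np.linalg.matrix_rank(rest) == full_rank:
            out.append(t)
    return out


def fit_quadratic(
    coded: np.ndarray,
    y: np.ndarray,
    terms: Sequence[ModelTerm] | None = None,
    factor_names: Sequence[str] = ("temperature", "time", "mass_fraction", "alkali"),
) -> QuadraticModel:
    """Ordinary least squares on coded levels, with ANOVA statistics.

    Raises for rank-deficient model matrices, naming the aliased terms.
    """
    coded = np.asarray(coded, dtype=float)
    y = np.asarray(y, dtype=float)
    if terms is None:
        terms = full_quadratic_terms(coded.shape[1])
    terms = list(terms)
    if len(set(terms)) != len(terms):
        raise ValueError("duplicate model terms")
    x = build_model_matrix(coded, terms)
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        aliased = _aliased_terms(coded, terms)
        labels = [t.label(factor_names) for t in aliased]
        raise np.linalg.LinAlgError(f"model matrix is rank deficient; aliased terms: {labels}")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    sse = float(resid @ resid)
    df_resid = n - p
    sst = float(np.sum((y - y.mean()) ** 2))
    sigma2 = sse / df_resid if df_resid > 0 else 0.0
    mse = sigma2
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid if df_resid > 0 else r2
    sd = np.sqrt(mse)
    cv = 100.0 * sd / abs(y.mean()) if y.mean() != 0 else np.inf

    # drop-one (partial, type III) F tests per non-intercept term
    rows = []
    for k, t in enumerate(terms):
        if t.kind == "intercept":
            continue
        x_red = np.delete(x, k, axis=1)
        beta_red, _, _, _ = np.linalg.lstsq(x_red, y, rcond=None)
        sse_red = float(np.sum((y - x_red @ beta_red) ** 2))
        if df_resid > 0 and mse > 0:
            f_val = (sse_red - sse) / mse
            p_val = float(stats.f.sf(f_val, 1, df_resid))
        else:
            f_val, p_val = np.inf, 0.0
        rows.append({"term": t.label(factor_names), "F": f_val, "p": p_val})
    # whole-model F against the intercept-only model
    n_model_terms = sum(1 for t in terms if t.kind != "intercept")
    if n_model_terms > 0 and df_resid > 0 and mse > 0:
        f_model = ((sst - sse) / n_model_terms) / mse
        p_model = float(stats.f.sf(f_model, n_model_terms, df_resid))
    else:
        f_model, p_model = np.inf, 0.0
    rows.append({"term": "Model", "F": f_model, "p": p_model})

    return QuadraticModel(
        terms=terms,
        coefficients=beta,
        coef_covariance=sigma2 * xtx_inv,
        sigma2=sigma2,
        R2=r2,
        R2_adj=r2_adj,
        CV_percent=cv,
        SD=sd,
        anova=pd.DataFrame(rows),
        n_obs=n,
        factor_names=tuple(factor_names),
        residuals=resid,
    )


def _protected_linear(terms: Sequence[ModelTerm]) -> set[int]:
    """Factor indices whose linear terms hierarchy keeps in the model."""
    protected: set[int] = set()
    for t in terms:
        if t.kind in ("quadratic", "interaction"):
            protected.update(t.indices)
    return protected


def _eligible(terms: Sequence[ModelTerm]) -> list[ModelTerm]:
    protected = _protected_linear(terms)
    out = []
    for t in terms:
        if t.kind == "intercept":
            continue
        if t.kind == "linear" and t.indices[0] in protected:
            continue
        out.append(t)
    return out


def _make_estimable(coded: np.ndarray, terms: list[ModelTerm], y: np.ndarray) -> list[ModelTerm]:
    """Prune aliased eligible terms until the model matrix has full column rank.

    Aliased columns are mutually redundant, so dropping any of them leaves
    the fit unchanged — but *which* survives decides what later stepwise
    steps can see. The choice is made data-aware: project the response and
    each aliased column onto the complement of the unambiguous columns and
    drop the aliased term with the weakest partial association, so an
    aliasing group keeps its member that actually carries signal. Ties
    break toward removing the later-declared term.
    """
    terms = list(terms)
    while True:
        x = build_model_matrix(coded, terms)
        if np.linalg.matrix_rank(x) >= len(terms):
            return terms
        aliased = [t for t in _aliased_terms(coded, terms) if t in _eligible(terms)]
        if not aliased:
            raise np.linalg.LinAlgError(
                "model cannot be reduced to an estimable hierarchical form"
            )
        safe = [i for i, t in enumerate(terms) if t not in aliased]
        q, _ = np.linalg.qr(x[:, safe])

        def partial(v: np.ndarray) -> np.ndarray:
            return v - q @ (q.T @ v)

        ry = partial(y)
        scores = []
        for t in aliased:
            z = partial(x[:, terms.index(t)])
            nz = np.linalg.norm(z)
            scores.append(abs(float(z @ ry)) / nz if nz > 1e-10 else 0.0)
        drop = min(range(len(aliased)), key=lambda i: (scores[i], -terms.index(aliased[i])))
        terms.remove(aliased[drop])


def _shed_to_positive_df(coded: np.ndarray, y: np.ndarray, terms: list[ModelTerm]) -> list[ModelTerm]:
    """A saturated (zero-df) model gives no F tests: shed the eligible term
    with the smallest drop-one SSE increase until residual df exist."""
    while len(terms) >= len(y):
        x = build_model_matrix(coded, terms)
        beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        sse = float(np.sum((y - x @ beta) ** 2))
        candidates = _eligible(terms)
        if not candidates:
            break
        increases = []
        for t in candidates:
            k = terms.index(t)
            x_red = np.delete(x, k, axis=1)
            b_red, _, _, _ = np.linalg.lstsq(x_red, y, rcond=None)
            increases.append(float(np.sum((y - x_red @ b_red) ** 2)) - sse)
        # smallest increase wins; ties -> later declaration order
        best = min(range(len(candidates)), key=lambda i: (increases[i], -terms.index(candidates[i])))
        terms.remove(candidates[best])
    return terms


def _eliminate_loop(
    coded: np.ndarray,
    y: np.ndarray,
    terms: list[ModelTerm],
    alpha: float,
    factor_names: Sequence[str],
) -> QuadraticModel:
    while True:
        model = fit_quadratic(coded, y, terms, factor_names)
        candidates = _eligible(terms)
        if not candidates:
            return model
        pvals = [model.term_pvalue(t) for t in candidates]
        worst = max(range(len(candidates)), key=lambda i: (pvals[i], terms.index(candidates[i])))
        if pvals[worst] <= alpha:
            return model
        terms.remove(candidates[worst])


def _heredity_start(
    coded: np.ndarray,
    y: np.ndarray,
    terms: list[ModelTerm],
    alpha: float,
    factor_names: Sequence[str],
) -> list[ModelTerm]:
    """Estimable starting set for an over-parameterised screening fit.

    A full quadratic is unidentifiable on a definitive screening design
    (the second-order columns are mutually aliased), and which alias-group
    member is kept should not be decided by noise. The screening-design
    literature's strong-heredity strategy is used: backward-eliminate the
    (orthogonal, high-powered) main effects first, then admit only the
    quadratics and interactions whose parent factors survived, and hand
    that set — pruned further if still rank deficient — to the ordinary
    backward stepwise pass.
    """
    mains = [t for t in terms if t.kind in ("intercept", "linear")]
    screened = _eliminate_loop(coded, y, list(mains), alpha, factor_names)
    active = {t.indices[0] for t in screened.terms if t.kind == "linear"}
    second_order = [
        t
        for t in terms
        if (t.kind == "quadratic" and t.indices[0] in active)
        or (t.kind == "interaction" and set(t.indices) <= active)
    ]
    start = mains + second_order  # inactive mains may still re-enter play
    return _make_estimable(coded, start, y)


def backward_eliminate(
    coded: np.ndarray,
    y: np.ndarray,
    terms: Sequence[ModelTerm] | None = None,
    alpha: float = 0.10,
    factor_names: Sequence[str] = ("temperature", "time", "mass_fraction", "alkali"),
) -> QuadraticModel:
    """Backward stepwise elimination at significance level ``alpha``.

    Starting from the full quadratic (or the given term set), repeatedly
    refits and removes the eligible term with the largest partial-F p-value
    exceeding ``alpha``; ties break toward the later-declared term. Stops
    when every remaining eligible term is significant. A starting set the
    design cannot estimate is first reduced by strong-heredity screening
    (see :func:`_heredity_start`).
    """
    coded = np.asarray(coded, dtype=float)
    y = np.asarray(y, dtype=float)
    terms = list(terms) if terms is not None else full_quadratic_terms(coded.shape[1])
    if np.linalg.matrix_rank(build_model_matrix(coded, terms)) < len(terms):
        terms = _heredity_start(coded, y, terms, alpha, factor_names)
    terms = _shed_to_positive_df(coded, y, terms)
    return _eliminate_loop(coded, y, terms, alpha, factor_names)


def predict(
    model: QuadraticModel, coded_point: np.ndarray, with_uncertainty: bool = False
):
    """Mean predicted yield at a coded point; optionally its standard error."""
    x = build_model_matrix(np.atleast_2d(np.asarray(coded_point, dtype=float)), model.terms)
    mean = x @ model.coefficients
    mean_out = float(mean[0]) if mean.size == 1 else mean
    if not with_uncertainty:
        return mean_out
    se = np.sqrt(np.einsum("ij,jk,ik->i", x, model.coef_covariance, x))
    se_out = float(se[0]) if se.size == 1 else se
    return mean_out, se_out
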