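"""Correlation screening and linear prediction equations.

Nutritional-value outcomes (ingredient DE, ME, per-AA SID) are related to
chemical composition on a dry-matter basis across the surveyed ingredient
samples.  Screening uses Pearson correlation with t-based two-sided
p-values; equations are ordinary least squares, with fit judged by R²
(maximized) and RMSE (minimized), RMSE on residual degrees of freedom
``n - k - 1`` for ``k`` predictors.

The default equation selector is exhaustive best-subset search over model
sizes 1..max_terms — with a dozen candidates and two-term models this is
cheap and implements "maximize R², minimize RMSE" literally.  A classical
forward-stepwise selector with significance-to-enter/stay thresholds is
available for fidelity to traditional stepwise software.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .composition import IngredientComposition, Basis
from .exceptions import (
    CollinearityError,
    ConfigError,
    DegenerateVariableError,
    InsufficientDataError,
    SchemaError,
)

__all__ = [
    "StarConvention",
    "CorrelationMatrix",
    "PredictionEquation",
    "pearson_matrix",
    "fit_linear",
    "stepwise_select",
    "predict",
]


class StarConvention(Enum):
    """Significance-star conventions used in the result tables.

    ``ENERGY``: ``*`` for 0.01 <= p < 0.05, ``**`` for p < 0.01.
    ``SID``: ``*`` for 0.05 <= p < 0.10 (tendency), ``**`` for
    0.01 <= p < 0.05.
    """

    ENERGY = "energy"
    SID = "sid"

    def star(self, p: float) -> str:
        if self is StarConvention.ENERGY:
            if p < 0.01:
                return "**"
            if p < 0.05:
                return "*"
        else:
            if 0.01 <= p < 0.05:
                return "**"
            if 0.05 <= p < 0.10:
                return "*"
        return ""


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson correlations with p-values and star annotations."""

    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame

    def annotated(self, decimals: int = 2) -> pd.DataFrame:
        """Lower-triangular display: ``r`` rounded, with stars appended."""
        out = pd.DataFrame("", index=self.r.index, columns=self.r.columns)
        for i, a in enumerate(self.variables):
            for j, b in enumerate(self.variables[: i + 1]):
                out.loc[a, b] = (
                    f"{self.r.loc[a, b]:.{decimals}f}{self.stars.loc[a, b]}"
                )
        return out


@dataclass(frozen=True)
class PredictionEquation:
    """A fitted linear prediction equation with its diagnostics."""

    response: str
    intercept: float
    coefficients: Mapping[str, float]
    r2: float
    rmse: float
    model_p: float
    n: int

    def __str__(self) -> str:
        terms = " ".join(
            f"{'-' if c < 0 else '+'} ({abs(c):.2f} x {name})"
            for name, c in self.coefficients.items()
        )
        return (
            f"{self.response} = {self.intercept:.2f} {terms}"
            f"  [R2 = {self.r2:.2f}, RMSE = {self.rmse:.2f}, p = {self.model_p:.2g}]"
        )


def pearson_matrix(
    table: pd.DataFrame,
    variables: Sequence[str] | None = None,
    convention: StarConvention = StarConvention.ENERGY,
) -> CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided t-based p-values.

    ``p = 2 * P(T_{n-2} > |t|)`` with ``t = r * sqrt((n-2)/(1-r^2))`` —
    the same sampling distribution scipy's ``pearsonr`` uses.
    """
    if variables is None:
        variables = list(table.columns)
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise SchemaError(f"variables not in table: {missing}")
    data = table[list(variables)].dropna()
    n = len(data)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete rows, got {n}")
    for v in variables:
        if np.ptp(data[v].to_numpy()) == 0:
            raise DegenerateVariableError(f"variable {v!r} has zero variance")
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i):
            res = stats.pearsonr(data.iloc[:, i], data.iloc[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = list(variables)
    r_df = pd.DataFrame(r, index=idx, columns=idx)
    p_df = pd.DataFrame(p, index=idx, columns=idx)
    stars = p_df.map(convention.star)
    np.fill_diagonal(stars.values, "")
    return CorrelationMatrix(tuple(variables), r_df, p_df, stars)


def fit_linear(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame,
    response: str | None = None,
) -> PredictionEquation:
    """Ordinary least squares of ``y`` on the named predictor columns.

    The intercept is always included.  ``rmse = sqrt(SSE / (n - k - 1))``;
    ``model_p`` is the overall F-test p-value.
    """
    y = pd.Series(np.asarray(y, dtype=float), name=getattr(y, "name", None))
    n, k = len(X), X.shape[1]
    if n <= k + 1:
        raise InsufficientDataError(
            f"need n > k + 1 observations (n={n}, k={k})"
        )
    design = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise CollinearityError(
            f"rank-deficient design with predictors {list(X.columns)}"
        )
    res = sm.OLS(y.to_numpy(), design).fit()
    return PredictionEquation(
        response=response or (y.name or "y"),
        intercept=float(res.params["const"]),
        coefficients={c: float(res.params[c]) for c in X.columns},
        r2=float(res.rsquared),
        rmse=float(np.sqrt(res.mse_resid)),
        model_p=float(res.f_pvalue),
        n=n,
    )


def _rank_key(eq: PredictionEquation) -> tuple:
    # r2 desc, rmse asc, fewer terms, lexicographic predictor names
    return (-eq.r2, eq.rmse, len(eq.coefficients), tuple(sorted(eq.coefficients)))


def stepwise_select(
    y: pd.Series | np.ndarray,
    candidates: pd.DataFrame,
    *,
    max_terms: int = 2,
    method: str = "best_subset",
    entry_p: float = 0.15,
    stay_p: float = 0.15,
    response: str | None = None,
) -> list[PredictionEquation]:
    """Rank candidate prediction equations for ``y``.

    ``method="best_subset"`` (default) enumerates every predictor subset of
    size 1..``max_terms`` and ranks the fits by R² descending then RMSE
    ascending (ties: fewer terms, then predictor names).  ``method="forward"``
    is classical forward stepwise with significance thresholds ``entry_p`` /
    ``stay_p`` and returns the single selected model's path-final equation
    first, followed by the best-subset ranking of the remaining fits.
    """
    if candidates.shape[1] == 0:
        raise ConfigError("empty candidate set")
    if method not in ("best_subset", "forward"):
        raise ConfigError(f"unknown selection method {method!r}")
    names = list(candidates.columns)
    fits: list[PredictionEquation] = []
    for size in range(1, min(max_terms, len(names)) + 1):
        for combo in combinations(names, size):
            try:
                fits.append(
                    fit_linear(y, candidates[list(combo)], response=response)
                )
            except CollinearityError:
                continue
    fits.sort(key=_rank_key)
    if method == "best_subset":
        return fits
    selected = _forward_stepwise(y, candidates, max_terms, entry_p, stay_p,
                                 response)
    rest = [f for f in fits if set(f.coefficients) != set(selected.coefficients)]
    return [selected, *rest]


def _forward_stepwise(y, candidates, max_terms, entry_p, stay_p, response):
    chosen: list[str] = []
    remaining = list(candidates.columns)
    while remaining and len(chosen) < max_terms:
        best_name, best_p = None, entry_p
        for name in remaining:
            res = sm.OLS(
                np.asarray(y, float),
                sm.add_constant(candidates[chosen + [name]].astype(float)),
            ).fit()
            pv = float(res.pvalues[name])
            if pv < best_p:
                best_name, best_p = name, pv
        if best_name is None:
            break
        chosen.append(best_name)
        remaining.remove(best_name)
        # backward pass: drop terms that no longer stay
        while True:
            res = sm.OLS(
                np.asarray(y, float),
                sm.add_constant(candidates[chosen].astype(float)),
            ).fit()
            worst = max(chosen, key=lambda c: float(res.pvalues[c]))
            if float(res.pvalues[worst]) >= stay_p and len(chosen) > 1:
                chosen.remove(worst)
                if worst not in remaining:
                    remaining.append(worst)
            else:
                break
    if not chosen:
        chosen = [candidates.columns[0]]
    return fit_linear(y, candidates[chosen], response=response)


def predict(
    eq: PredictionEquation,
    comp: IngredientComposition | Mapping[str, float],
) -> float:
    """Apply a prediction equation to a composition or plain mapping.

    Compositions must be on a dry-matter basis (equations are fitted on DM
    values).  Raises :class:`SchemaError` naming any missing predictor.
    """
    if isinstance(comp, IngredientComposition):
        if comp.basis is not Basis.DRY_MATTER:
            raise SchemaError(
                "composition must be on dry-matter basis; use convert_basis"
            )
        values = {"GE": comp.ge, "DM": comp.dm_pct, **comp.analytes}
    else:
        values = dict(comp)
    total = eq.intercept
    for name, coef in eq.coefficients.items():
        if name not in values:
            raise SchemaError(f"missing predictor {name!r}")
        total += coef * values[name]
    return total
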