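"""Fixed- and random-intercept linear models with backward stepwise AIC.

"GLM" here is a Gaussian-identity linear model fitted by least squares on
transformed variables; the mixed model adds a random intercept per
population fitted by REML (ML during stepwise comparison so AIC values
are comparable across fixed-effect specifications).  Mixed-model p-values
use the normal approximation for fixed effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .transforms import TransformedVariable


@dataclass(frozen=True)
class AssociationResult:
    response: str
    terms: tuple[str, ...]
    estimates: dict[str, float]
    pvalues: dict[str, float]
    adj_r2: float
    model_kind: str  # "fixed_only" | "random_intercept_population"
    aic: float
    n: int
    metadata: dict = field(default_factory=dict)


def _column(var) -> tuple[str, np.ndarray]:
    if isinstance(var, TransformedVariable):
        return var.name, np.asarray(var.transformed, dtype=float)
    name, values = var
    return name, np.asarray(values, dtype=float)


def _design(
    response, predictors: Sequence, population
) -> tuple[str, pd.DataFrame, pd.Series, pd.Series | None]:
    y_name, y = _column(response)
    cols = {}
    for pred in predictors:
        name, values = _column(pred)
        if name in cols or name == y_name:
            raise ValueError(f"duplicate variable name {name!r}")
        cols[name] = values
    frame = pd.DataFrame(cols)
    frame[y_name] = y
    groups = None
    if population is not None:
        groups = pd.Series(np.asarray(population), name="population")
        frame["__group__"] = groups.to_numpy()
    frame = frame.dropna()
    if population is not None:
        groups = frame.pop("__group__")
    y_clean = frame.pop(y_name)
    return y_name, frame, y_clean, groups


def _check_rank(x: pd.DataFrame) -> None:
    mat = sm.add_constant(x, has_constant="add").to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        collinear = []
        for name in x.columns:
            reduced = sm.add_constant(x.drop(columns=[name])).to_numpy()
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(name)
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")


def fit_association(
    response,
    predictors: Sequence,
    population=None,
    reml: bool = True,
) -> AssociationResult:
    """Fit a linear (or random-intercept) association model.

    Parameters
    ----------
    response, predictors
        :class:`TransformedVariable` objects or ``(name, values)`` pairs.
    population
        Optional grouping vector; when given, a random intercept per
        population is fitted (REML by default).

    Complete cases only; requires at least 3 more cases than estimated
    mean parameters.  The adjusted R-squared is reported for the fixed
    model and is NaN for the mixed model.
    """
    y_name, x, y, groups = _design(response, predictors, population)
    k = x.shape[1]
    n = len(y)
    if n < k + 1 + 3:
        raise ValueError(
            f"too few complete cases (n={n}) for {k} predictors"
        )
    if k:
        _check_rank(x)

    exog = sm.add_constant(x, has_constant="add")
    if population is None:
        fit = sm.OLS(y, exog).fit()
        estimates = {t: float(fit.params[t]) for t in exog.columns}
        pvalues = {t: float(fit.pvalues[t]) for t in exog.columns}
        adj_r2 = float(fit.rsquared_adj)
        aic = float(fit.aic)
        meta = {"df_method": "t", "estimator": "ols"}
        kind = "fixed_only"
    else:
        model = sm.MixedLM(y, exog, groups=groups)
        try:
            fit = model.fit(reml=reml)
        except Exception:  # noqa: BLE001 — fall back to a derivative-free optimizer
            fit = model.fit(reml=reml, method="powell")
        estimates = {t: float(fit.fe_params[t]) for t in exog.columns}
        pvalues = {t: float(fit.pvalues[t]) for t in exog.columns}
        adj_r2 = math.nan
        # statsmodels leaves aic undefined under REML; compute from llf
        n_par = len(exog.columns) + 1  # fixed effects + group variance
        aic = float(-2.0 * fit.llf + 2.0 * n_par)
        meta = {
            "df_method": "normal_approximation",
            "estimator": "reml" if reml else "ml",
            "group_var": float(fit.cov_re.iloc[0, 0]),
        }
        kind = "random_intercept_population"
    return AssociationResult(
        response=y_name,
        terms=tuple(x.columns),
        estimates=estimates,
        pvalues=pvalues,
        adj_r2=adj_r2,
        model_kind=kind,
        aic=aic,
        n=n,
        metadata=meta,
    )


def stepwise_aic(
    response,
    predictors: Sequence,
    population=None,
) -> AssociationResult:
    """Backward elimination on AIC.

    Starting from the full model, repeatedly drop the single term whose
    removal most decreases AIC; stop when no removal decreases it.  Mixed
    models are compared under ML.  The elimination path is recorded in
    ``metadata["elimination_path"]``; the final model's AIC is never above
    the full model's.
    """
    preds = {(_column(p)[0]): p for p in predictors}
    reml = False  # ML so AIC comparisons across fixed specs are valid
    current = fit_association(
        response, list(preds.values()), population=population, reml=reml
    )
    path: list[dict] = [{"dropped": None, "aic": current.aic}]
    while preds:
        candidates = []
        for name in preds:
            trial = fit_association(
                response,
                [p for t, p in preds.items() if t != name],
                population=population,
                reml=reml,
            )
            candidates.append((trial.aic, name, trial))
        best_aic, best_name, best_fit = min(candidates, key=lambda c: (c[0], c[1]))
        if best_aic >= current.aic:
            break
        del preds[best_name]
        current = best_fit
        path.append({"dropped": best_name, "aic": current.aic})
    current.metadata["elimination_path"] = path
    return current
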