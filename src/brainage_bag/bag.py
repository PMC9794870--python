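"""Age-bias correction, brain age gap (BAG) and risk-factor associations.

Age-regression models systematically overpredict young and underpredict old
subjects.  The standard linear correction fits, on each fold's validation
set, the regression ``predicted = alpha * chronological + beta`` and then
shifts each test prediction by the age-dependent residual::

    corrected = predicted + [chronological - (alpha * chronological + beta)]

The BAG is ``corrected predicted age - chronological age``, computed only
for test subjects (never involved in training or in fitting alpha/beta).

Associations are per risk factor and per model: OLS of the BAG on
chronological age, sex (0 female / 1 male) and the z-scored risk factor,
with the factor coefficient's p-values corrected for false discovery rate
(Benjamini-Hochberg) over the whole model x factor family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = ["BiasParams", "fit_bias", "correct", "compute_bag",
           "AssociationResult", "associate", "fdr_correct", "associate_all"]


@dataclass
class BiasParams:
    """Slope/intercept of predicted-on-chronological OLS, fitted on one
    fold's validation subjects for one model."""

    alpha: float
    beta: float
    fold: int | None = None
    model: str | None = None


def fit_bias(val_predictions: np.ndarray, val_ages: np.ndarray,
             fold: int | None = None, model: str | None = None) -> BiasParams:
    """OLS of predicted age on chronological age over validation subjects."""
    pred = np.asarray(val_predictions, float)
    age = np.asarray(val_ages, float)
    if len(age) < 3:
        raise ValueError("need at least 3 validation subjects")
    if np.var(age) == 0:
        raise ValueError("validation ages have zero variance; cannot fit bias")
    alpha, beta = np.polyfit(age, pred, 1)
    return BiasParams(float(alpha), float(beta), fold, model)


def correct(test_predictions: np.ndarray, test_ages: np.ndarray,
            params: BiasParams) -> np.ndarray:
    """Bias-corrected predictions:
    ``predicted + [age - (age * alpha + beta)]`` per subject."""
    pred = np.asarray(test_predictions, float)
    age = np.asarray(test_ages, float)
    return pred + (age - (age * params.alpha + params.beta))


def compute_bag(corrected_predictions: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Brain age gap: corrected predicted age minus chronological age."""
    return np.asarray(corrected_predictions, float) - np.asarray(ages, float)


@dataclass
class AssociationResult:
    """One multiple regression ``BAG ~ age + sex + z(factor)``."""

    model: str
    factor: str
    beta_age: float
    beta_sex: float
    beta_factor: float
    se_age: float
    se_sex: float
    se_factor: float
    p_factor: float
    q_factor: float | None = None
    n: int = 0


def associate(
    bag: np.ndarray,
    cohort: pd.DataFrame,
    factor: str,
    model: str = "model",
) -> AssociationResult:
    """OLS of the BAG on chronological age, sex and the standardized factor.

    The risk factor is z-scored (mean 0, sd 1) over the analysis subjects so
    coefficients are comparable across factors; the two-sided p-value refers
    to the factor coefficient.  ``cohort`` rows must align with ``bag``.
    """
    bag = np.asarray(bag, float)
    if len(bag) != len(cohort):
        raise ValueError("bag vector and cohort table must align")
    x = cohort[factor].to_numpy(float)
    if np.std(x) == 0:
        raise ValueError(f"risk factor {factor!r} has zero variance")
    z = (x - x.mean()) / x.std()
    X = sm.add_constant(np.column_stack([
        cohort["age"].to_numpy(float),
        cohort["sex"].to_numpy(float),
        z,
    ]))
    fit = sm.OLS(bag, X).fit()
    return AssociationResult(
        model=model, factor=factor,
        beta_age=float(fit.params[1]), beta_sex=float(fit.params[2]),
        beta_factor=float(fit.params[3]),
        se_age=float(fit.bse[1]), se_sex=float(fit.bse[2]),
        se_factor=float(fit.bse[3]),
        p_factor=float(fit.pvalues[3]),
        n=len(bag),
    )


def fdr_correct(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over one test family."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=alpha, method="fdr_bh")[1]


def associate_all(
    bags: dict[str, np.ndarray],
    cohort: pd.DataFrame,
    factors: tuple[str, ...] = ("bp", "bmi", "whr", "smoking", "alcohol"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All model x factor associations with a joint BH family (default
    4 models x 5 factors = 20 tests)."""
    results = [associate(bags[m], cohort, f, model=m) for m in bags for f in factors]
    q = fdr_correct([r.p_factor for r in results], alpha=alpha)
    rows = []
    for r, qv in zip(results, q):
        r.q_factor = float(qv)
        rows.append((r.model, r.factor, r.beta_age, r.beta_sex, r.beta_factor,
                     r.se_factor, r.p_factor, r.q_factor, r.q_factor < alpha, r.n))
    return pd.DataFrame(rows, columns=[
        "model", "factor", "beta_age", "beta_sex", "beta_factor",
        "se_factor", "p", "q", "significant", "n",
    ])
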