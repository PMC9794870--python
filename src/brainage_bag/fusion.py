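"""Stacked fusion of age predictors and paired model comparison.

Individual models are combined by regressing chronological age on their
validation-set predictions (ordinary least squares with an optional
intercept), separately per cross-validation fold; the fitted weights are
then applied to the fold's test predictions.  Reporting the coefficients
divided by their sum ("normalized shares") makes the relative contribution
of each model comparable across stacks; shares always sum to 1 and can be
negative.  Pairs of models are compared with two-sided Wilcoxon signed-rank
tests on per-subject absolute errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["StackWeights", "fit_stack", "apply_stack", "compare_abs_errors"]

#: Condition number above which the stacking design is flagged collinear.
COLLINEARITY_THRESHOLD = 1e8


@dataclass
class StackWeights:
    """OLS stacking weights for one fold: one coefficient per input model,
    an intercept, and coefficient shares normalized by the coefficient sum
    (intercept excluded)."""

    model_ids: tuple[str, ...]
    intercept: float
    coefs: np.ndarray
    fold: int | None = None
    shares: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        total = self.coefs.sum()
        self.shares = self.coefs / total if total != 0 else np.full_like(self.coefs, np.nan)

    def to_dict(self) -> dict:
        return {
            "fold": self.fold,
            "model_ids": list(self.model_ids),
            "intercept": float(self.intercept),
            "coefs": [float(c) for c in self.coefs],
            "shares": [float(s) for s in self.shares],
        }


def fit_stack(
    val_predictions: dict[str, np.ndarray],
    val_ages: np.ndarray,
    fold: int | None = None,
    include_intercept: bool = True,
) -> StackWeights:
    """OLS of chronological age on the models' validation predictions.

    All models must predict the same validation subjects, in the same order.
    A collinear design (condition number above ``COLLINEARITY_THRESHOLD``)
    triggers a warning and the minimum-norm (pseudo-inverse) solution is
    returned.
    """
    model_ids = tuple(val_predictions)
    P = np.column_stack([np.asarray(val_predictions[m], float) for m in model_ids])
    y = np.asarray(val_ages, float)
    if P.shape[0] != len(y):
        raise ValueError("prediction and age vectors differ in length")
    X = np.column_stack([np.ones(len(y)), P]) if include_intercept else P
    if np.linalg.cond(X) > COLLINEARITY_THRESHOLD:
        warnings.warn(
            "collinear model predictions in stacking design; "
            "returning the minimum-norm least-squares solution"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    if include_intercept:
        intercept, coefs = float(beta[0]), beta[1:]
    else:
        intercept, coefs = 0.0, beta
    return StackWeights(model_ids, intercept, coefs, fold)


def apply_stack(weights: StackWeights, predictions: dict[str, np.ndarray]) -> np.ndarray:
    """Linear combination ``intercept + sum(coef * prediction)`` per subject;
    the model set and order must match the fitted stack."""
    if tuple(predictions) != weights.model_ids:
        raise ValueError(
            f"model set mismatch: stack fitted on {weights.model_ids}, "
            f"got {tuple(predictions)}"
        )
    P = np.column_stack([np.asarray(predictions[m], float) for m in weights.model_ids])
    return weights.intercept + P @ weights.coefs


def compare_abs_errors(errors_a: np.ndarray, errors_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired absolute errors.

    Zero differences are dropped; the exact signed-rank distribution is used
    for n <= 25 remaining pairs, a normal approximation with tie-corrected
    variance otherwise.  If every difference is zero the models are
    indistinguishable and p = 1 is returned with a warning.
    """
    a = np.abs(np.asarray(errors_a, float))
    b = np.abs(np.asarray(errors_b, float))
    if a.shape != b.shape:
        raise ValueError("paired error vectors must have the same length")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired absolute-error differences are zero; p = 1")
        return 1.0
    n_nonzero = int(np.sum(d != 0))
    method = "exact" if n_nonzero <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method=method)
    return float(res.pvalue)
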