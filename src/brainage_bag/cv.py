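"""Age-stratified cross-validation, null model and evaluation metrics.

The evaluation protocol: 5-fold cross-validation with test folds balanced
over age (subjects are sorted into age-quantile bins and dealt round-robin),
plus a validation set per fold -- 15 % of the whole cohort, drawn
age-stratified from the fold's training portion -- used for checkpointing,
stacking and bias-parameter estimation.  A null model predicting the
training-mean age everywhere provides the reference error.

Metrics per model: mean absolute error (years), Pearson correlation between
chronological and predicted age, and the age-related bias
``corr(predicted - chronological, chronological)`` -- negative when young
subjects are overpredicted and old subjects underpredicted, the typical
regression-to-the-mean signature of age models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FoldPlan", "Metrics", "plan_folds", "null_model",
           "compute_metrics", "evaluate"]


@dataclass
class FoldPlan:
    """Test-fold assignment per subject plus per-fold validation draws.

    ``test_fold`` maps subject_id -> fold index; ``validation`` maps fold
    index -> list of subject_ids (disjoint from that fold's test set, drawn
    from its training portion).
    """

    k: int
    test_fold: pd.Series  # index: subject_id, value: fold
    validation: dict[int, list[str]] = field(default_factory=dict)

    def test_ids(self, fold: int) -> list[str]:
        return list(self.test_fold.index[self.test_fold == fold])

    def val_ids(self, fold: int) -> list[str]:
        return list(self.validation[fold])

    def train_ids(self, fold: int) -> list[str]:
        """Training subjects: everything outside the fold's test and
        validation sets."""
        excluded = set(self.test_ids(fold)) | set(self.validation[fold])
        return [s for s in self.test_fold.index if s not in excluded]

    def to_frame(self) -> pd.DataFrame:
        """Long-format (fold, subject_id, role) table for serialization."""
        rows = []
        for f in range(self.k):
            test = set(self.test_ids(f))
            val = set(self.val_ids(f))
            for sid in self.test_fold.index:
                role = "test" if sid in test else ("val" if sid in val else "train")
                rows.append((f, sid, role))
        return pd.DataFrame(rows, columns=["fold", "subject_id", "role"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FoldPlan":
        k = int(frame["fold"].max()) + 1
        test = frame[frame["role"] == "test"].set_index("subject_id")["fold"]
        val = {f: list(frame[(frame["fold"] == f) & (frame["role"] == "val")]["subject_id"])
               for f in range(k)}
        return cls(k, test, val)


def _age_bins(ages: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count age bins via rank; returns a bin index per subject."""
    order = np.argsort(ages, kind="stable")
    bins = np.empty(len(ages), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def plan_folds(
    cohort: pd.DataFrame,
    k: int = 5,
    val_frac: float = 0.15,
    n_bins: int = 10,
    seed: int = 0,
) -> FoldPlan:
    """Age-stratified fold plan.

    Subjects are sorted into ``n_bins`` age-quantile bins; within each bin
    they are shuffled and dealt round-robin to the ``k`` test folds (a global
    deal counter keeps fold sizes within one subject of each other).  For
    each fold, ``round(val_frac * n)`` validation subjects are then drawn
    from the training portion, allocated over age bins by largest remainder
    so the validation set matches the cohort's age profile.
    """
    n = len(cohort)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} subjects")
    if n < k * n_bins:
        raise ValueError(f"need at least k*n_bins={k * n_bins} subjects, got {n}")
    rng = np.random.default_rng(seed)
    ages = cohort["age"].to_numpy(float)
    ids = cohort["subject_id"].to_numpy()
    bins = _age_bins(ages, n_bins)

    fold_of = np.empty(n, dtype=int)
    counter = rng.integers(0, k)  # global round-robin counter
    for b in range(n_bins):
        members = np.flatnonzero(bins == b)
        members = members[rng.permutation(len(members))]
        for m in members:
            fold_of[m] = counter % k
            counter += 1
    test_fold = pd.Series(fold_of, index=ids)

    n_val = int(round(val_frac * n))
    validation: dict[int, list[str]] = {}
    for f in range(k):
        train_mask = fold_of != f
        # proportional allocation over age bins, largest remainder
        counts = np.array([np.sum(train_mask & (bins == b)) for b in range(n_bins)])
        quota = n_val * counts / counts.sum()
        take = np.floor(quota).astype(int)
        rem = n_val - take.sum()
        for b in np.argsort(-(quota - take))[:rem]:
            take[b] += 1
        chosen: list[str] = []
        for b in range(n_bins):
            cand = np.flatnonzero(train_mask & (bins == b))
            cand = cand[rng.permutation(len(cand))]
            chosen.extend(ids[cand[: take[b]]])
        validation[f] = chosen
    return FoldPlan(k, test_fold, validation)


def null_model(train_ages: np.ndarray, test_ages: np.ndarray) -> np.ndarray:
    """Baseline: predict the training-mean age for every test subject."""
    train_ages = np.asarray(train_ages, float)
    if len(train_ages) == 0:
        raise ValueError("null model needs a nonempty training set")
    return np.full(len(test_ages), train_ages.mean())


@dataclass
class Metrics:
    mae: float
    pearson_r: float
    bias_r: float


def compute_metrics(age: np.ndarray, predicted: np.ndarray) -> Metrics:
    """MAE, Pearson r(age, predicted) and age-related bias
    r(predicted - age, age).

    Conventions for degenerate inputs: constant predictions make Pearson r
    undefined (NaN, with a warning); a constant brain-age gap (e.g. perfect
    predictions) makes the bias correlation undefined and is reported as 0.
    """
    age = np.asarray(age, float)
    predicted = np.asarray(predicted, float)
    if len(age) < 3:
        raise ValueError("need at least 3 subjects to compute metrics")
    mae = float(np.mean(np.abs(predicted - age)))
    if np.std(predicted) == 0 or np.std(age) == 0:
        warnings.warn("zero-variance predictions: Pearson r undefined (NaN)")
        r = float("nan")
    else:
        r = float(stats.pearsonr(age, predicted).statistic)
    gap = predicted - age
    if np.std(gap) == 0:
        bias = 0.0
    else:
        bias = float(stats.pearsonr(gap, age).statistic)
    return Metrics(mae, r, bias)


def evaluate(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-fold metrics plus their mean and sd across folds.

    ``predictions`` needs columns ``age``, ``predicted`` and ``fold``.
    Returns a table indexed by fold with a trailing ``mean`` / ``sd`` pair,
    invariant to subject ordering.
    """
    rows = {}
    for f, grp in predictions.groupby("fold"):
        m = compute_metrics(grp["age"].to_numpy(), grp["predicted"].to_numpy())
        rows[f] = (m.mae, m.pearson_r, m.bias_r)
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["mae", "pearson_r", "bias_r"]).sort_index()
    table.loc["mean"] = table.mean()
    table.loc["sd"] = table.iloc[:-1].std(ddof=1) if len(rows) > 1 else 0.0
    return table
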