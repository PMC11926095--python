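"""Holdout prediction experiments, accuracy metrics and dimension selection.

The model's predictive value is measured by hiding a fraction of the
observed (student, task, score) links, fitting on the rest, and predicting
the hidden quintiles. Two accuracies are reported: exact (predicted modal
quintile equals the observed one) and one-off (within one quintile). A
per-task mode predictor provides the ordering baseline.

Model dimensions (K student groups, L task groups) are chosen by exhaustive
grid search on holdout exact accuracy with a one-standard-error parsimony
rule: among grid points whose mean accuracy is within one standard error of
the grid maximum, the smallest K + L wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._rng import rng_for
from .mmsbm import MixedMembershipSBM, MMSBMParams, predict as _predict
from .ratings import RatingsTable

__all__ = [
    "HoldoutSplit",
    "make_holdout_splits",
    "exact_accuracy",
    "one_off_accuracy",
    "TaskModeBaseline",
    "baseline_mode_predictor",
    "select_dimensions",
    "discrepancy_profile",
    "run_prediction_experiment",
]


@dataclass(frozen=True)
class HoldoutSplit:
    """A train/test partition of the observed links.

    Train and test share the parent table's full user/task index, so users
    or tasks left without training links survive (the model gives them
    uniform memberships rather than failing).
    """

    train: RatingsTable
    test: RatingsTable
    hide_fraction: float
    index: int
    seed: int


def make_holdout_splits(
    ratings: RatingsTable,
    hide_fraction: float,
    n_splits: int = 20,
    seed: int = 0,
) -> list:
    """Random link partitions hiding ``hide_fraction`` of the links per split."""
    if not 0 < hide_fraction < 1:
        raise ValueError("hide_fraction must be in (0, 1)")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    n = ratings.n_links
    n_test = int(round(hide_fraction * n))
    if n_test >= n:
        raise ValueError("hide_fraction would empty the training set")
    splits = []
    for i in range(n_splits):
        rng = rng_for(seed, "split", i)
        test_idx = rng.choice(n, size=n_test, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        splits.append(
            HoldoutSplit(
                train=ratings.subset(~mask),
                test=ratings.subset(mask),
                hide_fraction=hide_fraction,
                index=i,
                seed=seed,
            )
        )
    return splits


def _check_aligned(predictions, truth):
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {predictions.shape} predictions vs "
            f"{truth.shape} truths"
        )
    return predictions, truth


def exact_accuracy(predictions, truth) -> float:
    """Fraction of predictions equal to the observed quintile."""
    predictions, truth = _check_aligned(predictions, truth)
    return float((predictions == truth).mean())


def one_off_accuracy(predictions, truth) -> float:
    """Fraction of predictions within one quintile of the observed score."""
    predictions, truth = _check_aligned(predictions, truth)
    return float((np.abs(predictions - truth) <= 1).mean())


class TaskModeBaseline(BaseEstimator):
    """Per-task most-frequent-score predictor.

    Ties break toward the lower score; tasks unseen in training fall back to
    the global training mode. This is the naive ordering baseline for the
    prediction experiments.
    """

    def fit(self, X, y=None) -> "TaskModeBaseline":
        table = X if isinstance(X, RatingsTable) else MixedMembershipSBM._as_table(X)
        if table.n_links == 0:
            raise ValueError("cannot fit on an empty ratings table")
        global_counts = np.bincount(table.s, minlength=6)[1:]
        self.global_mode_ = int(np.argmax(global_counts) + 1)
        self.task_mode_ = {}
        for j, tid in enumerate(table.tasks):
            scores = table.s[table.t == j]
            if scores.size:
                counts = np.bincount(scores, minlength=6)[1:]
                self.task_mode_[tid] = int(np.argmax(counts) + 1)
        self.tasks_ = table.tasks
        return self

    def predict_pair(self, user_id, task_id) -> int:
        return self.task_mode_.get(task_id, self.global_mode_)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, RatingsTable):
            task_ids = X.tasks[X.t]
        elif isinstance(X, pd.DataFrame):
            task_ids = X["task_id"].to_numpy()
        else:
            task_ids = np.asarray(X, dtype=object)[:, 1]
        return np.array(
            [self.task_mode_.get(t, self.global_mode_) for t in task_ids]
        )


def baseline_mode_predictor(train: RatingsTable) -> TaskModeBaseline:
    """Fit the per-task mode baseline on a training table."""
    return TaskModeBaseline().fit(train)


def select_dimensions(
    ratings: RatingsTable,
    K_range,
    L_range,
    seed: int = 0,
    hide_fraction: float = 0.4,
    n_splits: int = 5,
    n_restarts: int = 2,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> tuple[int, int, pd.DataFrame]:
    """Grid search over (K, L) with a one-standard-error parsimony rule.

    The criterion is mean exact accuracy on ``hide_fraction``-holdout
    splits (the same splits for every grid point). Among grid points whose
    mean is within one standard error of the grid maximum, the smallest
    K + L is returned (ties toward smaller K, then L). Returns
    (K*, L*, table) where the table has one row per grid point.
    """
    K_range = sorted(set(int(k) for k in K_range))
    L_range = sorted(set(int(l) for l in L_range))
    if not K_range or not L_range:
        raise ValueError("empty K or L range")
    splits = make_holdout_splits(
        ratings, hide_fraction, n_splits=n_splits, seed=rng_for(seed, "sel").integers(2**31)
    )
    rows = []
    for K in K_range:
        for L in L_range:
            accs = []
            for sp in splits:
                model = MixedMembershipSBM(
                    K,
                    L,
                    tol=tol,
                    max_iter=max_iter,
                    n_restarts=n_restarts,
                    random_state=rng_for(seed, "fit", K, L, sp.index).integers(2**31),
                ).fit(sp.train)
                _, modal = _predict(model.params_, sp.test.u, sp.test.t)
                accs.append(exact_accuracy(modal, sp.test.s))
            accs = np.asarray(accs)
            rows.append(
                {
                    "K": K,
                    "L": L,
                    "mean_accuracy": float(accs.mean()),
                    "se": float(accs.std(ddof=1) / np.sqrt(accs.size))
                    if accs.size > 1
                    else 0.0,
                    "n_splits": int(accs.size),
                }
            )
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_accuracy"].idxmax()]
    threshold = best["mean_accuracy"] - best["se"]
    ok = table[table["mean_accuracy"] >= threshold].copy()
    ok["complexity"] = ok["K"] + ok["L"]
    ok = ok.sort_values(["complexity", "K", "L"])
    chosen = ok.iloc[0]
    return int(chosen["K"]), int(chosen["L"]), table


def discrepancy_profile(
    params: MMSBMParams,
    ratings: RatingsTable,
    threshold: int = 2,
) -> tuple[pd.Series, float]:
    """Per-student count of tasks where the model misses by >= ``threshold``.

    A task is "high discrepancy" for a student when the absolute difference
    between the observed quintile and the modal predicted quintile is at
    least ``threshold`` (2 quintiles by default). Returns the per-student
    counts (indexed by user id, zero for students with no flagged task) and
    the fraction of flagged students (count >= 1) whose count is at most 2.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    _, modal = _predict(params, ratings.u, ratings.t)
    high = np.abs(modal - ratings.s) >= threshold
    counts = np.zeros(ratings.n_users, dtype=int)
    np.add.at(counts, ratings.u[high], 1)
    series = pd.Series(counts, index=pd.Index(ratings.users, name="user_id"))
    flagged = series[series >= 1]
    frac_at_most_two = float((flagged <= 2).mean()) if len(flagged) else np.nan
    return series, frac_at_most_two


def run_prediction_experiment(
    ratings: RatingsTable,
    hide_fractions=(0.4, 0.6, 0.8),
    n_splits: int = 20,
    seed: int = 0,
    K: int = 3,
    L: int = 3,
    n_restarts: int = 3,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> pd.DataFrame:
    """MMSBM vs per-task-mode baseline across hide fractions and splits.

    Returns a tidy DataFrame (fraction, split, method, exact, one_off).
    """
    rows = []
    for frac in hide_fractions:
        splits = make_holdout_splits(
            ratings, frac, n_splits=n_splits, seed=rng_for(seed, "ho", frac).integers(2**31)
        )
        for sp in splits:
            model = MixedMembershipSBM(
                K,
                L,
                tol=tol,
                max_iter=max_iter,
                n_restarts=n_restarts,
                random_state=rng_for(seed, "em", frac, sp.index).integers(2**31),
            ).fit(sp.train)
            _, modal = _predict(model.params_, sp.test.u, sp.test.t)
            baseline = baseline_mode_predictor(sp.train)
            base_pred = baseline.predict(sp.test)
            for method, pred in (("mmsbm", modal), ("task_mode", base_pred)):
                rows.append(
                    {
                        "fraction": frac,
                        "split": sp.index,
                        "method": method,
                        "exact": exact_accuracy(pred, sp.test.s),
                        "one_off": one_off_accuracy(pred, sp.test.s),
                    }
                )
    return pd.DataFrame(rows)
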