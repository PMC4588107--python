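"""Cross-validated accuracy estimation, exhaustive task-subset
personalization, and chance-level confidence limits.

Accuracy is estimated by 10 iterations of stratified 10-fold
cross-validation; feature selection and classifier training happen strictly
inside each training fold. Personalization evaluates every C(6, n) task
subset for a class count n and picks the subset with the highest mean
accuracy. A classifier beats chance when its accuracy exceeds the upper
Clopper-Pearson limit of the binomial interval around the theoretical chance
level at the available trial count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.proportion import proportion_confint

from .classifier import MulticlassModel
from .features import FeatureMatrix


class EvaluationError(ValueError):
    pass


@dataclass
class CVResult:
    """Cross-validation outcome for one task subset."""

    tasks: tuple[str, ...]
    fold_accuracies: np.ndarray  # one per fold over all iterations, in %
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def n_folds(self) -> int:
        return len(self.fold_accuracies)


def cross_validate(
    features: FeatureMatrix,
    tasks,
    seed: int = 0,
    n_iterations: int = 10,
    n_folds: int = 10,
    delta: float = 0.0,
    n_bins: int = 10,
) -> CVResult:
    """Stratified ``n_iterations x n_folds`` cross-validation of the
    one-vs-one voting classifier on a task subset.

    Each iteration reshuffles the stratified folds with a seed derived from
    ``seed``. Selection and training see only the training folds. Requires at
    least ``n_folds`` epochs per class so every fold holds each class.
    """
    tasks = tuple(tasks)
    sub = features.subset(tasks)
    y = sub.labels["task"].to_numpy()
    counts = {t: int((y == t).sum()) for t in tasks}
    low = {t: c for t, c in counts.items() if c < n_folds}
    if low:
        raise EvaluationError(
            f"classes with fewer than {n_folds} epochs: {low}"
        )
    accs = []
    for it in range(n_iterations):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=(seed * 1009 + it) % (2**31))
        for train, test in skf.split(np.zeros(len(y)), y):
            model = MulticlassModel(tasks=tasks)
            model.fit({k: v[train] for k, v in sub.X.items()}, y[train],
                      seed=(seed * 9176 + it) % (2**31), delta=delta, n_bins=n_bins)
            pred = model.predict({k: v[test] for k, v in sub.X.items()})
            accs.append(100.0 * float(np.mean(pred == y[test])))
    return CVResult(tasks=tasks, fold_accuracies=np.asarray(accs), seed=seed)


@dataclass
class PersonalizationResult:
    """Best task subset and per-subset accuracy table for one class count."""

    n_classes: int
    results: list[CVResult]
    seed: int

    @property
    def best(self) -> CVResult:
        # ties: highest accuracy, then lexicographically smallest subset
        return min(self.results, key=lambda r: (-r.mean_accuracy, r.tasks))

    @property
    def best_tasks(self) -> tuple[str, ...]:
        return self.best.tasks

    @property
    def best_accuracy(self) -> float:
        return self.best.mean_accuracy

    def table(self):
        import pandas as pd

        return pd.DataFrame({
            "tasks": [" ".join(r.tasks) for r in self.results],
            "mean_accuracy_pct": [r.mean_accuracy for r in self.results],
        }).sort_values("mean_accuracy_pct", ascending=False).reset_index(drop=True)


def personalize(
    features: FeatureMatrix,
    n_classes: int,
    seed: int = 0,
    all_tasks: tuple[str, ...] | None = None,
    **cv_kwargs,
) -> PersonalizationResult:
    """Evaluate every C(len(all_tasks), n) task subset and pick the best.

    With the six-task battery this explores 15, 20, 15, and 6 subsets for
    n = 2, 3, 4, 5.
    """
    if all_tasks is None:
        all_tasks = tuple(sorted(features.labels["task"].unique()))
    if not 2 <= n_classes <= len(all_tasks):
        raise EvaluationError(
            f"class count {n_classes} out of range for {len(all_tasks)} tasks"
        )
    results = [
        cross_validate(features, subset, seed=seed, **cv_kwargs)
        for subset in combinations(all_tasks, n_classes)
    ]
    assert len(results) == comb(len(all_tasks), n_classes)
    return PersonalizationResult(n_classes=n_classes, results=results, seed=seed)


@dataclass(frozen=True)
class ChanceInterval:
    """Binomial confidence limits around the theoretical chance level."""

    n_classes: int
    n_trials: int
    alpha: float
    p0: float  # %
    lower: float  # %
    upper: float  # %

    def exceeds_chance(self, accuracy_pct: float) -> bool:
        return accuracy_pct > self.upper

    def contains(self, accuracy_pct: float) -> bool:
        return self.lower <= accuracy_pct <= self.upper


def chance_interval(
    n_classes: int,
    n_trials: int = 60,
    alpha: float = 0.05,
    method: str = "clopper-pearson",
) -> ChanceInterval:
    """Confidence limits a classifier must exceed to beat chance.

    The chance level is 100/n_classes %. Limits come from the binomial
    interval around ``x = round(p0 * n_trials)`` successes in ``n_trials``
    (per-class trial count, 60 under the default protocol):
    Clopper-Pearson exact by default, Wald normal approximation optionally.
    """
    if n_trials < 1:
        raise EvaluationError("need at least one trial")
    if not 0 < alpha < 1:
        raise EvaluationError("alpha must be in (0, 1)")
    p0 = 1.0 / n_classes
    x = int(round(p0 * n_trials))
    if method == "clopper-pearson":
        lo, hi = proportion_confint(x, n_trials, alpha=alpha, method="beta")
    elif method == "wald":
        lo, hi = proportion_confint(x, n_trials, alpha=alpha, method="normal")
    else:
        raise EvaluationError(f"unknown method {method!r}")
    return ChanceInterval(
        n_classes=n_classes, n_trials=n_trials, alpha=alpha,
        p0=100.0 * p0, lower=100.0 * float(lo), upper=100.0 * float(hi),
    )
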