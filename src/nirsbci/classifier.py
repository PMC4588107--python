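"""Bagged-LDA ensembles, tri-ensemble binary voting, and one-vs-one
multiclass voting.

Each binary task-pair unit holds three bagging ensembles — one per feature
set (temporal, spatial, combined) — each with 10 pooled-covariance linear
discriminant members trained on bootstrap resamples; feature selection is
refit per unit and per feature set on that unit's training data. A binary
prediction is the majority of the three ensemble outputs (3 voters, 2
labels: never tied). An n-class prediction tallies the C(n, 2) binary
winners and returns the plurality class, breaking ties by the lowest task
index among the tied classes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .features import FEATURE_SETS
from .selection import fcbf


class ClassifierError(ValueError):
    pass


class LinearDiscriminant:
    """Two-class pooled-covariance LDA.

    The pooled within-class covariance gets a small ridge,
    ``gamma * trace(S)/p * I`` (default gamma 1e-6), so the discriminant
    stays defined on tiny folds where few selected features can make S
    singular. ``decision_function`` is positive for the second class in
    sorted label order.
    """

    def __init__(self, gamma: float = 1e-6):
        self.gamma = gamma
        self.classes_: np.ndarray | None = None
        self.coef_: np.ndarray | None = None
        self.intercept_: float | None = None

    def fit(self, X: np.ndarray, y) -> "LinearDiscriminant":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise ClassifierError("non-finite features")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ClassifierError(
                f"LDA requires both classes present, got {self.classes_!r}"
            )
        n = len(y)
        mus, scatter, priors = [], np.zeros((X.shape[1], X.shape[1])), []
        for c in self.classes_:
            Xc = X[y == c]
            mu = Xc.mean(axis=0)
            d = Xc - mu
            scatter += d.T @ d
            mus.append(mu)
            priors.append(len(Xc) / n)
        # MLE normalization (scatter/n): invariant under duplicating the
        # training sample, unlike the unbiased n-2 denominator
        cov = scatter / n
        p = X.shape[1]
        ridge = self.gamma * np.trace(cov) / p
        if ridge <= 0:
            ridge = self.gamma
        cov = cov + ridge * np.eye(p)
        mu0, mu1 = mus
        w = np.linalg.solve(cov, mu1 - mu0)
        self.coef_ = w
        self.intercept_ = float(
            -0.5 * (mu1 + mu0) @ w + np.log(priors[1] / priors[0])
        )
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise ClassifierError("discriminant not fitted")
        return np.atleast_2d(X) @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[(scores > 0).astype(int)]


@dataclass
class BaggedEnsemble:
    """Bootstrap-aggregated LDA ensemble for one feature set.

    Members are trained on seeded bootstrap resamples (same size as the
    training fold, with replacement; resamples missing a class are redrawn).
    Prediction is the member majority; a 5-5 split is broken by the summed
    discriminant score.
    """

    feature_set: str = "temporal"
    n_members: int = 10
    selected: list[int] = field(default_factory=list)
    members: list[LinearDiscriminant] = field(default_factory=list)
    classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y, rng: np.random.Generator,
            max_retries: int = 100) -> "BaggedEnsemble":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ClassifierError("bagging unit requires exactly two classes")
        n = len(y)
        self.members = []
        for _ in range(self.n_members):
            for attempt in range(max_retries):
                idx = rng.integers(0, n, size=n)
                if len(np.unique(y[idx])) == 2:
                    break
            else:
                raise ClassifierError(
                    f"could not draw a bootstrap resample with both classes "
                    f"in {max_retries} tries"
                )
            self.members.append(LinearDiscriminant().fit(X[idx], y[idx]))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.members:
            raise ClassifierError("ensemble not fitted")
        X = np.atleast_2d(X)
        scores = np.stack([m.decision_function(X) for m in self.members])
        votes = (scores > 0).sum(axis=0)
        out = np.where(votes * 2 > self.n_members, 1, 0)
        ties = votes * 2 == self.n_members
        if ties.any():
            out[ties] = (scores.sum(axis=0)[ties] > 0).astype(int)
        return self.classes_[out]


@dataclass
class BinaryUnit:
    """One task-pair classifier: three feature-set ensembles with their own
    FCBF-selected features, fused by majority vote."""

    pair: tuple[str, str]
    ensembles: dict = field(default_factory=dict)

    def fit(self, X_by_set: dict, y, seed: int, delta: float = 0.0,
            n_bins: int = 10) -> "BinaryUnit":
        y = np.asarray(y)
        present = np.unique(y)
        if sorted(present) != sorted(self.pair):
            raise ClassifierError(
                f"unit {self.pair} fitted with labels {present.tolist()}"
            )
        for k, fset in enumerate(FEATURE_SETS):
            if fset not in X_by_set:
                raise ClassifierError(f"missing feature set {fset!r}")
            X = np.asarray(X_by_set[fset], dtype=float)
            selected = fcbf(X, y, delta=delta, n_bins=n_bins)
            ens = BaggedEnsemble(feature_set=fset, selected=selected)
            pair_key = zlib.crc32("|".join(self.pair).encode())
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(pair_key, k))
            )
            ens.fit(X[:, selected], y, rng)
            self.ensembles[fset] = ens
        return self

    def predict(self, X_by_set: dict) -> np.ndarray:
        if len(self.ensembles) != len(FEATURE_SETS):
            raise ClassifierError("binary unit not fitted")
        preds = []
        for fset in FEATURE_SETS:
            ens = self.ensembles[fset]
            X = np.atleast_2d(np.asarray(X_by_set[fset], dtype=float))
            preds.append(ens.predict(X[:, ens.selected]))
        preds = np.stack(preds)  # (3, n)
        a, b = sorted(self.pair)
        n_b = (preds == b).sum(axis=0)
        return np.where(n_b * 2 > preds.shape[0], b, a)


def binary_vote(units_predictions: np.ndarray, pair: tuple[str, str]) -> np.ndarray:
    """Majority vote of three per-feature-set predictions (columns of shape
    (3, n)); exposed for clarity, :meth:`BinaryUnit.predict` uses the same
    rule."""
    preds = np.asarray(units_predictions)
    if preds.shape[0] != 3:
        raise ClassifierError("expected exactly three voters")
    a, b = sorted(pair)
    n_b = (preds == b).sum(axis=0)
    return np.where(n_b * 2 > 3, b, a)


@dataclass
class MulticlassModel:
    """One-vs-one decomposition over a task subset: C(n, 2) binary units."""

    tasks: tuple[str, ...]
    units: dict = field(default_factory=dict)

    def __post_init__(self):
        self.tasks = tuple(self.tasks)
        if len(self.tasks) < 2:
            raise ClassifierError("need at least two tasks")

    @property
    def n_units(self) -> int:
        n = len(self.tasks)
        return n * (n - 1) // 2

    def fit(self, X_by_set: dict, y, seed: int = 0, delta: float = 0.0,
            n_bins: int = 10) -> "MulticlassModel":
        y = np.asarray(y)
        self.units = {}
        for pair in combinations(self.tasks, 2):
            mask = np.isin(y, pair)
            sub = {k: np.asarray(v)[mask] for k, v in X_by_set.items()}
            unit = BinaryUnit(pair=pair)
            unit.fit(sub, y[mask], seed=seed, delta=delta, n_bins=n_bins)
            self.units[pair] = unit
        return self

    def predict(self, X_by_set: dict) -> np.ndarray:
        """Plurality of the binary winners; ties go to the tied task with the
        lowest index in ``self.tasks``."""
        if not self.units:
            raise ClassifierError("model not fitted")
        n = len(np.atleast_2d(next(iter(X_by_set.values()))))
        tally = np.zeros((n, len(self.tasks)), dtype=int)
        task_index = {t: i for i, t in enumerate(self.tasks)}
        for pair, unit in self.units.items():
            winners = unit.predict(X_by_set)
            for t, i in task_index.items():
                tally[:, i] += winners == t
        best = tally.argmax(axis=1)  # argmax takes the first (lowest index) max
        return np.array([self.tasks[i] for i in best])


def ovo_tally(tasks: tuple[str, ...], binary_winners: dict) -> str:
    """Resolve one sample's OVO vote from per-pair winners (for inspection
    and testing of the tie-break rule)."""
    counts = {t: 0 for t in tasks}
    for pair, w in binary_winners.items():
        if w not in pair:
            raise ClassifierError(f"winner {w!r} not in pair {pair!r}")
        counts[w] += 1
    best = max(counts.values())
    for t in tasks:  # lowest task index among tied
        if counts[t] == best:
            return t
    raise ClassifierError("unreachable")
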