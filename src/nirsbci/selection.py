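"""Fast correlation-based filter (FCBF) feature selection.

FCBF ranks features by symmetrical uncertainty (SU) with the class — a
normalized mutual information in [0, 1] — keeps those above a relevance
threshold, and then walks the ranked list removing every feature that is
more strongly associated with an already-kept feature than with the class
(approximate Markov-blanket redundancy pruning). Continuous features are
discretized into equal-width bins fitted on the training data only; test
data never reach selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class DiscretizationSpec:
    """Equal-width binning over the training min/max."""

    n_bins: int = 10

    def __post_init__(self):
        if self.n_bins < 2:
            raise SelectionError("need at least 2 bins")


def discretize(X: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Column-wise equal-width bin codes in 0..n_bins-1 (constant columns
    collapse to a single code)."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0, keepdims=True)
    hi = X.max(axis=0, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    codes = np.floor((X - lo) / span * n_bins).astype(np.int64)
    return np.clip(codes, 0, n_bins - 1)


def _entropy_from_counts(counts: np.ndarray, axis=None) -> np.ndarray:
    n = counts.sum(axis=axis, keepdims=True)
    p = counts / np.where(n > 0, n, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log2(p), 0.0)
    return -term.sum(axis=axis)


def _encode(y) -> np.ndarray:
    _, codes = np.unique(y, return_inverse=True)
    return codes


def symmetrical_uncertainty(x, y) -> float:
    """SU(X, Y) = 2 I(X; Y) / (H(X) + H(Y)), entropies base 2.

    Symmetric; 0 for independent variables, 1 for a deterministic
    relationship. Defined as 0 when both variables are constant.
    """
    x = _encode(x)
    y = _encode(y)
    if len(x) != len(y):
        raise SelectionError("x and y lengths differ")
    if len(x) < 2:
        raise SelectionError("need at least 2 samples")
    nx, ny = x.max() + 1, y.max() + 1
    joint = np.bincount(x * ny + y, minlength=nx * ny).reshape(nx, ny).astype(float)
    hx = _entropy_from_counts(joint.sum(axis=1))
    hy = _entropy_from_counts(joint.sum(axis=0))
    hxy = _entropy_from_counts(joint.reshape(-1))
    denom = hx + hy
    if denom <= 0:
        return 0.0
    mi = hx + hy - hxy
    return float(np.clip(2.0 * mi / denom, 0.0, 1.0))


def _su_with_class(codes: np.ndarray, y: np.ndarray, n_bins: int) -> np.ndarray:
    """Vectorized SU of every column of ``codes`` with the class labels."""
    n, p = codes.shape
    ny = y.max() + 1
    joint = np.zeros((p, n_bins, ny))
    np.add.at(joint, (np.repeat(np.arange(p), n), codes.T.reshape(-1),
                      np.tile(y, p)), 1.0)
    hx = _entropy_from_counts(joint.sum(axis=2), axis=1)
    hy = _entropy_from_counts(joint[0].sum(axis=0))
    hxy = _entropy_from_counts(joint.reshape(p, -1), axis=1)
    mi = hx + hy - hxy
    denom = hx + hy
    su = np.where(denom > 0, 2.0 * mi / denom, 0.0)
    return np.clip(su, 0.0, 1.0)


def _su_pairwise(pivot: np.ndarray, others: np.ndarray, n_bins: int) -> np.ndarray:
    """SU between one pivot column and many other columns at once."""
    p = others.shape[1]
    n = len(pivot)
    joint = np.zeros((p, n_bins, n_bins))
    np.add.at(joint, (np.repeat(np.arange(p), n), others.T.reshape(-1),
                      np.tile(pivot, p)), 1.0)
    hx = _entropy_from_counts(joint.sum(axis=2), axis=1)
    hy = _entropy_from_counts(joint[0].sum(axis=0))
    hxy = _entropy_from_counts(joint.reshape(p, -1), axis=1)
    denom = hx + hy
    su = np.where(denom > 0, 2.0 * (hx + hy - hxy) / denom, 0.0)
    return np.clip(su, 0.0, 1.0)


def fcbf(
    X: np.ndarray,
    y,
    delta: float = 0.0,
    n_bins: int = 10,
    return_report: bool = False,
):
    """FCBF selection on a training feature matrix.

    Parameters
    ----------
    X : (n_samples, n_features) training features (continuous; discretized
        internally with equal-width bins fitted on these data).
    y : class labels.
    delta : SU-with-class relevance threshold; features must exceed it.

    Returns
    -------
    Ordered list of selected feature indices (descending SU with class; ties
    broken by feature index). With ``return_report=True`` also a DataFrame
    with per-feature SU, kept flag, and the feature that removed it. If no
    feature exceeds ``delta``, falls back to the single top-SU feature and
    logs a warning.
    """
    X = np.asarray(X, dtype=float)
    y = _encode(np.asarray(y))
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise SelectionError("X must be (n_samples, n_features) matching y")
    codes = discretize(X, n_bins)
    su = _su_with_class(codes, y, n_bins)

    order = np.lexsort((np.arange(len(su)), -su))
    candidates = [int(i) for i in order if su[i] > delta]
    removed_by = {}
    if not candidates:
        top = int(order[0])
        logger.warning(
            "FCBF: no feature exceeded delta=%.3g; falling back to top-SU feature %d",
            delta, top,
        )
        selected = [top]
    else:
        alive = list(candidates)
        selected = []
        while alive:
            pivot = alive.pop(0)
            selected.append(pivot)
            if not alive:
                break
            rest = np.array(alive)
            su_pair = _su_pairwise(codes[:, pivot], codes[:, rest], n_bins)
            # tolerance guards the SU(i,j) == SU(j,class) boundary case
            # against float rounding between the two computation paths
            drop = su_pair >= su[rest] - 1e-12
            for j in rest[drop]:
                removed_by[int(j)] = pivot
            alive = [int(j) for j in rest[~drop]]

    if not return_report:
        return selected
    report = pd.DataFrame({
        "feature": np.arange(X.shape[1]),
        "su_class": su,
        "kept": np.isin(np.arange(X.shape[1]), selected),
        "removed_by": [removed_by.get(i, -1) for i in range(X.shape[1])],
    })
    return selected, report
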