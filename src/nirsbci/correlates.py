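"""Correlation of per-participant BCI accuracy with user characteristics.

Continuous characteristics (verbal IQ, session-averaged Likert items) are
tested with Pearson's product-moment correlation when the Shapiro-Wilk test
does not reject normality, otherwise with Spearman's rho; dichotomous
demographics (gender, handedness) always use Spearman. P-values are
two-sided; missing values are dropped pairwise. Age is excluded by default
(a homogeneous age range makes the test uninformative). No
multiple-comparison correction is applied by default; Benjamini-Hochberg is
available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LIKERT_VARS = ("tiredness", "concentration", "enjoyment", "ease_of_session",
               "headgear_comfort")
CONTINUOUS_VARS = ("verbal_iq",) + LIKERT_VARS
DEMOGRAPHIC_VARS = ("gender", "handedness")


class CorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationResult:
    variable: str
    method: str  # "pearson" | "spearman"
    rho: float
    p: float
    n: int
    significant: bool


def shapiro_normality(x) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value for 3 <= n <= 50 samples."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= len(x) <= 50:
        raise CorrelationError(f"Shapiro-Wilk needs 3..50 samples, got {len(x)}")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _paired(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise CorrelationError("paired samples must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise CorrelationError("need at least 3 complete pairs")
    return x, y


def pearson_corr(x, y, alpha: float = 0.1, variable: str = "") -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x, y = _paired(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise CorrelationError("zero variance in one of the samples")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(variable, "pearson", float(r), float(p), len(x),
                             bool(p <= alpha))


def spearman_corr(x, y, alpha: float = 0.1, variable: str = "") -> CorrelationResult:
    """Spearman rank correlation (midranks for ties), two-sided p-value."""
    x, y = _paired(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise CorrelationError("zero variance in one of the samples")
    r, p = stats.spearmanr(x, y)
    return CorrelationResult(variable, "spearman", float(r), float(p), len(x),
                             bool(p <= alpha))


def correlate_report(
    accuracies: pd.Series | np.ndarray,
    profiles: pd.DataFrame,
    alpha: float = 0.1,
    include_age: bool = False,
    normality_alpha: float = 0.05,
    fdr: bool = False,
) -> list[CorrelationResult]:
    """Accuracy-characteristic correlation table across participants.

    ``accuracies`` aligns with ``profiles`` rows (per-participant best
    two-class accuracy in %). Continuous variables route through Pearson when
    Shapiro-Wilk does not reject normality at ``normality_alpha`` (else
    Spearman, logged); dichotomous demographics through Spearman (coded 0/1).
    ``fdr=True`` recomputes significance with Benjamini-Hochberg.
    """
    acc = np.asarray(accuracies, dtype=float)
    if len(acc) != len(profiles):
        raise CorrelationError("one accuracy per participant required")
    if len(profiles) < 4:
        raise CorrelationError("need at least 4 participants")

    results: list[CorrelationResult] = []
    for var in CONTINUOUS_VARS:
        if var not in profiles.columns:
            continue
        x = profiles[var].to_numpy(dtype=float)
        if not np.isfinite(x).any():
            logger.warning("skipping %s: all values missing", var)
            continue
        valid = x[np.isfinite(x)]
        try:
            _, p_norm = shapiro_normality(valid)
        except CorrelationError:
            p_norm = 0.0
        if p_norm > normality_alpha:
            results.append(pearson_corr(x, acc, alpha=alpha, variable=var))
        else:
            logger.info("normality rejected for %s; using Spearman", var)
            results.append(spearman_corr(x, acc, alpha=alpha, variable=var))

    for var in DEMOGRAPHIC_VARS + (("age_range",) if include_age else ()):
        if var not in profiles.columns:
            continue
        codes = pd.Categorical(profiles[var]).codes.astype(float)
        codes[codes < 0] = np.nan
        if np.nanstd(codes) == 0:
            logger.warning("skipping %s: constant across participants", var)
            continue
        results.append(spearman_corr(codes, acc, alpha=alpha, variable=var))

    if fdr and results:
        reject, _, _, _ = multipletests([r.p for r in results], alpha=alpha,
                                        method="fdr_bh")
        results = [
            CorrelationResult(r.variable, r.method, r.rho, r.p, r.n, bool(rej))
            for r, rej in zip(results, reject)
        ]
    return results


def report_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tabular view of a correlation report (variable, method, rho, p, n,
    significant)."""
    return pd.DataFrame([
        {"variable": r.variable, "method": r.method, "rho": r.rho, "p": r.p,
         "n": r.n, "significant": r.significant}
        for r in results
    ])
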