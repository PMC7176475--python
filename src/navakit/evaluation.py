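"""Agreement statistics between NAVA-level estimate vectors.

Used to compare the algorithm's adequate-level estimates against a
reference — human raters or the simulator's planted truth — across
sessions: pairwise Pearson correlation with Fisher-z confidence limits
(optionally Lin's concordance correlation), and the multiple correlation
coefficient of one estimator against a panel of others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import NumericalError, ValidationError


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    ci_low: float
    ci_high: float
    n: int
    method: str


def _validated_pair(a, b, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.size != bv.size:
        raise ValidationError("vectors must have equal length")
    if av.size < min_n:
        raise ValidationError(f"need at least {min_n} paired values")
    if not (np.all(np.isfinite(av)) and np.all(np.isfinite(bv))):
        raise ValidationError("inputs must be finite (no missing values)")
    if np.std(av) == 0 or np.std(bv) == 0:
        raise NumericalError("zero variance: correlation undefined")
    return av, bv


def pearson_concordance(
    a, b, alpha: float = 0.05, method: str = "pearson"
) -> CorrelationResult:
    """Correlation between two estimate vectors with a 95% (default) CI.

    ``method="pearson"`` gives the plain Pearson coefficient with the
    Fisher-z interval; ``method="lin"`` gives Lin's concordance correlation
    coefficient (agreement about the identity line) with the Fisher-z
    interval on its z-transform.
    """
    av, bv = _validated_pair(a, b)
    n = av.size
    if method == "pearson":
        r = float(stats.pearsonr(av, bv).statistic)
    elif method == "lin":
        mx, my = av.mean(), bv.mean()
        sxy = np.mean((av - mx) * (bv - my))
        r = float(2 * sxy / (av.var() + bv.var() + (mx - my) ** 2))
    else:
        raise ValidationError(f"unknown method {method!r}")
    if n <= 3 or abs(r) >= 1.0:
        lo, hi = (r, r)
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        crit = stats.norm.ppf(1 - alpha / 2)
        lo, hi = np.tanh(z - crit * se), np.tanh(z + crit * se)
    return CorrelationResult(r, float(lo), float(hi), n, method)


def multiple_correlation(y, X) -> float:
    """Multiple correlation coefficient of y against the columns of X.

    The square root of the coefficient of determination of the
    least-squares projection of y onto X plus an intercept; ranges from 0
    (no correlation) to 1 (linear dependence).
    """
    yv = np.asarray(y, dtype=float)
    Xv = np.atleast_2d(np.asarray(X, dtype=float))
    if Xv.shape[0] == yv.size and Xv.ndim == 2:
        pass
    elif Xv.shape[1] == yv.size:
        Xv = Xv.T
    if Xv.shape[0] != yv.size:
        raise ValidationError("X rows must match the length of y")
    n, p = Xv.shape
    if n <= p + 1:
        raise ValidationError(f"need more than {p + 1} rows, got {n}")
    A = np.column_stack([np.ones(n), Xv])
    if np.linalg.matrix_rank(A) < p + 1:
        raise NumericalError("X (with intercept) is rank deficient")
    beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
    resid = yv - A @ beta
    sst = float(np.sum((yv - yv.mean()) ** 2))
    if sst == 0:
        raise NumericalError("y has zero variance: R undefined")
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    return float(np.sqrt(np.clip(r2, 0.0, 1.0)))


def multiple_correlation_ci(
    y, X, alpha: float = 0.05, n_boot: int = 2000, seed: int = 0
) -> CorrelationResult:
    """Bootstrap percentile interval for the multiple correlation coefficient.

    Sessions (rows) are resampled with replacement ``n_boot`` times; this
    is a resampling interval, not a closed-form one.
    """
    yv = np.asarray(y, dtype=float)
    Xv = np.atleast_2d(np.asarray(X, dtype=float))
    if Xv.shape[0] != yv.size:
        Xv = Xv.T
    r = multiple_correlation(yv, Xv)
    rng = np.random.default_rng(seed)
    n, p = Xv.shape
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.unique(idx).size <= p + 1:
            continue
        try:
            boots.append(multiple_correlation(yv[idx], Xv[idx]))
        except NumericalError:
            continue
    if not boots:
        raise NumericalError("all bootstrap resamples were degenerate")
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return CorrelationResult(r, float(lo), float(hi), n, "mcc-bootstrap")
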