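"""Statistical tests used across the pipeline.

The centrepiece is the modified asymptotic (MA) test for comparing two
overlapping Pearson correlations ``r1 = corr(X, Y)`` and ``r2 = corr(X, Z)``
that share the variable ``X``; ``r3 = corr(Y, Z)`` carries the dependence
between the two estimates. The test builds an asymmetric confidence interval
(L, U) for the difference ``r1 - r2`` from back-transformed single-correlation
limits; ``L > 0`` declares ``r1`` significantly larger than ``r2``.

Multiple-testing correction (Benjamini-Hochberg) and the Cochran-Armitage
trend test for binomial proportions across ordered bins are also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["MATestResult", "ma_test", "bh_adjust", "trend_test"]


@dataclass(frozen=True)
class MATestResult:
    """Outcome of the MA test for two overlapping correlations."""

    r1: float
    r2: float
    r3: float
    n: int
    alpha: float
    l1: float
    u1: float
    l2: float
    u2: float
    L: float
    U: float
    var_r1: float
    var_r2: float
    cov_r12: float
    corr_r12: float
    decision: str  # "r1", "r2" or "none"


def _var_r(r: float, n: int) -> float:
    return (1.0 - r * r) ** 2 / n


def _cov_r12(r1: float, r2: float, r3: float, n: int) -> float:
    # Asymptotic covariance of two overlapping correlation estimates.
    return ((r3 - 0.5 * r1 * r2) * (1.0 - r1 * r1 - r2 * r2 - r3 * r3) + r3**3) / n


def _sqrt_floor(x: float) -> float:
    if x < 0.0:
        warnings.warn(
            "MA-test radicand negative (%.3g); floored at 0" % x, RuntimeWarning
        )
        return 0.0
    return float(np.sqrt(x))


def ma_test(
    r1: float, r2: float, r3: float, n: int, alpha: float = 0.05
) -> MATestResult:
    """Compare overlapping correlations ``r1`` and ``r2`` with the MA test.

    Parameters
    ----------
    r1, r2
        The two correlations sharing a common variable, each in (-1, 1).
    r3
        Correlation between the two non-shared variables.
    n
        Sample size used for all three correlations; must be >= 4.
    alpha
        Two-sided significance level for the confidence limits.

    Returns
    -------
    MATestResult
        Confidence limits (L, U) for ``r1 - r2`` plus intermediate
        quantities. ``decision`` is ``"r1"`` when L > 0, ``"r2"`` when
        U < 0, otherwise ``"none"``.
    """
    for name, r in (("r1", r1), ("r2", r2), ("r3", r3)):
        if not np.isfinite(r) or abs(r) >= 1.0:
            raise ValueError(f"{name}={r!r} must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError(f"sample size n={n} must be >= 4")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")

    z = sps.norm.ppf(1.0 - alpha / 2.0)
    v1, v2 = _var_r(r1, n), _var_r(r2, n)
    l1, u1 = r1 - z * np.sqrt(v1), r1 + z * np.sqrt(v1)
    l2, u2 = r2 - z * np.sqrt(v2), r2 + z * np.sqrt(v2)
    cov = _cov_r12(r1, r2, r3, n)
    corr = cov / np.sqrt(v1 * v2)
    corr = float(np.clip(corr, -1.0, 1.0))

    diff = r1 - r2
    L = diff - _sqrt_floor(
        (r1 - l1) ** 2 + (u2 - r2) ** 2 - 2.0 * corr * (r1 - l1) * (u2 - r2)
    )
    U = diff + _sqrt_floor(
        (u1 - r1) ** 2 + (r2 - l2) ** 2 - 2.0 * corr * (u1 - r1) * (r2 - l2)
    )

    if L > 0.0:
        decision = "r1"
    elif U < 0.0:
        decision = "r2"
    else:
        decision = "none"
    return MATestResult(
        r1=r1, r2=r2, r3=r3, n=n, alpha=alpha,
        l1=float(l1), u1=float(u1), l2=float(l2), u2=float(u2),
        L=float(L), U=float(U),
        var_r1=float(v1), var_r2=float(v2),
        cov_r12=float(cov), corr_r12=corr,
        decision=decision,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def trend_test(successes, totals, scores=None) -> tuple[float, float]:
    """Cochran-Armitage test for a linear trend in proportions.

    Parameters
    ----------
    successes, totals
        Per-bin success counts and trial counts over >= 2 ordered bins.
    scores
        Bin scores; defaults to 0, 1, 2, ... (equally spaced).

    Returns
    -------
    (z, p)
        Standard-normal trend statistic and its two-sided p-value. When all
        outcomes are identical (no variance) the convention ``p = 1`` is
        returned with ``z = 0``.
    """
    x = np.asarray(successes, dtype=float)
    m = np.asarray(totals, dtype=float)
    if x.shape != m.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need >= 2 ordered bins with matching counts")
    if np.any(x < 0) or np.any(m <= 0) or np.any(x > m):
        raise ValueError("successes must satisfy 0 <= x <= n per bin")
    s = np.arange(x.size, dtype=float) if scores is None else np.asarray(scores, float)
    if s.size != x.size:
        raise ValueError("scores must match the number of bins")

    total_n = m.sum()
    pbar = x.sum() / total_n
    if pbar in (0.0, 1.0):
        return 0.0, 1.0
    stat = float(np.sum(s * x) - pbar * np.sum(s * m))
    var = pbar * (1.0 - pbar) * (np.sum(s * s * m) - np.sum(s * m) ** 2 / total_n)
    if var <= 0.0:
        return 0.0, 1.0
    zstat = stat / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(zstat))
    return float(zstat), float(min(p, 1.0))
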