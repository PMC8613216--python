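"""Agreement and paired-comparison statistics.

Three classical procedures used to compare two gating runs (or a gating run
against an external differential count) and to test within-animal shifts
over time:

* :func:`linreg_concordance` — Pearson r with the OLS fit of y on x and the
  two-sided t-test p-value for r != 0 (n - 2 df).
* :func:`bland_altman` — bias (mean difference, first minus second) and
  1.96-SD limits of agreement.
* :func:`friedman_test` — nonparametric rank test across matched blocks
  (animals) and treatments (time points), tie-corrected, chi-square
  approximation with k - 1 df.

Significance convention throughout: two-sided, alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConcordanceResult",
    "BlandAltmanResult",
    "FriedmanResult",
    "linreg_concordance",
    "bland_altman",
    "friedman_test",
]


@dataclass(frozen=True)
class ConcordanceResult:
    n: int
    r: float
    slope: float
    intercept: float
    p: float


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    bias: float
    loa_low: float
    loa_high: float
    sd: float


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    p: float
    n_blocks: int
    k_treatments: int
    small_sample_warning: bool


def linreg_concordance(x, y) -> ConcordanceResult:
    """Pearson correlation and OLS regression of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance in x or y (degenerate input)")
    sxy = float(xc @ yc)
    r = sxy / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return ConcordanceResult(n, r, float(slope), intercept, p)


def bland_altman(x, y) -> BlandAltmanResult:
    """Bias and 1.96-SD limits of agreement of the differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(n, bias, bias - 1.96 * sd, bias + 1.96 * sd, sd)


def friedman_test(values) -> FriedmanResult:
    """Friedman rank test: rows = blocks (animals), columns = treatments.

    Within-row mid-ranks; tie-corrected statistic referred to chi-square
    with k - 1 df.  When every row is fully tied the statistic is 0 and
    p = 1.  Missing cells are rejected (no imputation).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("values must be a 2-D blocks x treatments matrix")
    n, k = v.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 treatments and >= 2 blocks")
    if not np.all(np.isfinite(v)):
        raise ValueError("missing or non-finite cells are not allowed")
    ranks = np.apply_along_axis(stats.rankdata, 1, v)
    rj = ranks.sum(axis=0)
    q_num = 12.0 * float(((rj - n * (k + 1) / 2.0) ** 2).sum())
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    ties = 0.0
    for row in v:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    denom = n * k * (k + 1) - ties / (k - 1)
    if denom <= 0:
        return FriedmanResult(0.0, k - 1, 1.0, n, k, n < 5)
    q = q_num / denom
    p = float(stats.chi2.sf(q, k - 1))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return FriedmanResult(float(q), k - 1, p, n, k, n < 5)
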