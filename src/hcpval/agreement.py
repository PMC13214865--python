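"""Cross-software and cross-platform agreement statistics.

When the same samples are reprocessed with an independent search engine or
re-acquired on a different MS platform, agreement of the paired total-HCP
values is summarized three ways: Deming regression (errors in both axes,
bootstrap percentile CIs), Lin's concordance correlation coefficient, and
Bland-Altman limits of agreement on the relative-difference scale, checked
against the predefined symmetric acceptance limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AgreementStats",
    "deming_fit",
    "lin_ccc",
    "bland_altman_relative",
    "containment_check",
    "agreement_summary",
]


@dataclass
class AgreementStats:
    deming_slope: float
    deming_intercept: float
    slope_ci95: tuple[float, float]
    intercept_ci95: tuple[float, float]
    ccc: float
    ba_bias_percent: float
    ba_loa: tuple[float, float]
    within_limit: bool | None = None


def _deming_point(x: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, float]:
    # lam = ratio of error variances var(eps_y)/var(eps_x)
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxy == 0:
        if syy == sxx == 0:
            raise ValueError("zero variance in both series")
        return (0.0, float(np.mean(y)))
    slope = (syy - lam * sxx + np.sqrt((syy - lam * sxx) ** 2 + 4 * lam * sxy**2)) / (2 * sxy)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return float(slope), intercept


def deming_fit(
    x: np.ndarray,
    y: np.ndarray,
    lambda_ratio: float = 1.0,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, tuple[float, float], tuple[float, float]]:
    """Closed-form Deming regression with paired-bootstrap percentile CIs.

    ``lambda_ratio`` is the ratio of the y to x error variances; 1 treats
    both measurement systems as equally noisy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if lambda_ratio <= 0:
        raise ValueError("lambda_ratio must be > 0")
    slope, intercept = _deming_point(x, y, lambda_ratio)
    rng = np.random.default_rng(seed)
    n = x.size
    slopes = np.empty(n_boot)
    intercepts = np.empty(n_boot)
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        try:
            s, i = _deming_point(x[take], y[take], lambda_ratio)
        except ValueError:
            s, i = slope, intercept  # degenerate resample: fall back to point estimate
        slopes[b], intercepts[b] = s, i
    s_ci = tuple(np.percentile(slopes, [2.5, 97.5]))
    i_ci = tuple(np.percentile(intercepts, [2.5, 97.5]))
    return slope, intercept, (float(s_ci[0]), float(s_ci[1])), (float(i_ci[0]), float(i_ci[1]))


def lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population 1/n moments).

    ccc = 2 cov(x,y) / (var x + var y + (mean x - mean y)^2).  Identical
    constant series give 1 by convention; unequal constant series have no
    covariance but a positive location-shift denominator, hence 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired values")
    vx = np.var(x)
    vy = np.var(y)
    shift = (np.mean(x) - np.mean(y)) ** 2
    denom = vx + vy + shift
    if denom == 0:
        if np.array_equal(x, y):
            return 1.0
        raise ValueError("zero denominator: constant unequal series")
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2.0 * cov / denom)


def bland_altman_relative(x: np.ndarray, y: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Bland-Altman bias and 95% limits of agreement on the percent scale.

    d_i = 100 (y_i - x_i) / ((x_i + y_i)/2); bias = mean d; LoA = bias
    +/- 1.96 SD(d) with the sample SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    means = (x + y) / 2.0
    if np.any(means <= 0):
        raise ValueError("pairwise mean must be > 0 for relative differences")
    d = 100.0 * (y - x) / means
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def containment_check(loa: tuple[float, float], limit_percent: float) -> bool:
    """Pass iff both limits of agreement lie within +/-limit (closed bounds)."""
    return loa[0] >= -limit_percent and loa[1] <= limit_percent


def agreement_summary(
    x: np.ndarray,
    y: np.ndarray,
    limit_percent: float = 30.0,
    lambda_ratio: float = 1.0,
    n_boot: int = 2000,
    seed: int = 0,
) -> AgreementStats:
    """All three agreement statistics plus the containment verdict."""
    slope, intercept, s_ci, i_ci = deming_fit(x, y, lambda_ratio, n_boot, seed)
    ccc = lin_ccc(x, y)
    bias, loa = bland_altman_relative(x, y)
    return AgreementStats(
        deming_slope=slope,
        deming_intercept=intercept,
        slope_ci95=s_ci,
        intercept_ci95=i_ci,
        ccc=ccc,
        ba_bias_percent=bias,
        ba_loa=loa,
        within_limit=containment_check(loa, limit_percent),
    )
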