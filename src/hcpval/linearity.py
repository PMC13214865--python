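"""Weighted least-squares calibration of measured vs nominal total HCP.

The calibration model is Y = beta0 + beta1 * mu + eps on replicate-block
reportables pooled across assays, with inverse-variance weights from the
empirical per-level variance and HC3 heteroscedasticity-robust standard
errors.  A slope below one is proportional compression; a positive
intercept is an additive offset whose relative contribution decays as 1/x.
The implied relative bias 100*(beta0/x + beta1 - 1) links the calibration
directly to the trueness profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .core import ReplicateBlock

__all__ = ["CalibrationFit", "wls_calibration", "implied_relative_bias"]


@dataclass
class CalibrationFit:
    beta0: float
    beta1: float
    se_hc3: tuple[float, float]
    ci95_hc3: tuple[tuple[float, float], tuple[float, float]]
    r_squared: float
    weights: dict[float, float]  # nominal ng -> weight
    residuals: np.ndarray
    p_beta0_eq_0: float
    p_beta1_eq_1: float


def _level_weights(blocks: list[ReplicateBlock]) -> dict[float, float]:
    by_level: dict[float, list[float]] = {}
    for b in blocks:
        by_level.setdefault(b.nominal_ng, []).append(b.reportable_ng)
    variances = {}
    for mu, vals in by_level.items():
        if len(vals) < 2:
            raise ValueError(f"need >= 2 replicate blocks at level {mu} ng to estimate weights")
        variances[mu] = float(np.var(vals, ddof=1))
    if any(v == 0 for v in variances.values()):
        positive = [v for v in variances.values() if v > 0]
        if not positive:
            raise ValueError(
                "all level variances are zero; weights undefined (pool variances or add jitter)"
            )
        # documented fallback: pool the minimum positive variance into degenerate levels
        floor = min(positive)
        variances = {mu: (v if v > 0 else floor) for mu, v in variances.items()}
    return {mu: 1.0 / v for mu, v in variances.items()}


def wls_calibration(blocks: list[ReplicateBlock]) -> CalibrationFit:
    """Fit the weighted calibration line with HC3 inference.

    Wald tests of beta0 = 0 and beta1 = 1 use the HC3 sandwich covariance;
    the reported R^2 is the weighted R^2 of the WLS fit.
    """
    mus = sorted({b.nominal_ng for b in blocks})
    if len(mus) < 2:
        raise ValueError("need >= 2 distinct spike levels")
    weights = _level_weights(blocks)
    x = np.array([b.nominal_ng for b in blocks])
    y = np.array([b.reportable_ng for b in blocks])
    w = np.array([weights[b.nominal_ng] for b in blocks])
    X = sm.add_constant(x)
    fit = sm.WLS(y, X, weights=w).fit(cov_type="HC3")
    beta0, beta1 = map(float, fit.params)
    se0, se1 = map(float, fit.bse)
    ci = fit.conf_int(alpha=0.05)
    # Wald tests against the linearity nulls (beta0 = 0, beta1 = 1)
    z0 = beta0 / se0
    z1 = (beta1 - 1.0) / se1
    df = fit.df_resid
    p0 = 2 * stats.t.sf(abs(z0), df)
    p1 = 2 * stats.t.sf(abs(z1), df)
    return CalibrationFit(
        beta0=beta0,
        beta1=beta1,
        se_hc3=(se0, se1),
        ci95_hc3=((float(ci[0, 0]), float(ci[0, 1])), (float(ci[1, 0]), float(ci[1, 1]))),
        r_squared=float(fit.rsquared),
        weights=weights,
        residuals=np.asarray(fit.resid),
        p_beta0_eq_0=float(p0),
        p_beta1_eq_1=float(p1),
    )


def implied_relative_bias(beta0: float, beta1: float, x: float) -> float:
    """Calibration-implied relative bias in percent at nominal amount ``x``.

    100 * (beta0/x + beta1 - 1); as x -> inf this approaches 100*(beta1 - 1),
    the pure proportional compression.
    """
    if x <= 0:
        raise ValueError("x must be > 0")
    return 100.0 * (beta0 / x + beta1 - 1.0)
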