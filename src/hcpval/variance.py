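"""Variance-component decomposition of replicate-block relative errors.

Per spike level, a one-way random-effects ANOVA with assay as the grouping
factor splits the relative-error variance into a within-assay (repeatability)
and a between-assay component by the method of moments:

    sigma_W^2 = MS_within
    sigma_B^2 = max((MS_between - MS_within) / m_h, 0)
    sigma_T   = sqrt(sigma_W^2 + sigma_B^2)        (intermediate precision)

with m_h the harmonic-mean number of replicate blocks per assay.  Negative
moment estimates are truncated to zero and flagged; with the shallow
between-assay replication typical of validation designs, truncation means
"indistinguishable from zero", not "absent".

Level-wise total SDs are smoothed by a log-log model log sigma_T = a + b log
mu, fitted by WLS with degrees-of-freedom weights (n_j - 1); the smoothed
predictions feed the tolerance-interval coverage factors.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .core import ReplicateBlock

__all__ = [
    "LevelStats",
    "VarianceModel",
    "relative_errors",
    "anova_mom",
    "decompose_levels",
    "fit_variance_model",
]


@dataclass
class LevelStats:
    """Per-level bias and variance decomposition on the percent-RE scale."""

    level: str
    nominal_ng: float
    bias: float
    ms_within: float
    ms_between: float
    df_within: int
    df_between: int
    m_h: float
    sigma_w: float
    sigma_b: float
    sigma_t: float
    n_blocks: int
    n_assays: int
    truncated: bool


@dataclass
class VarianceModel:
    """Coefficients of log sigma_T = a + b log mu (natural log)."""

    a: float
    b: float

    def predict(self, nominal_ng: float | np.ndarray) -> np.ndarray | float:
        return np.exp(self.a + self.b * np.log(nominal_ng))


def relative_errors(blocks: list[ReplicateBlock]) -> np.ndarray:
    """Percent relative errors 100*(Y - mu)/mu, in block order."""
    return np.array([b.relative_error for b in blocks])


def anova_mom(
    re_by_assay: dict[str, np.ndarray], level: str = "", nominal_ng: float = float("nan")
) -> LevelStats:
    """Method-of-moments one-way random-effects decomposition at one level.

    ``re_by_assay`` maps assay id -> that assay's replicate-block relative
    errors (percent).  Group sizes may be unbalanced.  A level present in a
    single assay has df_between = 0; its between-assay component is not
    estimable and is reported as 0 with the truncation flag set.
    """
    groups = {a: np.asarray(v, dtype=float) for a, v in re_by_assay.items() if len(v) > 0}
    n_total = sum(v.size for v in groups.values())
    if n_total < 2:
        raise ValueError("need >= 2 replicate blocks")
    n_assays = len(groups)
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    df_w = n_total - n_assays
    df_b = n_assays - 1
    ss_w = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values())
    ms_w = ss_w / df_w if df_w > 0 else 0.0
    m_h = n_assays / sum(1.0 / v.size for v in groups.values())
    truncated = False
    if df_b > 0:
        ss_b = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
        ms_b = ss_b / df_b
        sigma_b2 = (ms_b - ms_w) / m_h
        if sigma_b2 < 0:
            sigma_b2 = 0.0
            truncated = True
    else:
        ms_b = 0.0
        sigma_b2 = 0.0
        truncated = True
    sigma_w = float(np.sqrt(ms_w))
    sigma_b = float(np.sqrt(sigma_b2))
    return LevelStats(
        level=level,
        nominal_ng=nominal_ng,
        bias=float(grand),
        ms_within=float(ms_w),
        ms_between=float(ms_b),
        df_within=int(df_w),
        df_between=int(df_b),
        m_h=float(m_h),
        sigma_w=sigma_w,
        sigma_b=sigma_b,
        sigma_t=float(np.hypot(sigma_w, sigma_b)),
        n_blocks=int(n_total),
        n_assays=int(n_assays),
        truncated=truncated,
    )


def decompose_levels(blocks: list[ReplicateBlock]) -> list[LevelStats]:
    """ANOVA decomposition at every level, in nominal-amount order."""
    by_level: dict[str, dict[str, list[float]]] = {}
    nominal: dict[str, float] = {}
    for b in blocks:
        by_level.setdefault(b.level, {}).setdefault(b.assay, []).append(b.relative_error)
        nominal[b.level] = b.nominal_ng
    out = []
    for level in sorted(by_level, key=lambda lv: nominal[lv]):
        groups = {a: np.array(v) for a, v in by_level[level].items()}
        out.append(anova_mom(groups, level=level, nominal_ng=nominal[level]))
    return out


def fit_variance_model(level_stats: list[LevelStats]) -> VarianceModel:
    """WLS fit of log sigma_T on log mu with weights n_j - 1.

    Levels with sigma_T = 0 carry no information on the log scale and are
    excluded with a warning.
    """
    usable = [s for s in level_stats if s.sigma_t > 0]
    dropped = [s.level for s in level_stats if s.sigma_t <= 0]
    if dropped:
        warnings.warn(f"levels excluded from variance model (sigma_T = 0): {dropped}")
    if len(usable) < 2:
        raise ValueError("need >= 2 levels with sigma_T > 0")
    mu = np.array([s.nominal_ng for s in usable])
    st = np.array([s.sigma_t for s in usable])
    w = np.array([max(s.n_blocks - 1, 1) for s in usable], dtype=float)
    X = np.column_stack([np.ones(mu.size), np.log(mu)])
    y = np.log(st)
    wx = X * w[:, None]
    a, b = np.linalg.solve(X.T @ wx, wx.T @ y)
    return VarianceModel(a=float(a), b=float(b))
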