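"""Abundance-stratified total-error analysis.

Aggregate total-HCP validation can hide abundance-dependent calibration
heterogeneity: low-abundance proteins may behave differently from the
high-abundance species that dominate the sum.  This module re-estimates the
accuracy profile within fixed abundance strata:

1. strata Q1-Q4 are assigned once from per-protein mean abundance at an
   anchor spike level, with cutpoints at the 5/25/50/75/100th percentiles
   (proteins below the 5th percentile are excluded as unstable);
2. each (assay, level, block, stratum) cell's reportable is the bootstrap
   expectation of the cell mean (cells under 30 proteins are excluded);
3. relative errors are taken on the ratio scale against the stratum's anchor
   mean, so the anchor level has zero mean bias by construction;
4. per-stratum beta-expectation tolerance intervals against a +/-35% limit
   define the validated domain (intersection over strata), from which
   abundance-aware LLOQ (P95 of Q1 reportables at the lowest validated
   ratio) and ULOQ (P05 of Q4 at the highest) are read off in ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .tolerance import (
    ToleranceInterval,
    acceptance_decision,
    beta_expectation_ti,
    satterthwaite_df,
)
from .variance import LevelStats, anova_mom, fit_variance_model

__all__ = [
    "Stratification",
    "StratumCell",
    "assign_strata",
    "bootstrap_reportable",
    "cell_reportables",
    "stratum_relative_errors",
    "stratum_accuracy_profile",
    "stratified_calibration",
    "abundance_lloq_uloq",
]

MIN_CELL_PROTEINS = 30
STRATA = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class Stratification:
    anchor_level: str
    cutpoints: tuple[float, ...]  # P5, P25, P50, P75
    membership: dict[str, str]  # protein -> Q1..Q4
    excluded_below_p5: tuple[str, ...]


@dataclass
class StratumCell:
    assay: str
    level: str
    block: int
    stratum: str
    n_proteins: int
    reportable_ppm: float
    r_obs: float = float("nan")
    r_theo: float = float("nan")
    relative_error: float = float("nan")


def assign_strata(anchor_abundance: pd.Series, anchor_level: str = "L4") -> Stratification:
    """Fix stratum membership from per-protein mean abundance at the anchor.

    ``anchor_abundance`` is indexed by protein.  Quantiles use linear
    interpolation; ties are resolved by (value, protein) ordering so
    membership is reproducible.  Requires >= 120 proteins so each stratum
    can clear the 30-protein cell floor.
    """
    if len(anchor_abundance) < 120:
        raise ValueError("need >= 120 proteins to stratify")
    vals = anchor_abundance.sort_index()
    p5, p25, p50, p75 = np.percentile(vals.to_numpy(), [5, 25, 50, 75])
    if p5 == p75:
        raise ValueError("degenerate abundance distribution: all cutpoints equal")
    order = sorted(vals.index, key=lambda p: (vals[p], p))
    membership: dict[str, str] = {}
    excluded: list[str] = []
    for prot in order:
        v = vals[prot]
        if v < p5:
            excluded.append(prot)
        elif v < p25:
            membership[prot] = "Q1"
        elif v < p50:
            membership[prot] = "Q2"
        elif v < p75:
            membership[prot] = "Q3"
        else:
            membership[prot] = "Q4"
    return Stratification(
        anchor_level=anchor_level,
        cutpoints=(float(p5), float(p25), float(p50), float(p75)),
        membership=membership,
        excluded_below_p5=tuple(excluded),
    )


def bootstrap_reportable(
    ppm_values: np.ndarray, n_boot: int = 10000, seed: int = 0
) -> float:
    """Bootstrap expectation of a cell mean (equals the cell mean as B -> inf)."""
    v = np.asarray(ppm_values, dtype=float)
    if v.size < MIN_CELL_PROTEINS:
        raise ValueError("cell_too_small")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    return float(v[idx].mean(axis=1).mean())


def cell_reportables(
    ppm_table: pd.DataFrame,
    strat: Stratification,
    n_boot: int = 10000,
    seed: int = 0,
) -> tuple[list[StratumCell], list[dict]]:
    """Bootstrap reportables for every (assay, level, block, stratum) cell.

    Returns the retained cells and an exclusion log (one entry per dropped
    cell with its reason); retained + excluded = all cells seen.
    """
    df = ppm_table.copy()
    df["stratum"] = df["protein"].map(strat.membership)
    df = df[df["stratum"].notna()]
    cells: list[StratumCell] = []
    excluded: list[dict] = []
    rng = np.random.default_rng(seed)
    for (assay, level, block, stratum), g in df.groupby(
        ["assay", "level", "block", "stratum"], sort=True
    ):
        v = g["ppm"].to_numpy()
        if v.size < MIN_CELL_PROTEINS:
            excluded.append(
                {
                    "assay": assay,
                    "level": level,
                    "block": block,
                    "stratum": stratum,
                    "n_proteins": int(v.size),
                    "reason": "fewer_than_30_proteins",
                }
            )
            continue
        rep = bootstrap_reportable(v, n_boot=n_boot, seed=int(rng.integers(0, 2**31 - 1)))
        cells.append(
            StratumCell(
                assay=str(assay),
                level=str(level),
                block=int(block),
                stratum=str(stratum),
                n_proteins=int(v.size),
                reportable_ppm=rep,
            )
        )
    return cells, excluded


def stratum_relative_errors(
    cells: list[StratumCell],
    spike_by_level: dict[str, float],
    anchor_level: str = "L4",
) -> list[StratumCell]:
    """Ratio-scale relative errors against each stratum's anchor mean.

    The anchor A_b is the mean reportable over all anchor-level cells of the
    stratum; R_obs = reportable/A_b, R_theo = S_j/S_anchor, and
    RE = 100 * (R_obs - R_theo)/R_theo.  The stratum mean RE at the anchor
    level is zero by construction.
    """
    s_anchor = spike_by_level[anchor_level]
    out = []
    for stratum in sorted({c.stratum for c in cells}):
        sc = [c for c in cells if c.stratum == stratum]
        anchor_cells = [c.reportable_ppm for c in sc if c.level == anchor_level]
        if not anchor_cells:
            raise ValueError(f"stratum {stratum} has no anchor-level cells")
        a_b = float(np.mean(anchor_cells))
        if a_b == 0:
            raise ValueError(f"stratum {stratum} anchor mean is zero")
        for c in sc:
            c.r_obs = c.reportable_ppm / a_b
            c.r_theo = spike_by_level[c.level] / s_anchor
            c.relative_error = 100.0 * (c.r_obs - c.r_theo) / c.r_theo
            out.append(c)
    return out


def stratum_accuracy_profile(
    cells: list[StratumCell],
    spike_by_level: dict[str, float],
    beta: float = 0.95,
    acceptance_limit: float = 35.0,
) -> dict[str, object]:
    """Per-stratum beta-expectation profile and the validated domain.

    Within each stratum the relative errors are decomposed by assay at each
    level (reusing the one-way random-effects machinery), the log-log
    variance model is refitted in the theoretical spike ratio, and each
    (level, stratum) interval is checked against the stratified acceptance
    limit.  The validated domain is the set of levels passing in *every*
    stratum.
    """
    strata = sorted({c.stratum for c in cells})
    tis: dict[tuple[str, str], ToleranceInterval] = {}
    level_pass: dict[str, dict[str, bool]] = {}
    for stratum in strata:
        sc = [c for c in cells if c.stratum == stratum]
        levels = sorted({c.level for c in sc}, key=lambda lv: spike_by_level[lv])
        stats_list: list[LevelStats] = []
        for lv in levels:
            groups: dict[str, list[float]] = {}
            for c in sc:
                if c.level == lv:
                    groups.setdefault(c.assay, []).append(c.relative_error)
            s = anova_mom(
                {a: np.array(v) for a, v in groups.items()},
                level=lv,
                # variance model runs in the theoretical spike ratio
                nominal_ng=spike_by_level[lv] / spike_by_level.get("L4", 1.0),
            )
            stats_list.append(s)
        model = fit_variance_model(stats_list)
        for s in stats_list:
            nu = satterthwaite_df(s.sigma_w, s.sigma_b, s.df_within, s.df_between, s.m_h)
            ti = beta_expectation_ti(
                s.bias, float(model.predict(s.nominal_ng)), nu, beta, level=s.level
            )
            acceptance_decision(ti, acceptance_limit)
            tis[(s.level, stratum)] = ti
            level_pass.setdefault(s.level, {})[stratum] = bool(ti.passed)
    validated = [
        lv
        for lv in sorted(level_pass, key=lambda lv: spike_by_level[lv])
        if all(level_pass[lv].values())
    ]
    return {"tolerance_intervals": tis, "per_level_pass": level_pass, "validated_levels": validated}


def stratified_calibration(
    cells: list[StratumCell], x_theoretical: dict[tuple[str, str], float]
) -> dict[str, dict[str, float]]:
    """Per-stratum WLS calibration of cell reportables on theoretical abundance.

    ``x_theoretical`` maps (level, stratum) -> expected ppm.  Weights are
    inverse empirical per-level variances within the stratum; inference uses
    the HC3 sandwich, mirroring the aggregate calibration.
    """
    out: dict[str, dict[str, float]] = {}
    for stratum in sorted({c.stratum for c in cells}):
        sc = [c for c in cells if c.stratum == stratum]
        x = np.array([x_theoretical[(c.level, c.stratum)] for c in sc])
        y = np.array([c.reportable_ppm for c in sc])
        var_by_level: dict[str, float] = {}
        for lv in {c.level for c in sc}:
            vals = [c.reportable_ppm for c in sc if c.level == lv]
            var_by_level[lv] = float(np.var(vals, ddof=1)) if len(vals) > 1 else np.nan
        floor = np.nanmin([v for v in var_by_level.values() if v and v > 0])
        w = np.array(
            [
                1.0 / (var_by_level[c.level] if var_by_level[c.level] and var_by_level[c.level] > 0 else floor)
                for c in sc
            ]
        )
        fit = sm.WLS(y, sm.add_constant(x), weights=w).fit(cov_type="HC3")
        ci = fit.conf_int(alpha=0.05)
        out[stratum] = {
            "intercept": float(fit.params[0]),
            "slope": float(fit.params[1]),
            "intercept_se": float(fit.bse[0]),
            "slope_se": float(fit.bse[1]),
            "intercept_ci_lo": float(ci[0, 0]),
            "intercept_ci_hi": float(ci[0, 1]),
            "slope_ci_lo": float(ci[1, 0]),
            "slope_ci_hi": float(ci[1, 1]),
            "r_squared": float(fit.rsquared),
        }
    return out


def abundance_lloq_uloq(
    cells: list[StratumCell],
    validated_levels: list[str],
    spike_by_level: dict[str, float],
) -> dict[str, float]:
    """Abundance-aware quantitation limits in ppm.

    LLOQ: 95th percentile (conservative) and mean of Q1 reportables at the
    lowest validated level; ULOQ: 5th percentile and mean of Q4 reportables
    at the highest validated level.
    """
    if not validated_levels:
        raise ValueError("validated domain is empty")
    ordered = sorted(validated_levels, key=lambda lv: spike_by_level[lv])
    lo_level, hi_level = ordered[0], ordered[-1]
    q1 = [c.reportable_ppm for c in cells if c.stratum == "Q1" and c.level == lo_level]
    q4 = [c.reportable_ppm for c in cells if c.stratum == "Q4" and c.level == hi_level]
    if not q1 or not q4:
        raise ValueError("missing Q1/Q4 cells at the boundary levels")
    return {
        "lloq_mean_ppm": float(np.mean(q1)),
        "lloq_p95_ppm": float(np.percentile(q1, 95)),
        "uloq_mean_ppm": float(np.mean(q4)),
        "uloq_p05_ppm": float(np.percentile(q4, 5)),
        "lloq_level": lo_level,
        "uloq_level": hi_level,
    }
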