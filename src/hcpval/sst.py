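"""System-suitability evaluation and Phase I individuals-moving-range charts.

Routine sequences are gated by bracketed standard injections at the
LLOQ-proximal level: the opening bracket must recover 70-130% of nominal
before the sequence starts, and the closing bracket decides release versus
deviation investigation.  Orthogonal retention-time-calibrant (RTC) metrics
separate chromatographic drift from quantitative degradation.  Run-level
metrics are monitored on I-MR charts with the standard SPC constants
(individuals limits center +/- 2.66 MRbar, moving-range UCL 3.267 MRbar).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ControlChart", "bracket_decision", "imr_chart", "rtc_metrics"]

# Phase I I-MR constants for n = 2 moving ranges: 3/d2 = 2.66, D4 = 3.267
_IMR_K = 2.66
_MR_D4 = 3.267


@dataclass
class ControlChart:
    series: np.ndarray
    center: float
    mr_bar: float
    lcl: float | None
    ucl: float | None
    mr_ucl: float | None
    violations: list[dict] = field(default_factory=list)
    spec_limits: tuple[float, float] | None = None
    limits_withheld: bool = False


def bracket_decision(opening_recovery: float, closing_recovery: float | None) -> str:
    """Sequence disposition from the opening/closing bracket recoveries (%).

    Returns ``"do not start"``, ``"deviation investigation"`` or
    ``"release"``; the 70/130 bounds are inclusive passes.
    """
    if opening_recovery < 0 or (closing_recovery is not None and closing_recovery < 0):
        raise ValueError("recoveries must be >= 0")
    if not 70.0 <= opening_recovery <= 130.0:
        return "do not start"
    if closing_recovery is None or not 70.0 <= closing_recovery <= 130.0:
        return "deviation investigation"
    return "release"


def imr_chart(
    series: np.ndarray, spec_limits: tuple[float, float] | None = None
) -> ControlChart:
    """Phase I individuals-moving-range chart.

    With fewer than 10 observations the control limits are withheld (only
    the specification-limit check runs).  Violations list individuals
    outside the control limits, moving ranges above the MR UCL, and
    spec-limit exceedances, each tagged by rule.
    """
    x = np.asarray(series, dtype=float)
    violations: list[dict] = []
    if spec_limits is not None:
        lo, hi = spec_limits
        for i, v in enumerate(x):
            if not lo <= v <= hi:
                violations.append({"index": i, "value": float(v), "rule": "spec_limit"})
    if x.size < 10:
        return ControlChart(
            series=x,
            center=float(np.mean(x)) if x.size else float("nan"),
            mr_bar=float("nan"),
            lcl=None,
            ucl=None,
            mr_ucl=None,
            violations=violations,
            spec_limits=spec_limits,
            limits_withheld=True,
        )
    center = float(np.mean(x))
    mr = np.abs(np.diff(x))
    mr_bar = float(np.mean(mr))
    lcl = center - _IMR_K * mr_bar
    ucl = center + _IMR_K * mr_bar
    mr_ucl = _MR_D4 * mr_bar
    for i, v in enumerate(x):
        if not lcl <= v <= ucl:
            violations.append({"index": i, "value": float(v), "rule": "individuals_3sigma"})
    for i, v in enumerate(mr, start=1):
        if v > mr_ucl:
            violations.append({"index": i, "value": float(v), "rule": "moving_range_ucl"})
    return ControlChart(
        series=x,
        center=center,
        mr_bar=mr_bar,
        lcl=lcl,
        ucl=ucl,
        mr_ucl=mr_ucl,
        violations=violations,
        spec_limits=spec_limits,
        limits_withheld=False,
    )


def rtc_metrics(
    observed_rt: dict[str, float],
    reference_rt: dict[str, float],
    ms1_intensities: dict[str, float],
    baseline_median: float,
) -> tuple[float, float]:
    """RTC panel metrics: median dRT (min) and median MS1 deviation (%).

    dRT is the median of (observed - reference) over the shared peptide
    panel; the MS1 deviation is 100 * (median observed MS1 / baseline
    median - 1).  A panel mismatch raises, listing the missing peptides.
    """
    missing = sorted(set(reference_rt) - set(observed_rt))
    if missing:
        raise ValueError(f"observed panel missing peptides: {missing}")
    if baseline_median <= 0:
        raise ValueError("baseline median must be > 0")
    drt = float(np.median([observed_rt[p] - reference_rt[p] for p in sorted(reference_rt)]))
    ms1_dev = 100.0 * (float(np.median(list(ms1_intensities.values()))) / baseline_median - 1.0)
    return drt, ms1_dev
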