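"""Peptide filtering and Hi3 (top-3) absolute protein quantification.

The Hi3 estimator converts a protein group's summed top-3 peptide intensity
to mass via a response factor (median intensity-per-fmol of spiked digest
standards of known amount):

    mass_ng = (I_HCP / RF) * MW * 1e-6

with I_HCP the summed intensity of the three highest-mean-intensity peptides,
RF in intensity/fmol, and MW the average molecular weight (Da) of the group's
lead protein.  Total HCP is the sum over all quantified groups and is the
reportable value; ppm = ng HCP per mg product.

Filter chain (fixed order): single-hit exclusion -> total-ion-current
normalization -> intensity-deviation screening -> modified Z-score outlier
removal -> replicate-CV filter.  Normalization precedes all outlier
statistics so run-scale differences never masquerade as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight

from .core import PeptideObservation, ResponseFactor

__all__ = [
    "FilterConfig",
    "tic_normalize",
    "single_hit_filter",
    "intensity_deviation_filter",
    "modified_zscore_filter",
    "cv_filter",
    "apply_filter_chain",
    "response_factor",
    "hi3_protein_mass",
    "total_hcp",
    "to_ppm",
    "compute_mw",
]


@dataclass(frozen=True)
class FilterConfig:
    modified_z_cutoff: float = 3.5
    cv_cutoff_percent: float = 20.0
    intensity_deviation_factor: float = 10.0
    single_hit_min_runs: int = 2

    def __post_init__(self) -> None:
        if min(
            self.modified_z_cutoff,
            self.cv_cutoff_percent,
            self.intensity_deviation_factor,
            self.single_hit_min_runs,
        ) <= 0:
            raise ValueError("all filter cutoffs must be > 0")


def _obs_frame(observations: Iterable[PeptideObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence": [o.sequence for o in observations],
            "run_id": [o.run_id for o in observations],
            "intensity": [o.intensity for o in observations],
        }
    )


def tic_normalize(intensities_by_run: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    """Scale each run so its total intensity equals the median run total."""
    totals = {r: float(np.sum(v)) for r, v in intensities_by_run.items()}
    if any(t <= 0 for t in totals.values()):
        zero = [r for r, t in totals.items() if t <= 0]
        raise ValueError(f"runs with zero total intensity: {zero}")
    target = float(np.median(list(totals.values())))
    return {
        r: np.asarray(v, dtype=float) * (target / totals[r]) for r, v in intensities_by_run.items()
    }


def single_hit_filter(runs_observed: int, min_runs: int = 2) -> bool:
    """Keep a peptide only if observed in at least ``min_runs`` injections."""
    return runs_observed >= min_runs


def intensity_deviation_filter(
    values: Sequence[float], cross_run_median: float, factor: float = 10.0
) -> np.ndarray:
    """Boolean keep-mask: drop values > ``factor`` x (or < 1/factor of) the
    peptide's cross-run median intensity."""
    v = np.asarray(values, dtype=float)
    if cross_run_median <= 0:
        return np.ones_like(v, dtype=bool)
    ratio = v / cross_run_median
    return (ratio <= factor) & (ratio >= 1.0 / factor)


def modified_zscore_filter(values: Sequence[float], cutoff: float = 3.5) -> np.ndarray:
    """Keep-mask from the modified Z-score M_i = 0.6745 (x_i - median) / MAD.

    With MAD = 0 the score falls back to the mean absolute deviation with
    0.7979 scaling; if that is also zero every value is kept.  Fewer than
    three values pass through unfiltered (too few points for a robust scale).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return np.ones_like(v, dtype=bool)
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad > 0:
        m = 0.6745 * (v - med) / mad
    else:
        meanad = np.mean(np.abs(v - med))
        if meanad == 0:
            return np.ones_like(v, dtype=bool)
        m = (v - med) / (1.253314 * meanad)  # 0.7979 scaling: M = (x-med)/(1.2533*meanAD)
    return np.abs(m) <= cutoff


def cv_filter(values: Sequence[float], cutoff_percent: float = 20.0) -> bool:
    """Keep a peptide if its replicate CV (100*SD/mean, sample SD) <= cutoff."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV filter needs >= 2 replicate values")
    mean = v.mean()
    if mean == 0:
        return False
    cv = 100.0 * v.std(ddof=1) / mean
    return bool(cv <= cutoff_percent)


def apply_filter_chain(
    observations: Sequence[PeptideObservation],
    config: FilterConfig = FilterConfig(),
) -> pd.DataFrame:
    """Run the full filter chain over one replicate block's observations.

    Returns a tidy frame (sequence, run_id, intensity) of surviving,
    TIC-normalized observations.  The five stages are applied in order and
    the sweep repeats until the kept row set stabilizes (removals can leave
    a peptide newly single-hit or unbalance run totals); at the fixed point
    run totals are equal, so re-filtering the output is the identity and
    the chain is idempotent.
    """
    df = _obs_frame(observations)
    for _ in range(20):
        if df.empty:
            return df.reset_index(drop=True)
        before = len(df)
        df = _filter_sweep(df, config)
        if len(df) == before:
            break
    return df.reset_index(drop=True)


def _filter_sweep(df: pd.DataFrame, config: FilterConfig) -> pd.DataFrame:
    # 1. single-hit exclusion
    runs_per_pep = df.groupby("sequence")["run_id"].nunique()
    df = df[df["sequence"].map(runs_per_pep) >= config.single_hit_min_runs]
    if df.empty:
        return df
    # 2. TIC normalization
    by_run = {r: g["intensity"].to_numpy() for r, g in df.groupby("run_id")}
    normed = tic_normalize(by_run)
    df = df.copy()
    for r, vals in normed.items():
        df.loc[df["run_id"] == r, "intensity"] = vals

    # 3. intensity-deviation screening (per peptide, vs cross-run median)
    def _dev(g: pd.DataFrame) -> pd.Series:
        mask = intensity_deviation_filter(
            g["intensity"].to_numpy(),
            float(np.median(g["intensity"])),
            config.intensity_deviation_factor,
        )
        return pd.Series(mask, index=g.index)

    df = df[df.groupby("sequence", group_keys=False).apply(_dev, include_groups=False)]

    # 4. modified Z-score outlier removal (per peptide across runs)
    def _mz(g: pd.DataFrame) -> pd.Series:
        mask = modified_zscore_filter(g["intensity"].to_numpy(), config.modified_z_cutoff)
        return pd.Series(mask, index=g.index)

    df = df[df.groupby("sequence", group_keys=False).apply(_mz, include_groups=False)]

    # 5. replicate-CV filter (whole peptide kept or dropped)
    def _cv_ok(g: pd.Series) -> bool:
        v = g.to_numpy()
        if v.size < 2:
            return True
        return cv_filter(v, config.cv_cutoff_percent)

    ok = df.groupby("sequence")["intensity"].apply(_cv_ok)
    return df[df["sequence"].map(ok)]


def response_factor(standards: Sequence[tuple[float, float]]) -> ResponseFactor:
    """Median intensity-per-fmol over the spiked digest standards."""
    if len(standards) == 0:
        raise ValueError("at least one standard is required")
    if any(n <= 0 for _, n in standards):
        raise ValueError("standard amounts must be > 0 fmol")
    rf = float(np.median([i / n for i, n in standards]))
    return ResponseFactor(standards=tuple((float(i), float(n)) for i, n in standards), rf=rf)


def hi3_protein_mass(
    peptide_mean_intensities: Mapping[str, float],
    rf: float,
    mw_da: float,
) -> tuple[float, tuple[str, ...]]:
    """Hi3 mass (ng) of one protein group and the three peptides summed.

    Requires >= 3 quantifiable peptides; the three with the highest mean
    intensity are summed (ties broken by sequence for determinism).

    Raises
    ------
    ValueError
        With reason code ``"too_few_peptides"`` when fewer than three
        peptides are quantifiable — the group is then not quantified.
    """
    if rf <= 0 or mw_da <= 0:
        raise ValueError("RF and MW must be > 0")
    if len(peptide_mean_intensities) < 3:
        raise ValueError("too_few_peptides")
    top3 = sorted(peptide_mean_intensities.items(), key=lambda kv: (-kv[1], kv[0]))[:3]
    i_hcp = float(sum(v for _, v in top3))
    mass_ng = (i_hcp / rf) * mw_da * 1e-6  # fmol * Da * 1e-6 = ng
    return mass_ng, tuple(p for p, _ in top3)


def total_hcp(group_masses_ng: Iterable[float]) -> float:
    """Total HCP (ng): sum of all inferred protein-group masses."""
    return float(sum(group_masses_ng))


def to_ppm(total_ng: float, mab_mg: float) -> float:
    """ng HCP per mg product."""
    if mab_mg <= 0:
        raise ValueError("product mass must be > 0 mg")
    return total_ng / mab_mg


def compute_mw(sequence: str) -> float:
    """Average (not monoisotopic) molecular weight of a protein sequence, Da."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        return float(molecular_weight(sequence.upper(), seq_type="protein", monoisotopic=False))
    except (ValueError, KeyError) as exc:
        raise ValueError(f"unknown residue in sequence: {exc}") from exc
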