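"""Entrapment-based empirical false-discovery-proportion (FDP) estimation.

An entrapment database is a negative-control sequence space searched
alongside the real (target) database.  Any entrapment peptide accepted at a
q-value threshold tau is a known false discovery, so the acceptance-rate
ratio calibrates the peptide-level identification error independently of
target-decoy competition:

    FDP(tau) = N_E(tau) * (1 + 1/r) / N_D(tau)

where N_E is the number of unique entrapment peptides at or below tau, N_D
the total number of unique accepted peptides (target + entrapment), and r
the entrapment-to-target unique-peptide ratio.  The (1 + 1/r) factor adds
the expected false matches hiding in the target space (N_E/r) to the
observed entrapment matches.  For r = 1 the estimator reduces to 2 N_E/N_D.

Two construction routes are supported: shuffling the target peptidome with
preserved C-terminal (cleavage-site) residues, and trimming a foreign
proteome of any peptide overlapping the target peptidome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .digest import DigestSpec, theoretical_digest

__all__ = [
    "EntrapmentResult",
    "build_shuffled_entrapment",
    "trim_foreign_entrapment",
    "collapse_to_peptides",
    "fdp_estimate",
    "fdp_curve",
    "bootstrap_fdp_bands",
    "wilson_interval",
    "protein_level_fdp",
]


@dataclass
class EntrapmentResult:
    """FDP curve over a threshold grid, with bootstrap and Wilson uncertainty."""

    tau_grid: np.ndarray
    n_entrapment: np.ndarray
    n_total: np.ndarray
    r: float
    fdp: np.ndarray
    bootstrap_lo: np.ndarray | None = None
    bootstrap_hi: np.ndarray | None = None
    wilson_95: tuple[float, float] | None = None


def build_shuffled_entrapment(
    target_fasta: dict[str, str],
    spec: DigestSpec = DigestSpec(),
    seed: int = 0,
    max_attempts: int = 20,
) -> tuple[set[str], float]:
    """Shuffled-peptidome entrapment set and the achieved ratio r.

    Each target peptide's internal residues are permuted while the
    C-terminal residue (the proteolytic cleavage site) is kept fixed.
    Shuffles colliding with the target peptidome are redrawn up to
    ``max_attempts`` times, then the peptide is dropped; r is therefore the
    achieved, not nominal, ratio.
    """
    rng = np.random.default_rng(seed)
    target: set[str] = set()
    for seq in target_fasta.values():
        target |= theoretical_digest(seq, spec)
    entrap: set[str] = set()
    for pep in sorted(target):  # sorted for seed-stable iteration order
        body = list(pep[:-1])
        for _ in range(max_attempts):
            rng.shuffle(body)
            cand = "".join(body) + pep[-1]
            if cand not in target and cand not in entrap:
                entrap.add(cand)
                break
        # unresolvable (e.g. homopolymers, length-1 bodies) -> dropped
    r = len(entrap) / len(target) if target else 0.0
    return entrap, r


def trim_foreign_entrapment(foreign_peptides: set[str], target_peptidome: set[str]) -> set[str]:
    """Foreign-proteome entrapment: remove any peptide shared with the target."""
    return set(foreign_peptides) - set(target_peptidome)


def collapse_to_peptides(psm_rows: pd.DataFrame) -> pd.DataFrame:
    """Collapse PSM rows to unique stripped peptides with the minimum q-value.

    ``psm_rows`` needs columns ``sequence``, ``q_value``, ``label`` (each
    label in {"target", "entrapment"}).  A sequence carrying both labels is
    a construction error and raises.
    """
    labels = psm_rows.groupby("sequence")["label"].nunique()
    conflicted = labels[labels > 1]
    if len(conflicted):
        raise ValueError(f"conflicting labels for sequences: {list(conflicted.index)[:5]}")
    out = (
        psm_rows.groupby("sequence", as_index=False)
        .agg(q_value=("q_value", "min"), label=("label", "first"))
        .sort_values("sequence", ignore_index=True)
    )
    return out


def fdp_estimate(peptides: pd.DataFrame, tau: float, r: float) -> float:
    """Point FDP estimate at threshold ``tau``; 0 when nothing is accepted."""
    if r <= 0:
        raise ValueError("r must be > 0")
    accepted = peptides[peptides["q_value"] <= tau]
    n_d = len(accepted)
    if n_d == 0:
        return 0.0
    n_e = int((accepted["label"] == "entrapment").sum())
    return n_e * (1.0 + 1.0 / r) / n_d


def fdp_curve(peptides: pd.DataFrame, tau_grid: np.ndarray, r: float) -> EntrapmentResult:
    """FDP over a threshold grid, with the monotone N_E/N_D counts."""
    q = peptides["q_value"].to_numpy()
    is_e = (peptides["label"] == "entrapment").to_numpy()
    tau_grid = np.asarray(tau_grid, dtype=float)
    order = np.argsort(q, kind="stable")
    qs, es = q[order], is_e[order]
    idx = np.searchsorted(qs, tau_grid, side="right")
    cum_e = np.concatenate([[0], np.cumsum(es)])
    n_total = idx.astype(int)
    n_e = cum_e[idx].astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        fdp = np.where(n_total > 0, n_e * (1.0 + 1.0 / r) / np.maximum(n_total, 1), 0.0)
    return EntrapmentResult(tau_grid=tau_grid, n_entrapment=n_e, n_total=n_total, r=r, fdp=fdp)


def bootstrap_fdp_bands(
    peptides: pd.DataFrame,
    tau_grid: np.ndarray,
    r: float,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise 95% percentile bands of the FDP curve.

    Unique stripped sequences are resampled with replacement and the curve
    recomputed per resample.
    """
    if n_boot < 200:
        raise ValueError("need >= 200 bootstrap resamples")
    rng = np.random.default_rng(seed)
    q = peptides["q_value"].to_numpy()
    is_e = (peptides["label"] == "entrapment").to_numpy()
    n = len(q)
    tau_grid = np.asarray(tau_grid, dtype=float)
    curves = np.empty((n_boot, tau_grid.size))
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        qb, eb = q[take], is_e[take]
        order = np.argsort(qb, kind="stable")
        qs, es = qb[order], eb[order]
        idx = np.searchsorted(qs, tau_grid, side="right")
        cum_e = np.concatenate([[0], np.cumsum(es)])
        n_total = idx
        n_e = cum_e[idx]
        curves[b] = np.where(n_total > 0, n_e * (1.0 + 1.0 / r) / np.maximum(n_total, 1), 0.0)
    lo = np.percentile(curves, 2.5, axis=0)
    hi = np.percentile(curves, 97.5, axis=0)
    return lo, hi


def wilson_interval(successes: int, n: int, scale_factor: float = 1.0) -> tuple[float, float]:
    """Two-sided 95% Wilson score interval for a proportion, optionally scaled.

    The scale factor (1 + 1/r) converts the raw entrapment proportion
    interval onto the FDP scale.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=0.05, method="wilson")
    return float(lo) * scale_factor, float(hi) * scale_factor


def protein_level_fdp(peptide_fdp: float, k_required: int = 3) -> float:
    """Probability of ``k_required`` independent false peptides co-occurring.

    Under the independence approximation, requiring k concordant peptides
    per quantified group attenuates the peptide-level error geometrically:
    FDP^k.  At peptide FDP ~ 0.009 and k = 3 this is on the order of 1e-7.
    """
    if not 0 <= peptide_fdp < 1:
        raise ValueError("peptide_fdp must be in [0, 1)")
    if k_required < 1:
        raise ValueError("k_required must be >= 1")
    return peptide_fdp**k_required
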