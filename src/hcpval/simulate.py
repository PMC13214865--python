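"""Synthetic-data generators with known ground truth for every pipeline stage.

Every generator is a pure function of (parameters, seed): the same seed
yields bit-identical output.  The defaults reproduce the reference study
conditions: a four-assay hierarchical design (assay 1 with seven levels,
assays 2-4 with five), a compressed linear calibration (slope 0.798,
intercept 1.25 ng), a two-level Gaussian relative-error hierarchy
(between-assay and within-assay SDs on the percent scale), stratum-dependent
calibration for a log-normal protein-abundance population, and
target/entrapment q-value tables with a known true false-discovery
proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PeptideObservation, ReplicateBlock, ValidationDesign, default_design

__all__ = [
    "SyntheticTruth",
    "gen_replicate_blocks",
    "gen_protein_ppm_table",
    "gen_peptide_table",
    "gen_entrapment_scores",
]

#: stratum calibration (slope, intercept ppm) for Q1..Q4, low -> high abundance
_DEFAULT_STRATA = (
    (1.0588, 0.26),
    (0.9906, 0.81),
    (0.9029, 3.71),
    (0.7986, 29.57),
)


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator-side ground truth.

    beta0/beta1 define the aggregate calibration Y = beta0 + beta1*mu before
    noise; sigma_w/sigma_b are the within-/between-assay relative-error SDs
    in percent; stratum_params are per-stratum (slope, intercept ppm) for the
    abundance-stratified generator; the abundance population is log-normal in
    ppm at the anchor level; true_fdp is the false fraction among accepted
    peptides at q = 0.01.
    """

    beta0: float = 1.25
    beta1: float = 0.798
    sigma_w: float = 2.3
    sigma_b: float = 1.5
    stratum_params: tuple[tuple[float, float], ...] = _DEFAULT_STRATA
    abundance_log_mean: float = float(np.log(20.0))
    abundance_log_sd: float = 1.5
    protein_cv: float = 5.0
    true_fdp: float = 0.009
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_w < 0 or self.sigma_b < 0:
            raise ValueError("sigma_w and sigma_b must be >= 0")
        if not 0 <= self.true_fdp < 1:
            raise ValueError("true_fdp must be in [0, 1)")

    def true_bias(self, nominal_ng: float) -> float:
        """Noise-free relative bias (percent) implied by the calibration."""
        return 100.0 * (self.beta0 / nominal_ng + self.beta1 - 1.0)

    def re_scale(self, nominal_ng: float) -> float:
        """Recovery factor (beta0 + beta1*mu)/mu mapping the multiplicative
        noise SD onto the relative-error-vs-nominal scale."""
        return self.beta0 / nominal_ng + self.beta1

    def true_re_sd(self, nominal_ng: float) -> float:
        """SD (percent) of a future replicate-block relative error at mu."""
        return self.re_scale(nominal_ng) * float(np.hypot(self.sigma_w, self.sigma_b))

    def draw_future_re(self, nominal_ng: float, n: int, rng: np.random.Generator) -> np.ndarray:
        """Future replicate-block relative errors (each from a fresh assay)."""
        u = rng.normal(0.0, self.sigma_b, n)
        e = rng.normal(0.0, self.sigma_w, n)
        return self.true_bias(nominal_ng) + self.re_scale(nominal_ng) * (u + e)


def gen_replicate_blocks(
    design: ValidationDesign | None = None, truth: SyntheticTruth = SyntheticTruth()
) -> list[ReplicateBlock]:
    """Replicate-block reportables under the hierarchical error model.

    Per assay and level draw u ~ N(0, sigma_b^2), shared by all of that
    assay's blocks at the level; per block draw e ~ N(0, sigma_w^2); the
    reportable is (beta0 + beta1*mu_j) * (1 + (u + e)/100).  Levels missing
    from an assay's plan are simply absent.  The between-assay effect is
    drawn per (assay, level) — the assay-grouped error structure every
    per-level variance decomposition sees — rather than shared across a
    whole assay, matching replicate-block responses that follow a common
    calibration function without assay-specific displacement.
    """
    design = design or default_design()
    rng = np.random.default_rng(truth.seed)
    blocks: list[ReplicateBlock] = []
    for assay in sorted(design.assay_layout):
        plan = design.assay_layout[assay]
        for label in design.level_labels:
            if label not in plan.levels:
                continue
            u_a = rng.normal(0.0, truth.sigma_b) if truth.sigma_b > 0 else 0.0
            mu = design.nominal(label)
            base = truth.beta0 + truth.beta1 * mu
            for k in range(plan.n_preparations):
                e = rng.normal(0.0, truth.sigma_w) if truth.sigma_w > 0 else 0.0
                y = base * (1.0 + (u_a + e) / 100.0)
                blocks.append(
                    ReplicateBlock(
                        assay=assay,
                        level=label,
                        block=k + 1,
                        reportable_ng=max(y, 0.0),
                        nominal_ng=mu,
                    )
                )
    return blocks


def gen_protein_ppm_table(
    truth: SyntheticTruth = SyntheticTruth(),
    n_proteins: int = 1000,
    design: ValidationDesign | None = None,
) -> pd.DataFrame:
    """Per-protein ppm observations by (assay, level, block) with strata truth.

    Each protein draws a base abundance (its theoretical ppm at the anchor
    level L4) from the log-normal population and belongs to a truth stratum
    by the same 5/25/50/75/100-percentile scheme the pipeline uses.  The
    theoretical ppm at level j scales the base by the spike ratio
    S_j / S_anchor; the observed ppm applies the stratum calibration
    (intercept + slope * theoretical) and then the hierarchical block noise
    shared by all proteins in a cell, plus independent per-protein noise.

    Returns a long frame: protein, assay, level, block, ppm, theoretical_ppm,
    stratum (truth label, "" for proteins below the 5th percentile).
    """
    design = design or default_design()
    if n_proteins < 120:
        raise ValueError("need >= 120 proteins for stratified analysis")
    rng = np.random.default_rng(truth.seed)
    base = rng.lognormal(truth.abundance_log_mean, truth.abundance_log_sd, size=n_proteins)
    cut = np.percentile(base, [5, 25, 50, 75])
    stratum_idx = np.searchsorted(cut, base, side="right") - 1  # -1 below P5, 0..3 = Q1..Q4
    anchor = design.level_labels[3] if len(design.level_labels) >= 4 else design.level_labels[-1]
    s_anchor = design.nominal(anchor)
    slopes = np.array([p[0] for p in truth.stratum_params])
    intercepts = np.array([p[1] for p in truth.stratum_params])
    prot_slope = np.where(stratum_idx >= 0, slopes[np.maximum(stratum_idx, 0)], 1.0)
    prot_int = np.where(stratum_idx >= 0, intercepts[np.maximum(stratum_idx, 0)], 0.0)

    rows = []
    for assay in sorted(design.assay_layout):
        plan = design.assay_layout[assay]
        for label in design.level_labels:
            if label not in plan.levels:
                continue
            u_a = rng.normal(0.0, truth.sigma_b) if truth.sigma_b > 0 else 0.0
            ratio = design.nominal(label) / s_anchor
            theo = base * ratio
            expected = prot_int + prot_slope * theo
            for k in range(plan.n_preparations):
                e = rng.normal(0.0, truth.sigma_w) if truth.sigma_w > 0 else 0.0
                noise_p = (
                    rng.normal(0.0, truth.protein_cv, size=n_proteins)
                    if truth.protein_cv > 0
                    else np.zeros(n_proteins)
                )
                ppm = expected * (1.0 + (u_a + e) / 100.0) * (1.0 + noise_p / 100.0)
                rows.append(
                    pd.DataFrame(
                        {
                            "protein": [f"P{i:05d}" for i in range(n_proteins)],
                            "assay": assay,
                            "level": label,
                            "block": k + 1,
                            "ppm": np.maximum(ppm, 0.0),
                            "theoretical_ppm": theo,
                            "stratum": np.where(
                                stratum_idx >= 0,
                                np.array([f"Q{q + 1}" for q in np.maximum(stratum_idx, 0)]),
                                "",
                            ),
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def gen_peptide_table(
    protein_fmol: dict[str, float],
    peptides_per_protein: dict[str, list[str]],
    rf: float,
    n_injections: int = 3,
    noise_cv: float = 0.0,
    outlier_rate: float = 0.0,
    dropout_rate: float = 0.0,
    seed: int = 0,
    assay: str = "A1",
    level: str = "L1",
) -> list[PeptideObservation]:
    """Peptide intensity observations for one replicate block.

    Each protein must carry >= 3 theoretical peptides.  Its three
    highest-responding peptides each carry intensity fmol * rf / 3 (so the
    Hi3 sum recovers fmol * rf exactly at zero noise); any further peptides
    respond at a lower, deterministically decaying share.  Multiplicative
    Gaussian noise (``noise_cv`` percent), spike-in outliers (intensity x 50
    at ``outlier_rate``) and missingness (``dropout_rate``) emulate the
    failure modes the filter chain must absorb.
    """
    rng = np.random.default_rng(seed)
    out: list[PeptideObservation] = []
    for prot in sorted(protein_fmol):
        peps = peptides_per_protein[prot]
        if len(peps) < 3:
            raise ValueError(f"protein {prot!r} needs >= 3 theoretical peptides")
        fmol = protein_fmol[prot]
        for rank, pep in enumerate(sorted(peps)):
            share = (1.0 / 3.0) if rank < 3 else (1.0 / 3.0) * 0.5 ** (rank - 2)
            base = fmol * rf * share
            for inj in range(1, n_injections + 1):
                if dropout_rate > 0 and rng.random() < dropout_rate:
                    continue
                val = base
                if noise_cv > 0:
                    val *= 1.0 + rng.normal(0.0, noise_cv / 100.0)
                if outlier_rate > 0 and rng.random() < outlier_rate:
                    val *= 50.0
                out.append(
                    PeptideObservation(
                        sequence=pep,
                        accessions=(prot,),
                        run_id=f"{assay}_{level}_inj{inj}",
                        assay=assay,
                        level=level,
                        preparation=1,
                        injection=inj,
                        intensity=max(val, 0.0),
                        q_value=0.001,
                        is_heavy=True,
                    )
                )
    return out


def gen_entrapment_scores(
    n_target: int = 20000,
    r: float = 1.0,
    true_fdp: float = 0.009,
    seed: int = 0,
) -> pd.DataFrame:
    """Target/entrapment q-value table with known true FDP at q = 0.01.

    ``n_target`` true target peptides get q ~ U(0, 0.005) (all accepted at
    0.01).  False matches land in target and entrapment space in proportion
    to the space sizes (1 : r) with q ~ U(0, 1), sized so the expected false
    fraction among acceptances at q = 0.01 equals ``true_fdp``.  Columns:
    sequence, q_value, label, is_false (truth).
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    if not 0 <= true_fdp < 1:
        raise ValueError("true_fdp must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = {"q_value": [], "label": [], "is_false": []}
    q_true = rng.uniform(0.0, 0.005, size=n_target)
    rows["q_value"].append(q_true)
    rows["label"].append(np.repeat("target", n_target))
    rows["is_false"].append(np.zeros(n_target, dtype=bool))
    if true_fdp > 0:
        # expected accepted false at 0.01: n_false_e * (1 + 1/r) * 0.01
        n_false_e = int(round(n_target * true_fdp / ((1 - true_fdp) * 0.01 * (1 + 1 / r))))
        n_false_t = int(round(n_false_e / r))
        for n_f, lab in ((n_false_t, "target"), (n_false_e, "entrapment")):
            rows["q_value"].append(rng.uniform(0.0, 1.0, size=n_f))
            rows["label"].append(np.repeat(lab, n_f))
            rows["is_false"].append(np.ones(n_f, dtype=bool))
    q = np.concatenate(rows["q_value"])
    df = pd.DataFrame(
        {
            "sequence": [f"PEP{i:07d}K" for i in range(q.size)],
            "q_value": q,
            "label": np.concatenate(rows["label"]),
            "is_false": np.concatenate(rows["is_false"]),
        }
    )
    return df
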