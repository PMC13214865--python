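"""Pipeline orchestration: run all validation stages and assemble the report.

``run_pipeline`` ties the stages together (quantification inputs ->
linearity -> trueness/precision -> tolerance intervals -> stratified
analysis -> identification error -> agreement -> SST) and emits a single
JSON-serializable report whose verdict (validated range, LLOQ,
abundance-aware limits) is derivable from the contained tables alone.
Optional stages whose inputs are absent are marked absent, never silently
skipped.  Under a fixed seed the report is byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .agreement import agreement_summary
from .core import ReplicateBlock, ValidationDesign, default_design
from .entrapment import bootstrap_fdp_bands, fdp_curve, wilson_interval
from .linearity import implied_relative_bias, wls_calibration
from .simulate import SyntheticTruth, gen_entrapment_scores, gen_protein_ppm_table, gen_replicate_blocks
from .sst import bracket_decision, imr_chart
from .stratified import (
    abundance_lloq_uloq,
    assign_strata,
    cell_reportables,
    stratum_accuracy_profile,
    stratum_relative_errors,
)
from .tolerance import BootstrapSpec, accuracy_profile

__all__ = ["default_config", "run_pipeline", "report_to_json"]


def default_config(seed: int = 0) -> dict[str, Any]:
    """Synthetic end-to-end configuration mirroring the reference design."""
    return {
        "seed": seed,
        "design": "default",
        "truth": {},
        "stages": {
            "linearity": True,
            "accuracy": True,
            "stratified": True,
            "fdp": True,
            "agreement": False,
            "sst": False,
        },
        "bootstrap": {"n_outer": 1000, "n_inner": 500},
        "stratified": {"n_proteins": 600, "cell_bootstrap": 500},
        "fdp": {"n_target": 20000, "r": 1.0},
        "agreement_pairs": None,  # optional path to a two-column TSV
        "sst_series": None,  # optional path to a run-level metrics TSV
    }


def _validate_config(config: dict[str, Any]) -> None:
    required = {"seed", "design", "truth", "stages"}
    missing = required - set(config)
    if missing:
        raise ValueError(f"config missing keys: {sorted(missing)}")
    if not isinstance(config["seed"], int):
        raise ValueError("seed must be an integer")


def run_pipeline(
    config: dict[str, Any],
    blocks: list[ReplicateBlock] | None = None,
    design: ValidationDesign | None = None,
) -> dict[str, Any]:
    """Execute the configured stages and return the validation report.

    Without explicit ``blocks`` the synthetic generator supplies every
    input, so the full report is reproducible from (config, seed) alone.
    """
    _validate_config(config)
    seed = int(config["seed"])
    design = design or default_design()
    truth = SyntheticTruth(seed=seed, **config.get("truth", {}))
    stages = config["stages"]
    report: dict[str, Any] = {
        "software": {"package": "hcpval", "version": __version__},
        "seed": seed,
        "config": config,
        "design": {
            "levels": {lv.label: lv.nominal_ng for lv in design.levels},
            "beta": design.beta,
            "acceptance_limit_aggregate": design.acceptance_limit_aggregate,
            "acceptance_limit_stratified": design.acceptance_limit_stratified,
        },
    }
    if blocks is None:
        blocks = gen_replicate_blocks(design, truth)
        report["inputs"] = {"source": "synthetic", "truth": asdict(truth)}
    else:
        report["inputs"] = {"source": "provided", "n_blocks": len(blocks)}

    if stages.get("linearity", True):
        fit = wls_calibration(blocks)
        report["linearity"] = {
            "intercept_ng": fit.beta0,
            "slope": fit.beta1,
            "intercept_se_hc3": fit.se_hc3[0],
            "slope_se_hc3": fit.se_hc3[1],
            "intercept_ci95": list(fit.ci95_hc3[0]),
            "slope_ci95": list(fit.ci95_hc3[1]),
            "r_squared": fit.r_squared,
            "p_intercept_eq_0": fit.p_beta0_eq_0,
            "p_slope_eq_1": fit.p_beta1_eq_1,
            "implied_bias_at_top_percent": implied_relative_bias(
                fit.beta0, fit.beta1, design.levels[-1].nominal_ng
            ),
        }

    if stages.get("accuracy", True):
        bs_cfg = config.get("bootstrap", {})
        spec = BootstrapSpec(
            n_outer=int(bs_cfg.get("n_outer", 1000)),
            n_inner=int(bs_cfg.get("n_inner", 500)),
            seed=seed,
        )
        prof = accuracy_profile(blocks, design, bootstrap=spec)
        report["accuracy"] = {
            "levels": [
                {
                    "level": s.level,
                    "spike_ng": s.nominal_ng,
                    "bias_percent": s.bias,
                    "sigma_w": s.sigma_w,
                    "sigma_b": s.sigma_b,
                    "sigma_t": s.sigma_t,
                    "sigma_t_pred": float(prof["variance_model"].predict(s.nominal_ng)),
                    "df_within": s.df_within,
                    "df_between": s.df_between,
                    "truncated": s.truncated,
                    "nu_eff": prof["beta_tis"][s.level].nu_eff,
                    "beta_ti": [
                        prof["beta_tis"][s.level].lower,
                        prof["beta_tis"][s.level].upper,
                    ],
                    "content_ti": [
                        prof["content_tis"][s.level].lower,
                        prof["content_tis"][s.level].upper,
                    ]
                    if prof["content_tis"]
                    else None,
                    "pass": prof["decisions"][s.level],
                }
                for s in prof["level_stats"]
            ],
            "variance_model": {
                "a": prof["variance_model"].a,
                "b": prof["variance_model"].b,
            },
            "verdict": prof["range"],
        }

    if stages.get("stratified", True):
        st_cfg = config.get("stratified", {})
        ppm = gen_protein_ppm_table(
            truth, n_proteins=int(st_cfg.get("n_proteins", 600)), design=design
        )
        anchor = "L4"
        anchor_means = (
            ppm[ppm["level"] == anchor].groupby("protein")["ppm"].mean()
        )
        strat = assign_strata(anchor_means, anchor_level=anchor)
        cells, excluded = cell_reportables(
            ppm, strat, n_boot=int(st_cfg.get("cell_bootstrap", 500)), seed=seed
        )
        spike = {lv.label: lv.nominal_ng for lv in design.levels}
        cells = stratum_relative_errors(cells, spike, anchor_level=anchor)
        prof = stratum_accuracy_profile(
            cells, spike, beta=design.beta, acceptance_limit=design.acceptance_limit_stratified
        )
        limits = (
            abundance_lloq_uloq(cells, prof["validated_levels"], spike)
            if prof["validated_levels"]
            else None
        )
        report["stratified"] = {
            "n_proteins": int(st_cfg.get("n_proteins", 600)),
            "excluded_cells": len(excluded),
            "excluded_proteins_below_p5": len(strat.excluded_below_p5),
            "validated_levels": prof["validated_levels"],
            "tolerance_intervals": {
                f"{lv}:{b}": [ti.lower, ti.upper, bool(ti.passed)]
                for (lv, b), ti in sorted(prof["tolerance_intervals"].items())
            },
            "limits": limits,
        }

    if stages.get("fdp", True):
        fd_cfg = config.get("fdp", {})
        scores = gen_entrapment_scores(
            n_target=int(fd_cfg.get("n_target", 20000)),
            r=float(fd_cfg.get("r", 1.0)),
            true_fdp=truth.true_fdp,
            seed=seed,
        )
        tau_grid = np.array([0.001, 0.002, 0.005, 0.01, 0.02, 0.05])
        curve = fdp_curve(scores, tau_grid, r=float(fd_cfg.get("r", 1.0)))
        lo, hi = bootstrap_fdp_bands(
            scores, tau_grid, r=float(fd_cfg.get("r", 1.0)), n_boot=200, seed=seed
        )
        i01 = int(np.argmin(np.abs(tau_grid - 0.01)))
        wil = wilson_interval(
            int(curve.n_entrapment[i01]),
            int(curve.n_total[i01]),
            scale_factor=1.0 + 1.0 / curve.r,
        )
        report["identification_error"] = {
            "tau": tau_grid.tolist(),
            "n_entrapment": curve.n_entrapment.tolist(),
            "n_total": curve.n_total.tolist(),
            "fdp": curve.fdp.tolist(),
            "band_lo": lo.tolist(),
            "band_hi": hi.tolist(),
            "wilson_95_at_0.01": list(wil),
            "fdp_at_0.01": float(curve.fdp[i01]),
        }

    if stages.get("agreement", False):
        path = config.get("agreement_pairs")
        if path is None:
            report["agreement"] = {"status": "absent", "reason": "no paired input configured"}
        else:
            pairs = pd.read_csv(path, sep="\t")
            x, y = pairs.iloc[:, 0].to_numpy(), pairs.iloc[:, 1].to_numpy()
            stats = agreement_summary(
                x, y, limit_percent=design.acceptance_limit_aggregate, seed=seed
            )
            report["agreement"] = {
                "deming_slope": stats.deming_slope,
                "deming_intercept": stats.deming_intercept,
                "slope_ci95": list(stats.slope_ci95),
                "intercept_ci95": list(stats.intercept_ci95),
                "ccc": stats.ccc,
                "ba_bias_percent": stats.ba_bias_percent,
                "ba_loa": list(stats.ba_loa),
                "within_limit": stats.within_limit,
            }

    if stages.get("sst", False):
        path = config.get("sst_series")
        if path is None:
            report["sst"] = {"status": "absent", "reason": "no run-level metrics configured"}
        else:
            series = pd.read_csv(path, sep="\t")
            charts = {}
            for col in series.columns:
                chart = imr_chart(series[col].to_numpy())
                charts[col] = {
                    "center": chart.center,
                    "mr_bar": chart.mr_bar,
                    "lcl": chart.lcl,
                    "ucl": chart.ucl,
                    "mr_ucl": chart.mr_ucl,
                    "n_violations": len(chart.violations),
                    "limits_withheld": chart.limits_withheld,
                }
            report["sst"] = {"charts": charts}

    return report


def report_to_json(report: dict[str, Any], path: str | Path | None = None) -> str:
    """Serialize the report deterministically (sorted keys, fixed format)."""
    text = json.dumps(report, indent=2, sort_keys=True, default=_jsonable)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
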