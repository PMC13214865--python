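"""Abundance stratification, cell reportables, and stratified accuracy."""

import numpy as np
import pandas as pd
import pytest

from hcpval.core import default_design
from hcpval.simulate import SyntheticTruth, gen_protein_ppm_table
from hcpval.stratified import (
    StratumCell,
    abundance_lloq_uloq,
    assign_strata,
    bootstrap_reportable,
    cell_reportables,
    stratum_accuracy_profile,
    stratum_relative_errors,
)

SPIKE = {f"L{i+1}": ng for i, ng in enumerate((20, 30, 40, 50, 60, 70, 80))}


class TestAssignStrata:
    def test_percentile_arithmetic_on_ranks(self):
        vals = pd.Series(np.arange(1.0, 1001.0), index=[f"P{i:04d}" for i in range(1000)])
        strat = assign_strata(vals)
        sizes = pd.Series(strat.membership).value_counts()
        assert len(strat.excluded_below_p5) == 50
        assert sizes["Q1"] == 200
        assert abs(sizes["Q2"] - 250) <= 1
        assert abs(sizes["Q3"] - 250) <= 1
        assert abs(sizes["Q4"] - 250) <= 1

    def test_degenerate_distribution_errors(self):
        vals = pd.Series(np.ones(200), index=[f"P{i}" for i in range(200)])
        with pytest.raises(ValueError, match="degenerate"):
            assign_strata(vals)

    def test_too_few_proteins_errors(self):
        vals = pd.Series(np.arange(50.0), index=[f"P{i}" for i in range(50)])
        with pytest.raises(ValueError, match="120"):
            assign_strata(vals)

    def test_membership_deterministic(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.lognormal(3, 1, 300), index=[f"P{i:04d}" for i in range(300)])
        assert assign_strata(vals).membership == assign_strata(vals).membership


class TestBootstrapReportable:
    def test_constant_cell(self):
        assert bootstrap_reportable(np.full(40, 3.6), n_boot=200, seed=0) == pytest.approx(3.6)

    def test_converges_to_cell_mean(self, rng):
        v = rng.lognormal(2, 0.5, 64)
        est = bootstrap_reportable(v, n_boot=4000, seed=1)
        assert abs(est - v.mean()) < 3 * v.std() / np.sqrt(v.size * 4000) * 10

    def test_small_cell_rejected(self):
        with pytest.raises(ValueError, match="cell_too_small"):
            bootstrap_reportable(np.ones(29), n_boot=100, seed=0)


class TestCellReportables:
    def test_exclusion_bookkeeping(self, design):
        t = SyntheticTruth(seed=2)
        ppm = gen_protein_ppm_table(t, n_proteins=150, design=design)
        anchor = ppm[ppm["level"] == "L4"].groupby("protein")["ppm"].mean()
        strat = assign_strata(anchor)
        cells, excluded = cell_reportables(ppm, strat, n_boot=100, seed=0)
        n_cells_seen = ppm.assign(stratum=ppm["protein"].map(strat.membership)).dropna(
            subset=["stratum"]
        ).groupby(["assay", "level", "block", "stratum"]).ngroups
        assert len(cells) + len(excluded) == n_cells_seen
        assert all(e["reason"] == "fewer_than_30_proteins" for e in excluded)
        # 150 proteins -> Q1 has ~30 members, Q2-Q4 always >= 30
        assert all(c.n_proteins >= 30 for c in cells)


def _cells_from_table(ppm):
    return [
        StratumCell(a, lv, int(blk), st, len(g), float(g["ppm"].mean()))
        for (a, lv, blk, st), g in ppm[ppm["stratum"] != ""].groupby(
            ["assay", "level", "block", "stratum"]
        )
    ]


class TestStratumRelativeErrors:
    def test_anchor_level_mean_re_is_zero(self, design):
        ppm = gen_protein_ppm_table(SyntheticTruth(seed=4), n_proteins=200, design=design)
        cells = stratum_relative_errors(_cells_from_table(ppm), SPIKE)
        for st in ("Q1", "Q2", "Q3", "Q4"):
            res = [c.relative_error for c in cells if c.stratum == st and c.level == "L4"]
            assert np.mean(res) == pytest.approx(0.0, abs=1e-9)

    def test_exact_ratio_values(self):
        cells = [
            StratumCell("A1", "L4", 1, "Q1", 40, 10.0),
            StratumCell("A1", "L7", 1, "Q1", 40, 17.6),
        ]
        out = stratum_relative_errors(cells, SPIKE)
        l7 = next(c for c in out if c.level == "L7")
        # R_obs = 1.76, R_theo = 1.6 -> RE = +10%
        assert l7.relative_error == pytest.approx(10.0)


class TestStratumProfile:
    def test_zero_noise_unit_slope_all_pass(self, design):
        t = SyntheticTruth(
            seed=0, sigma_w=0.0, sigma_b=0.0, protein_cv=0.0,
            stratum_params=((1.0, 0.0),) * 4,
        )
        ppm = gen_protein_ppm_table(t, n_proteins=200, design=design)
        # tiny jitter so the variance model has positive SDs
        rng = np.random.default_rng(0)
        ppm["ppm"] *= 1 + rng.normal(0, 1e-6, len(ppm))
        cells = stratum_relative_errors(_cells_from_table(ppm), SPIKE)
        prof = stratum_accuracy_profile(cells, SPIKE)
        assert prof["validated_levels"] == sorted(SPIKE, key=SPIKE.get)
        for ti in prof["tolerance_intervals"].values():
            assert abs(ti.center) < 1e-3

    def test_compressed_stratum_bias_transition(self, design):
        """A slope-0.8, positive-intercept stratum goes from positive bias at
        low spike ratios to negative at high ratios."""
        t = SyntheticTruth(seed=6, sigma_w=1.0, sigma_b=0.0, protein_cv=2.0)
        ppm = gen_protein_ppm_table(t, n_proteins=300, design=design)
        cells = stratum_relative_errors(_cells_from_table(ppm), SPIKE)
        q4 = {c.level: [] for c in cells if c.stratum == "Q4"}
        for c in cells:
            if c.stratum == "Q4":
                q4[c.level].append(c.relative_error)
        assert np.mean(q4["L1"]) > 0 > np.mean(q4["L7"])

    def test_failing_stratum_removes_level(self):
        rng = np.random.default_rng(1)
        cells = []
        for st, shift in (("Q1", 0.0), ("Q4", 0.0)):
            for lv in ("L1", "L4", "L7"):
                for a in ("A1", "A2", "A3", "A4"):
                    for blk in (1, 2, 3):
                        re = rng.normal(0, 1)
                        if st == "Q4" and lv == "L1":
                            re += 60.0  # far outside +/-35
                        r_theo = SPIKE[lv] / SPIKE["L4"]
                        c = StratumCell(a, lv, blk, st, 40, np.nan)
                        c.relative_error = re
                        c.r_theo = r_theo
                        cells.append(c)
        prof = stratum_accuracy_profile(cells, SPIKE)
        assert "L1" not in prof["validated_levels"]
        assert "L4" in prof["validated_levels"]


class TestAbundanceLimits:
    def _cells(self):
        rng = np.random.default_rng(2)
        cells = []
        for lv in ("L1", "L4", "L7"):
            for st, base in (("Q1", 3.6), ("Q4", 230.0)):
                for k in range(12):
                    cells.append(
                        StratumCell("A1", lv, k, st, 50, base * SPIKE[lv] / 50.0)
                    )
        return cells

    def test_constant_cells(self):
        out = abundance_lloq_uloq(self._cells(), ["L1", "L4", "L7"], SPIKE)
        assert out["lloq_mean_ppm"] == pytest.approx(3.6 * 0.4)
        assert out["lloq_p95_ppm"] == pytest.approx(out["lloq_mean_ppm"])
        assert out["uloq_level"] == "L7"

    def test_percentile_sides(self, rng):
        cells = self._cells()
        for c in cells:
            c.reportable_ppm *= rng.lognormal(0, 0.2)  # right-skew
        out = abundance_lloq_uloq(cells, ["L1", "L4", "L7"], SPIKE)
        assert out["lloq_p95_ppm"] >= out["lloq_mean_ppm"] * 0.99
        assert out["uloq_p05_ppm"] <= out["uloq_mean_ppm"]

    def test_empty_domain_errors(self):
        with pytest.raises(ValueError, match="empty"):
            abundance_lloq_uloq(self._cells(), [], SPIKE)
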