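"""Peptide filters, response factor, and Hi3 mass conversion."""

import numpy as np
import pytest

from hcpval.quant import (
    FilterConfig,
    apply_filter_chain,
    compute_mw,
    cv_filter,
    hi3_protein_mass,
    intensity_deviation_filter,
    modified_zscore_filter,
    response_factor,
    tic_normalize,
    to_ppm,
    total_hcp,
)
from hcpval.simulate import gen_peptide_table


class TestTicNormalize:
    def test_equal_totals_unchanged(self):
        out = tic_normalize({"r1": [10, 10], "r2": [5, 15]})
        assert np.allclose(out["r1"], [10, 10]) and np.allclose(out["r2"], [5, 15])

    def test_totals_scaled_to_median(self):
        out = tic_normalize({"a": [100.0], "b": [200.0], "c": [300.0]})
        assert all(np.isclose(sum(v), 200.0) for v in out.values())

    def test_within_run_ratios_preserved(self):
        out = tic_normalize({"a": [10.0, 30.0], "b": [5.0, 5.0]})
        assert out["a"][1] / out["a"][0] == pytest.approx(3.0)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            tic_normalize({"a": [0.0], "b": [1.0]})


class TestModifiedZscore:
    def test_hand_computed_outlier(self):
        # median 3, MAD 1 -> M(100) = 0.6745*97 = 65.4 > 3.5
        keep = modified_zscore_filter([1, 2, 3, 4, 100], cutoff=3.5)
        assert list(keep) == [True, True, True, True, False]

    def test_constant_series_unchanged(self):
        assert modified_zscore_filter([5, 5, 5, 5]).all()

    def test_three_points_all_kept(self):
        assert modified_zscore_filter([1, 2, 3]).all()

    def test_short_series_passes_through(self):
        assert modified_zscore_filter([1, 1000]).all()

    def test_mad_zero_falls_back_to_mean_ad(self):
        # {1,1,1,1,10}: median 1, MAD 0; meanAD = 1.8, M(10) = 9/(1.2533*1.8) = 3.99
        keep = modified_zscore_filter([1, 1, 1, 1, 10], cutoff=3.5)
        assert list(keep) == [True, True, True, True, False]


class TestCvFilter:
    @pytest.mark.parametrize(
        "values, kept",
        [((7, 7, 7), True), ((100, 200), False), ((100, 101, 99), True)],
    )
    def test_hand_computed(self, values, kept):
        assert cv_filter(values, 20.0) is kept

    def test_zero_mean_dropped(self):
        assert cv_filter([0.0, 0.0]) is False

    def test_single_value_errors(self):
        with pytest.raises(ValueError):
            cv_filter([1.0])


class TestResponseFactor:
    def test_median_of_ratios(self):
        rf = response_factor([(90, 1), (100, 1), (110, 1), (200, 1)])
        assert rf.rf == pytest.approx(105.0)

    def test_single_standard(self):
        assert response_factor([(500, 5)]).rf == pytest.approx(100.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            response_factor([])

    def test_zero_amount_errors(self):
        with pytest.raises(ValueError):
            response_factor([(100, 0)])


class TestHi3:
    def test_direct_arithmetic(self):
        mass, top3 = hi3_protein_mass({"a": 500, "b": 300, "c": 200, "d": 1}, rf=100, mw_da=50000)
        assert mass == pytest.approx(0.5)
        assert set(top3) == {"a", "b", "c"}

    def test_zero_intensity_zero_mass(self):
        mass, _ = hi3_protein_mass({"a": 0, "b": 0, "c": 0}, rf=100, mw_da=50000)
        assert mass == 0.0

    def test_homogeneity(self):
        m1, _ = hi3_protein_mass({"a": 5, "b": 3, "c": 2}, 10, 1000)
        m2, _ = hi3_protein_mass({"a": 10, "b": 6, "c": 4}, 10, 1000)
        assert m2 == pytest.approx(2 * m1)

    def test_too_few_peptides_excluded(self):
        with pytest.raises(ValueError, match="too_few_peptides"):
            hi3_protein_mass({"a": 5, "b": 3}, 10, 1000)


class TestTotals:
    def test_sum_and_ppm(self):
        assert total_hcp([0.5, 0.25]) == pytest.approx(0.75)
        assert to_ppm(50, 0.5) == pytest.approx(100.0)
        assert total_hcp([]) == 0.0

    def test_mass_additivity_over_partition(self, rng):
        masses = rng.uniform(0, 1, 20)
        assert total_hcp(masses[:7]) + total_hcp(masses[7:]) == pytest.approx(
            total_hcp(masses)
        )


class TestMolecularWeight:
    def test_glycine(self):
        assert compute_mw("G") == pytest.approx(75.07, abs=0.01)

    def test_diglycine_loses_one_water(self):
        assert compute_mw("GG") == pytest.approx(132.12, abs=0.01)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            compute_mw("")


class TestFilterChain:
    PEPS = {
        f"PR{i}": [f"{'ACDEFG'[i]}{'LMNQ'[j]}PEPTIDEK" for j in range(4)] for i in range(3)
    }
    FMOL = {"PR0": 10.0, "PR1": 2.5, "PR2": 7.0}
    RF = 120.0

    def test_noiseless_end_to_end_identity(self):
        """Zero noise, RF known: the Hi3 pipeline returns the true mass."""
        obs = gen_peptide_table(self.FMOL, self.PEPS, self.RF, seed=1)
        kept = apply_filter_chain(obs)
        for prot, fmol in self.FMOL.items():
            sub = kept[kept["sequence"].isin(self.PEPS[prot])]
            means = sub.groupby("sequence")["intensity"].mean().to_dict()
            mass, _ = hi3_protein_mass(means, self.RF, 50000.0)
            assert mass == pytest.approx(fmol * 50000.0 * 1e-6, rel=1e-9)

    def test_idempotence(self):
        from hcpval.core import PeptideObservation

        obs = gen_peptide_table(self.FMOL, self.PEPS, self.RF, noise_cv=8, seed=3)
        once = apply_filter_chain(obs)
        again = apply_filter_chain(
            [
                PeptideObservation(
                    sequence=r.sequence, accessions=("X",), run_id=r.run_id, intensity=r.intensity
                )
                for r in once.itertuples(index=False)
            ]
        )
        a = once.sort_values(["sequence", "run_id"])["intensity"].to_numpy()
        b = again.sort_values(["sequence", "run_id"])["intensity"].to_numpy()
        assert np.allclose(a, b)

    def test_injected_outliers_removed(self):
        """Modified Z-score stage removes >= 90% of 50x spikes over 50 seeds."""
        removed = tot = 0
        for seed in range(50):
            obs = gen_peptide_table(
                self.FMOL, self.PEPS, self.RF, noise_cv=5.0, outlier_rate=0.05, seed=seed
            )
            n_out = sum(
                1
                for o in obs
                if o.intensity
                > 20 * np.median([p.intensity for p in obs if p.sequence == o.sequence])
            )
            kept = apply_filter_chain(obs)
            surviving = int(
                (
                    kept["intensity"]
                    > 10 * kept.groupby("sequence")["intensity"].transform("median")
                ).sum()
            )
            removed += n_out - min(n_out, surviving)
            tot += n_out
        assert tot > 0 and removed / tot >= 0.9

    def test_single_hit_rule_drops_sparse_peptide(self):
        obs = gen_peptide_table(self.FMOL, self.PEPS, self.RF, seed=1)
        # keep one peptide in only 1 of 3 injections
        victim = self.PEPS["PR0"][0]
        obs = [o for o in obs if not (o.sequence == victim and o.injection > 1)]
        kept = apply_filter_chain(obs)
        assert victim not in set(kept["sequence"])

    def test_intensity_deviation_mask(self):
        keep = intensity_deviation_filter([1, 10, 100, 2000], cross_run_median=55, factor=10)
        assert list(keep) == [False, True, True, False]

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(cv_cutoff_percent=-1)
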