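"""Entrapment construction and FDP estimation."""

import numpy as np
import pandas as pd
import pytest

from hcpval.digest import DigestSpec
from hcpval.entrapment import (
    bootstrap_fdp_bands,
    build_shuffled_entrapment,
    collapse_to_peptides,
    fdp_curve,
    fdp_estimate,
    protein_level_fdp,
    trim_foreign_entrapment,
    wilson_interval,
)
from hcpval.simulate import gen_entrapment_scores

FASTA = {
    "P1": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEK",
    "P2": "MSERVQQHVLTALGPGGRLIEVQAPILSRVGDGTQDNLSGAEKAVQVK",
}
SPEC = DigestSpec(max_missed_cleavages=1, min_length=6, max_length=40)


class TestShuffledEntrapment:
    def test_composition_and_terminus_preserved(self):
        entrap, r = build_shuffled_entrapment(FASTA, SPEC, seed=3)
        from hcpval.digest import theoretical_digest

        target = set()
        for s in FASTA.values():
            target |= theoretical_digest(s, SPEC)
        assert entrap, "entrapment set should not be empty"
        assert not entrap & target
        # every entrapment peptide matches some target peptide's composition + C-term
        keyed = {}
        for p in target:
            keyed.setdefault(("".join(sorted(p)), p[-1]), set()).add(p)
        for e in entrap:
            assert ("".join(sorted(e)), e[-1]) in keyed

    def test_seed_determinism(self):
        a, ra = build_shuffled_entrapment(FASTA, SPEC, seed=5)
        b, rb = build_shuffled_entrapment(FASTA, SPEC, seed=5)
        assert a == b and ra == rb

    def test_unresolvable_peptide_dropped(self):
        # "AK" can only shuffle to itself -> dropped, r < 1
        fa = {"X": "AKAK"}
        spec = DigestSpec(max_missed_cleavages=0, min_length=2, max_length=5)
        entrap, r = build_shuffled_entrapment(fa, spec, seed=0)
        assert entrap == set() and r == 0.0


class TestTrimForeign:
    def test_disjoint_unchanged(self):
        assert trim_foreign_entrapment({"AAA", "BBB"}, {"CCC"}) == {"AAA", "BBB"}

    def test_subset_emptied(self):
        assert trim_foreign_entrapment({"AAA"}, {"AAA", "BBB"}) == set()

    def test_size_conservation(self):
        foreign = {"a", "b", "c", "d"}
        target = {"c", "d", "e"}
        out = trim_foreign_entrapment(foreign, target)
        assert len(out) == len(foreign) - len(foreign & target)


class TestCollapse:
    def test_min_q_per_sequence(self):
        rows = pd.DataFrame(
            {
                "sequence": ["AAK", "AAK", "CCK"],
                "q_value": [0.02, 0.005, 0.01],
                "label": ["target", "target", "entrapment"],
            }
        )
        out = collapse_to_peptides(rows)
        assert len(out) == 2
        assert out.set_index("sequence").loc["AAK", "q_value"] == 0.005

    def test_conflicting_labels_error(self):
        rows = pd.DataFrame(
            {
                "sequence": ["AAK", "AAK"],
                "q_value": [0.1, 0.2],
                "label": ["target", "entrapment"],
            }
        )
        with pytest.raises(ValueError, match="conflicting"):
            collapse_to_peptides(rows)


class TestFdpEstimate:
    def _table(self, n_e, n_t):
        return pd.DataFrame(
            {
                "sequence": [f"s{i}" for i in range(n_e + n_t)],
                "q_value": [0.005] * (n_e + n_t),
                "label": ["entrapment"] * n_e + ["target"] * n_t,
            }
        )

    def test_no_entrapments_zero(self):
        assert fdp_estimate(self._table(0, 100), 0.01, 1.0) == 0.0

    def test_r1_reduces_to_2ne_over_nd(self):
        assert fdp_estimate(self._table(5, 995), 0.01, 1.0) == pytest.approx(0.01)

    def test_general_r(self):
        assert fdp_estimate(self._table(5, 995), 0.01, 0.5) == pytest.approx(0.015)

    def test_counts_monotone_in_tau(self):
        scores = gen_entrapment_scores(n_target=2000, r=1.0, true_fdp=0.05, seed=0)
        tau = np.array([0.001, 0.005, 0.01, 0.05, 0.2, 1.0])
        curve = fdp_curve(scores, tau, 1.0)
        assert (np.diff(curve.n_entrapment) >= 0).all()
        assert (np.diff(curve.n_total) >= 0).all()
        assert (curve.n_entrapment <= curve.n_total).all()
        assert (curve.fdp >= 0).all()


class TestBootstrapBands:
    def test_zero_entrapments_zero_bands(self):
        scores = gen_entrapment_scores(n_target=500, r=1.0, true_fdp=0.0, seed=0)
        lo, hi = bootstrap_fdp_bands(scores, np.array([0.005, 0.01]), 1.0, n_boot=200, seed=0)
        assert np.all(lo == 0) and np.all(hi == 0)

    def test_seed_determinism(self):
        scores = gen_entrapment_scores(n_target=1000, r=1.0, true_fdp=0.02, seed=1)
        tau = np.array([0.01, 0.05])
        a = bootstrap_fdp_bands(scores, tau, 1.0, n_boot=200, seed=9)
        b = bootstrap_fdp_bands(scores, tau, 1.0, n_boot=200, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_bands_bracket_point_estimate(self):
        scores = gen_entrapment_scores(n_target=5000, r=1.0, true_fdp=0.02, seed=2)
        tau = np.array([0.01, 0.02, 0.05])
        curve = fdp_curve(scores, tau, 1.0)
        lo, hi = bootstrap_fdp_bands(scores, tau, 1.0, n_boot=400, seed=2)
        assert np.all(lo <= curve.fdp + 1e-12) and np.all(hi >= curve.fdp - 1e-12)


class TestWilson:
    def test_zero_successes_lower_zero(self):
        lo, hi = wilson_interval(0, 100)
        assert lo == 0.0 and hi > 0

    def test_textbook_values(self):
        lo, hi = wilson_interval(10, 100)
        assert lo == pytest.approx(0.0552, abs=5e-4)
        assert hi == pytest.approx(0.1744, abs=5e-4)

    def test_scale_factor(self):
        lo1, hi1 = wilson_interval(10, 100)
        lo2, hi2 = wilson_interval(10, 100, scale_factor=2.0)
        assert lo2 == pytest.approx(2 * lo1) and hi2 == pytest.approx(2 * hi1)

    def test_n_zero_errors(self):
        with pytest.raises(ValueError):
            wilson_interval(0, 0)


class TestProteinLevel:
    def test_three_peptide_attenuation(self):
        assert protein_level_fdp(0.009, 3) == pytest.approx(7.29e-7)

    def test_identity_at_k1(self):
        assert protein_level_fdp(0.42, 1) == 0.42

    def test_zero_fdp(self):
        assert protein_level_fdp(0.0, 5) == 0.0
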