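import numpy as np
import pandas as pd
import pytest

from coevkit.conservation import ConservationParams, conservation_profile
from coevkit.coevolution import (
    REGION_PRESETS,
    compare_regions,
    delta_statistic,
    permutation_test,
    region_scores,
    signed_rank_test,
)
from coevkit.io import alignment_from_records
from coevkit.simulate import MsaSimConfig, simulate_ortholog_families


def _family(seed=1, **overrides):
    cfg = MsaSimConfig(seed=seed, **overrides)
    sim = simulate_ortholog_families(cfg)
    aln_pos = alignment_from_records([sim.reference] + sim.partner_positive)
    aln_neg = alignment_from_records([sim.reference] + sim.partner_negative)
    return sim, aln_pos, aln_neg


SMALL = dict(reference_length=80, n_partner_pos=8, n_partner_neg=8,
             region=(21, 40), n_strain_duplicates=0)


class TestRegionScores:
    def test_row_per_mapped_residue(self):
        sim, aln_pos, aln_neg = _family(**SMALL)
        p1 = conservation_profile(aln_pos, sim.reference.id)
        p2 = conservation_profile(aln_neg, sim.reference.id)
        paired = region_scores(p1, p2, (21, 40))
        assert len(paired) == 20
        assert list(paired["residue"]) == list(range(21, 41))

    def test_identical_profiles_zero_delta(self):
        sim, aln_pos, _ = _family(**SMALL)
        prof = conservation_profile(aln_pos, sim.reference.id)
        paired = region_scores(prof, prof, (21, 40))
        assert np.allclose(paired["delta"], 0.0)

    def test_region_beyond_reference_excluded_and_counted(self):
        sim, aln_pos, aln_neg = _family(**SMALL)
        p1 = conservation_profile(aln_pos, sim.reference.id)
        p2 = conservation_profile(aln_neg, sim.reference.id)
        paired = region_scores(p1, p2, (75, 90))
        assert list(paired["residue"]) == list(range(75, 81))
        assert paired.attrs["n_excluded"] == 10
        with pytest.raises(ValueError, match="no comparable residues"):
            region_scores(p1, p2, (81, 90))

    def test_preset_regions(self):
        assert REGION_PRESETS["al_ctr"] == (336, 501)
        assert REGION_PRESETS["y2h_clone"] == (371, 501)


class TestDeltaStatistic:
    def test_mean_and_antisymmetry(self):
        paired = pd.DataFrame({"delta": [0.1, 0.3]})
        assert delta_statistic(paired) == pytest.approx(0.2)
        sim, aln_pos, aln_neg = _family(**SMALL)
        p1 = conservation_profile(aln_pos, sim.reference.id)
        p2 = conservation_profile(aln_neg, sim.reference.id)
        fwd = delta_statistic(region_scores(p1, p2, (21, 40)))
        rev = delta_statistic(region_scores(p2, p1, (21, 40)))
        assert fwd == pytest.approx(-rev, abs=1e-15)

    def test_planted_signal_positive_every_seed(self):
        for seed in range(20):
            sim, aln_pos, aln_neg = _family(seed=seed, reference_length=120,
                                            n_partner_pos=15, n_partner_neg=15,
                                            region=(41, 70), n_strain_duplicates=0)
            p1 = conservation_profile(aln_pos, sim.reference.id)
            p2 = conservation_profile(aln_neg, sim.reference.id)
            assert delta_statistic(region_scores(p1, p2, sim.config.region)) > 0


class TestPermutationTest:
    def test_identical_sets_p_near_one(self):
        sim, aln_pos, _ = _family(**SMALL)
        p, obs, _ = permutation_test(aln_pos, aln_pos, sim.reference.id, (21, 40),
                                     n_permutations=999, seed=3)
        assert obs == pytest.approx(0.0, abs=1e-12)
        assert p > 0.9

    def test_planted_signal_small_p(self):
        sim, aln_pos, aln_neg = _family(seed=4)
        p, obs, _ = permutation_test(aln_pos, aln_neg, sim.reference.id,
                                     sim.config.region, n_permutations=999, seed=5)
        assert obs > 0
        assert p <= 0.01

    def test_p_floor_and_min_permutations(self):
        sim, aln_pos, aln_neg = _family(**SMALL)
        p, _, deltas = permutation_test(aln_pos, aln_neg, sim.reference.id, (21, 40),
                                        n_permutations=99, seed=1)
        assert p >= 1 / 100
        assert deltas.size == 99
        with pytest.raises(ValueError, match="19"):
            permutation_test(aln_pos, aln_neg, sim.reference.id, (21, 40),
                             n_permutations=5, seed=1)

    def test_deterministic_given_seed(self):
        sim, aln_pos, aln_neg = _family(**SMALL)
        r1 = permutation_test(aln_pos, aln_neg, sim.reference.id, (21, 40),
                              n_permutations=99, seed=11)
        r2 = permutation_test(aln_pos, aln_neg, sim.reference.id, (21, 40),
                              n_permutations=99, seed=11)
        assert r1[0] == r2[0]
        np.testing.assert_array_equal(r1[2], r2[2])

    def test_fast_path_matches_full_profile_route(self):
        # the span-restricted permutation scorer must reproduce the
        # full-profile delta exactly when fed the observed labeling
        from coevkit.coevolution import _region_delta
        from coevkit.conservation import encode_alignment

        sim, aln_pos, aln_neg = _family(**SMALL)
        params = ConservationParams()
        p1 = conservation_profile(aln_pos, sim.reference.id, params)
        p2 = conservation_profile(aln_neg, sim.reference.id, params)
        paired = region_scores(p1, p2, (21, 40))
        full = delta_statistic(paired)
        cols = p1.reference_map[paired["residue"].to_numpy() - 1]
        fast = _region_delta(encode_alignment(aln_pos), encode_alignment(aln_neg),
                             cols, params, __import__("coevkit.conservation", fromlist=["blosum62_background"]).blosum62_background())
        assert fast == pytest.approx(full, abs=1e-12)

    def test_label_swap_leaves_p_unchanged(self):
        sim, aln_pos, aln_neg = _family(**SMALL)
        p_fwd, obs_fwd, _ = permutation_test(aln_pos, aln_neg, sim.reference.id, (21, 40),
                                             n_permutations=199, seed=13)
        p_rev, obs_rev, _ = permutation_test(aln_neg, aln_pos, sim.reference.id, (21, 40),
                                             n_permutations=199, seed=13)
        assert obs_fwd == pytest.approx(-obs_rev, abs=1e-12)
        # two-sided |delta| null with equal set sizes: same p up to resampling
        assert abs(p_fwd - p_rev) < 0.1

    def test_mismatched_columns_rejected(self):
        sim, aln_pos, _ = _family(**SMALL)
        sim2, aln2, _ = _family(reference_length=60, n_partner_pos=8,
                                n_partner_neg=8, region=(11, 30), n_strain_duplicates=0)
        with pytest.raises(ValueError, match="column space"):
            permutation_test(aln_pos, aln2, sim.reference.id, (21, 40))


class TestSignedRank:
    def test_all_zero_deltas_degenerate(self):
        paired = pd.DataFrame({"delta": np.zeros(10)})
        assert signed_rank_test(paired).p_value == 1.0

    def test_trio_exact(self):
        paired = pd.DataFrame({"delta": [1.0, 2.0, 3.0]})
        assert signed_rank_test(paired).p_value == pytest.approx(0.25)


class TestCompareRegions:
    def test_end_to_end_report_consistency(self):
        sim, aln_pos, aln_neg = _family(seed=9)
        cmp = compare_regions(aln_pos, aln_neg, sim.reference.id,
                              region=sim.config.region, n_permutations=199, seed=2)
        assert cmp.delta_mean == pytest.approx(cmp.paired["delta"].mean(), abs=1e-12)
        assert 1 / 200 <= cmp.permutation_p <= 1.0
        assert cmp.n_permutations == 199
        assert cmp.permutation_p <= 0.05 and cmp.signed_rank_p < 0.05
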