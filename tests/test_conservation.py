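import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coevkit.conservation import (
    ConservationParams,
    blosum62_background,
    column_distribution,
    column_score,
    conservation_profile,
    jsd,
    sequence_weights,
)
from coevkit.io import AA_ALPHABET, MultipleAlignment
from coevkit.simulate import MsaSimConfig, simulate_ortholog_families
from coevkit.io import alignment_from_records
from oracles import naive_profile

BG = blosum62_background()
BG_DICT = dict(zip(AA_ALPHABET, BG))


class TestBackground:
    def test_normalised_strictly_positive(self):
        assert BG.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(BG > 0) and np.all(BG < 0.12)

    def test_leucine_most_frequent(self):
        assert AA_ALPHABET[int(np.argmax(BG))] == "L"


class TestSequenceWeights:
    def test_identical_sequences_equal_weights(self):
        aln = MultipleAlignment(ids=list("abcd"), sequences=["ACDE"] * 4)
        np.testing.assert_allclose(sequence_weights(aln), [0.25] * 4)

    def test_single_column_hand_computation(self):
        aln = MultipleAlignment(ids=list("abc"), sequences=["A", "A", "C"])
        np.testing.assert_allclose(sequence_weights(aln), [0.25, 0.25, 0.5])

    @given(st.integers(2, 6), st.integers(1, 8), st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_weights_sum_to_one(self, n, ncol, seed):
        rng = np.random.default_rng(seed)
        seqs = ["".join(rng.choice(list(AA_ALPHABET + "-"), ncol)) for _ in range(n)]
        aln = MultipleAlignment(ids=[f"s{i}" for i in range(n)], sequences=seqs)
        assert sequence_weights(aln).sum() == pytest.approx(1.0)


class TestColumnDistribution:
    def test_conserved_column(self):
        aln = MultipleAlignment(ids=list("ab"), sequences=["A", "A"])
        p, gap = column_distribution(aln, 0)
        assert gap == 0.0
        assert p[0] == pytest.approx(1.0, abs=1e-5)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_half_gap_column(self):
        aln = MultipleAlignment(ids=list("ab"), sequences=["A", "-"])
        p, gap = column_distribution(aln, 0)
        assert gap == pytest.approx(0.5)
        assert p[0] == pytest.approx(1.0, abs=1e-5)

    def test_matches_direct_recomputation_fuzz(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 8))
            col = rng.choice(list(AA_ALPHABET + "--"), n)
            aln = MultipleAlignment(ids=[f"s{i}" for i in range(n)], sequences=list(col))
            w = rng.dirichlet(np.ones(n))
            eps = 1e-7
            p, gap = column_distribution(aln, 0, weights=w, pseudocount=eps)
            mass = np.zeros(20)
            gap_w = 0.0
            for i, ch in enumerate(col):
                if ch == "-":
                    gap_w += w[i]
                else:
                    mass[AA_ALPHABET.index(ch)] += w[i]
            if mass.sum() > 0:
                expect = (mass + eps) / (mass.sum() + 20 * eps)
                np.testing.assert_allclose(p, expect, atol=1e-12)
            assert gap == pytest.approx(gap_w, abs=1e-12)


class TestJsd:
    def test_identical_zero(self):
        assert jsd(BG, BG) == 0.0

    def test_disjoint_one_hots_maximal(self):
        p = np.zeros(20); p[0] = 1
        q = np.zeros(20); q[2] = 1
        assert jsd(p, q) == pytest.approx(1.0, abs=1e-12)

    def test_one_hot_vs_uniform_closed_form(self):
        p = np.zeros(20); p[0] = 1
        u = np.full(20, 0.05)
        # 0.5*(log2(1/0.525) + 0.05*log2(0.05/0.525) + 0.95), evaluated directly
        expected = 0.5 * (np.log2(1 / 0.525) + 0.05 * np.log2(0.05 / 0.525) + 0.95)
        assert jsd(p, u) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.855, abs=6e-4)

    def test_non_normalised_rejected(self):
        with pytest.raises(ValueError):
            jsd(np.full(20, 0.06), BG)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_bounded_matches_scipy(self, seed):
        from scipy.spatial.distance import jensenshannon

        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(20))
        q = rng.dirichlet(np.ones(20))
        v = jsd(p, q)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(jsd(q, p), abs=1e-12)
        assert v == pytest.approx(jensenshannon(p, q, base=2) ** 2, abs=1e-12)


class TestColumnScore:
    def test_all_gap_scores_zero(self):
        aln = MultipleAlignment(ids=list("ab"), sequences=["-", "-"])
        assert column_score(aln, 0) == 0.0

    def test_conserved_column_matches_closed_form(self):
        # a fully conserved gap-free column scores the JSD of a (pseudocounted)
        # one-hot against the background: high for every residue, highest for
        # rare residues (Trp), lowest for abundant ones (Leu, still > 0.75)
        from scipy.spatial.distance import jensenshannon

        scores = {}
        for k, aa in enumerate(AA_ALPHABET):
            aln = MultipleAlignment(ids=list("abcd"), sequences=[aa] * 4)
            s = column_score(aln, 0)
            eps = 1e-7
            p = np.full(20, eps / (1 + 20 * eps))
            p[k] = (1 + eps) / (1 + 20 * eps)
            assert s == pytest.approx(jensenshannon(p, BG, base=2) ** 2, abs=1e-12)
            scores[aa] = s
        assert min(scores.values()) == scores["L"] > 0.75
        assert max(scores.values()) == scores["W"] > 0.9

    def test_background_column_low(self):
        # large column drawn i.i.d. from the background distribution
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            col = rng.choice(list(AA_ALPHABET), size=200, p=BG)
            aln = MultipleAlignment(ids=[f"s{i}" for i in range(200)], sequences=list(col))
            if column_score(aln, 0) >= 0.05:
                rejections += 1
        assert rejections == 0


class TestProfile:
    def test_single_column_window_is_identity(self):
        aln = MultipleAlignment(ids=list("ab"), sequences=["A", "A"])
        prof = conservation_profile(aln, "a")
        assert prof.windowed[0] == prof.raw[0]

    def test_constant_raw_scores_unchanged_by_window(self):
        aln = MultipleAlignment(ids=list("ab"), sequences=["AAAA", "AAAA"])
        prof = conservation_profile(aln, "a")
        np.testing.assert_allclose(prof.windowed, prof.raw, atol=1e-12)

    def test_unknown_reference_rejected(self, small_alignment):
        with pytest.raises(KeyError):
            conservation_profile(small_alignment, "nope")

    def test_reference_map_skips_gaps(self):
        aln = MultipleAlignment(ids=["r", "s"], sequences=["A-CD", "AWCD"])
        prof = conservation_profile(aln, "r")
        np.testing.assert_array_equal(prof.reference_map, [0, 2, 3])
        assert prof.reference_length == 3

    def test_matches_naive_reimplementation(self, rng):
        # vectorised pipeline vs plain-loop oracle on random gapped alignments
        for _ in range(5):
            n = int(rng.integers(3, 9))
            ncol = int(rng.integers(2, 15))
            seqs = ["".join(rng.choice(list(AA_ALPHABET + "-"), ncol)) for _ in range(n)]
            # ensure the reference row has at least one residue
            seqs[0] = "".join(rng.choice(list(AA_ALPHABET), ncol))
            aln = MultipleAlignment(ids=[f"s{i}" for i in range(n)], sequences=seqs)
            for weighting in (True, False):
                params = ConservationParams(use_sequence_weighting=weighting)
                prof = conservation_profile(aln, "s0", params)
                oracle = naive_profile(seqs, 3, 0.5, 1e-7, weighting, BG_DICT)
                np.testing.assert_allclose(prof.windowed, oracle, atol=1e-12)

    def test_invariant_to_sequence_order(self, rng):
        cfg = MsaSimConfig(reference_length=60, n_partner_pos=12, n_partner_neg=0,
                           region=(11, 30), seed=5)
        sim = simulate_ortholog_families(cfg)
        recs = [sim.reference] + sim.partner_positive
        prof1 = conservation_profile(alignment_from_records(recs), sim.reference.id)
        shuffled = [recs[0]] + [recs[i] for i in rng.permutation(np.arange(1, len(recs)))]
        prof2 = conservation_profile(alignment_from_records(shuffled), sim.reference.id)
        np.testing.assert_allclose(prof1.windowed, prof2.windowed, atol=1e-12)

    def test_monotone_response_to_substitution_pressure(self):
        # conserved sites (p_sub 0.02) outscore background sites (0.3), every seed
        for seed in range(20):
            cfg = MsaSimConfig(seed=seed)
            sim = simulate_ortholog_families(cfg)
            aln = alignment_from_records([sim.reference] + sim.partner_positive)
            prof = conservation_profile(aln, sim.reference.id)
            lo, hi = cfg.region
            region_cols = np.arange(lo - 1, hi)
            mask = np.zeros(prof.n_columns, dtype=bool)
            mask[region_cols] = True
            assert prof.windowed[mask].mean() > prof.windowed[~mask].mean()

    def test_weighting_robust_to_duplicated_sequences(self):
        cfg = MsaSimConfig(reference_length=120, n_partner_pos=20, n_partner_neg=0,
                           region=(31, 60), n_strain_duplicates=0, seed=11)
        sim = simulate_ortholog_families(cfg)
        recs = [sim.reference] + sim.partner_positive
        aln = alignment_from_records(recs)
        dup_recs = recs + [
            type(recs[1])(id=f"dup{i}", organism=f"Dup organism{i}", sequence=recs[1].sequence)
            for i in range(10)
        ]
        dup_aln = alignment_from_records(dup_recs)
        lo, hi = cfg.region
        sl = slice(lo - 1, hi)

        weighted = ConservationParams(use_sequence_weighting=True)
        unweighted = ConservationParams(use_sequence_weighting=False)
        base_w = conservation_profile(aln, sim.reference.id, weighted).windowed[sl].mean()
        base_u = conservation_profile(aln, sim.reference.id, unweighted).windowed[sl].mean()
        dup_w = conservation_profile(dup_aln, sim.reference.id, weighted).windowed[sl].mean()
        dup_u = conservation_profile(dup_aln, sim.reference.id, unweighted).windowed[sl].mean()

        # distinct species: weighting barely matters
        assert abs(base_w - base_u) < 0.05
        # 10 extra copies of one sequence: unweighted shifts, weighted holds
        assert abs(dup_w - base_w) < 0.02
        assert abs(dup_u - base_u) > abs(dup_w - base_w)
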