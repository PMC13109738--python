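import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietniche import (
    NicheProfile,
    diversity,
    evenness,
    levins,
    overlap_matrix,
    pianka,
    shannon,
    simpson,
)
from dietniche import study
from dietniche.ingest import TaxonRank


def study_profile(species):
    """Profile from the study's printed numeric proportions (%N)."""
    pct = study.category_pct_n(species)
    return NicheProfile.from_percentages(species, list(pct), list(pct.values()))


def reconstructed_counts(species):
    """Integer category counts reconstructed as round(%N x total items)."""
    total = study.N_ITEMS[species]
    return [round(p * total / 100.0) for p in study.category_pct_n(species).values()]


proportion_vectors = st.lists(st.floats(0.01, 1.0), min_size=2, max_size=12).map(
    lambda v: np.array(v) / np.sum(v))


class TestSimpson:
    def test_hand_enumerated_pairs(self):
        # counts [2, 2]: 2 same-category pairs of 6 total -> D = 1/3
        D, one_minus = simpson([2, 2])
        assert math.isclose(D, 1.0 / 3.0)
        assert math.isclose(one_minus, 2.0 / 3.0)

    @pytest.mark.parametrize("n", [2, 10, 1000])
    def test_single_category_is_pure(self, n):
        D, one_minus = simpson([n])
        assert D == 1.0 and one_minus == 0.0

    def test_study_counts_match_printed_heterogeneity(self):
        # reconstruction from the printed composition reproduces the study's
        # diversity table (the running-text sentence swaps the two Microhyla)
        for species, expected in [("Occidozyga lingnanica", 0.91),
                                  ("Microhyla mukhlesuri", 0.39),
                                  ("Microhyla heymonsi", 0.15)]:
            _, one_minus = simpson(reconstructed_counts(species))
            assert round(one_minus, 2) == expected, species

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            simpson([1])


class TestShannonEvenness:
    def test_uniform_is_log_n(self):
        assert math.isclose(shannon([0.25] * 4), math.log(4))

    def test_single_category_is_zero(self):
        assert shannon([1.0]) == 0.0

    def test_study_counts_frozen_value(self):
        # independent high-precision summation oracle over the reconstructed
        # M. mukhlesuri counts (666, 174, 13, 12, 7, and six singletons)
        counts = reconstructed_counts("Microhyla mukhlesuri")
        assert sorted(counts, reverse=True)[:5] == [666, 174, 13, 12, 7]
        N = sum(counts)
        oracle = -math.fsum(c / N * math.log(c / N) for c in counts)
        H = shannon(np.array(counts) / N)
        assert math.isclose(H, oracle, abs_tol=1e-12)
        assert round(H, 3) == 0.736
        # with S = 11 registered categories the evenness is ~0.31, not the
        # study's printed 0.27 (the S the authors used is unstated)
        assert round(evenness(H, len(counts)), 2) == 0.31

    def test_evenness_limits(self):
        assert math.isclose(evenness(math.log(7), 7), 1.0)
        assert evenness(0.0, 5) == 0.0
        with pytest.raises(ValueError):
            evenness(0.5, 1)

    @settings(max_examples=100, derandomize=True)
    @given(proportion_vectors)
    def test_matches_summation_oracle(self, p):
        oracle = -math.fsum(x * math.log(x) for x in p if x > 0)
        assert math.isclose(shannon(p), oracle, abs_tol=1e-12)


class TestLevins:
    @pytest.mark.parametrize("species,expected", [
        ("Microhyla heymonsi", 0.02),
        ("Microhyla mukhlesuri", 0.06),
    ])
    def test_study_profiles_match_printed_breadth(self, species, expected):
        res = levins(study_profile(species))
        assert round(res.B_sta, 2) == expected

    def test_lingnanica_close_to_printed(self):
        # printed 0.33; recomputation from rounded proportions gives ~0.34
        res = levins(study_profile("Occidozyga lingnanica"))
        assert res.n == 28
        assert abs(res.B_sta - 0.33) <= 0.02

    @pytest.mark.parametrize("n", [2, 5, 30])
    def test_uniform_is_generalist_limit(self, n):
        res = levins(np.full(n, 1.0 / n))
        assert math.isclose(res.B, n)
        assert math.isclose(res.B_sta, 1.0)

    def test_relabeling_invariance(self, rng):
        p = rng.dirichlet(np.ones(9))
        res = levins(p)
        shuffled = levins(rng.permutation(p))
        assert math.isclose(res.B_sta, shuffled.B_sta)

    @settings(max_examples=100, derandomize=True)
    @given(proportion_vectors, st.floats(0.05, 0.95))
    def test_mass_equalizing_transfer_increases_breadth(self, p, frac):
        # Pigou-Dalton: moving mass from the largest to the smallest
        # proportion (without overshooting) widens the niche
        i, j = int(np.argmax(p)), int(np.argmin(p))
        if math.isclose(p[i], p[j]):
            return
        q = p.copy()
        transfer = frac * (p[i] - p[j]) / 2.0
        q[i] -= transfer
        q[j] += transfer
        assert levins(q).B_sta > levins(p).B_sta

    @settings(max_examples=100, derandomize=True)
    @given(proportion_vectors)
    def test_matches_summation_oracle(self, p):
        B = 1.0 / math.fsum(x * x for x in p)
        n = len(p)
        assert math.isclose(levins(p).B_sta, (B - 1) / (n - 1), abs_tol=1e-12)


class TestPianka:
    def test_identical_profiles_overlap_fully(self):
        prof = study_profile("Microhyla heymonsi")
        assert math.isclose(pianka(prof, prof), 1.0)

    def test_disjoint_profiles_do_not_overlap(self):
        a = NicheProfile("a", TaxonRank.CATEGORY, ["x", "y"], [0.5, 0.5])
        b = NicheProfile("b", TaxonRank.CATEGORY, ["u", "v"], [0.3, 0.7])
        assert pianka(a, b) == 0.0

    def test_study_pair_matches_printed_overlap(self):
        # brute-force dot product over the union of categories
        o = pianka(study_profile("Microhyla heymonsi"),
                   study_profile("Occidozyga lingnanica"))
        assert round(o, 2) == 0.49

    def test_brute_force_oracle(self):
        pj = study_profile("Microhyla heymonsi")
        pk = study_profile("Occidozyga lingnanica")
        union = sorted(set(pj.labels) | set(pk.labels))
        a = {lab: v for lab, v in zip(pj.labels, pj.proportions)}
        b = {lab: v for lab, v in zip(pk.labels, pk.proportions)}
        num = math.fsum(a.get(l, 0) * b.get(l, 0) for l in union)
        den = math.sqrt(math.fsum(v * v for v in a.values())
                        * math.fsum(v * v for v in b.values()))
        assert math.isclose(pianka(pj, pk), num / den, abs_tol=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(proportion_vectors, proportion_vectors)
    def test_bounded_and_symmetric(self, p, q):
        labels_p = [f"t{i}" for i in range(len(p))]
        labels_q = [f"t{i}" for i in range(0, 2 * len(q), 2)]  # partial overlap
        a = NicheProfile("a", TaxonRank.CATEGORY, labels_p, p)
        b = NicheProfile("b", TaxonRank.CATEGORY, labels_q, q)
        o = pianka(a, b)
        assert 0.0 <= o <= 1.0 + 1e-12
        assert math.isclose(o, pianka(b, a))

    def test_moving_mass_off_shared_categories_decreases_overlap(self):
        a = NicheProfile("a", TaxonRank.CATEGORY, ["x", "y"], [0.5, 0.5])
        prev = None
        for off in [0.0, 0.2, 0.4, 0.6]:
            b = NicheProfile("b", TaxonRank.CATEGORY, ["x", "y", "z"],
                             [(1 - off) / 2, (1 - off) / 2, off])
            o = pianka(a, b)
            if prev is not None:
                assert o < prev
            prev = o


class TestOverlapMatrix:
    def test_identical_profiles(self):
        prof = study_profile("Microhyla heymonsi")
        m = overlap_matrix([prof, prof])
        assert np.allclose(m.O, 1.0)

    def test_mutually_disjoint_is_identity(self):
        profs = [NicheProfile(s, TaxonRank.CATEGORY, [f"{s}{i}" for i in range(3)],
                              [0.2, 0.3, 0.5]) for s in "abc"]
        assert np.allclose(overlap_matrix(profs).O, np.eye(3))

    def test_study_species_offdiagonals(self):
        m = overlap_matrix([study_profile(s) for s in study.SPECIES])
        assert np.allclose(np.diag(m.O), 1.0)
        assert np.allclose(m.O, m.O.T)
        assert round(m.pair("Microhyla heymonsi", "Microhyla mukhlesuri"), 2) == 0.98
        assert round(m.pair("Microhyla heymonsi", "Occidozyga lingnanica"), 2) == 0.49
        assert round(m.pair("Microhyla mukhlesuri", "Occidozyga lingnanica"), 2) == 0.52


class TestDiversitySummary:
    def test_from_counts_profile(self):
        prof = NicheProfile.from_counts("sp", ["a", "b", "c"], [5, 3, 2])
        res = diversity(prof)
        assert res.S == 3
        assert math.isclose(res.one_minus_D, 1.0 - res.D)
        assert math.isclose(res.J, res.H / math.log(3))
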