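import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parvapop.diversity import (
    bootstrap_standardized_H,
    expected_standardized_H,
    group_compare,
    haplotype_diversity,
    k2p_distance,
    k2p_from_proportions,
    nucleotide_diversity,
    pairwise_matrices,
    theta_and_ne,
    harmonic_number,
)
from parvapop.errors import ParameterError, SaturationError, UndefinedStatisticError
from parvapop.popio import table_from_records


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([15], 0.0),
            ([1, 1], 1.0),
            ([13, 2], 0.2476),  # 15/14 * (1 - (13/15)^2 - (2/15)^2)
        ],
    )
    def test_known_values(self, counts, expected):
        assert haplotype_diversity(counts) == pytest.approx(expected, abs=1e-4)

    def test_single_individual_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            haplotype_diversity([1])

    @given(st.lists(st.integers(1, 20), min_size=2, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_relabeling(self, counts):
        shuffled = list(reversed(counts))
        assert haplotype_diversity(counts) == pytest.approx(haplotype_diversity(shuffled))


class TestStandardizedH:
    def test_monomorphic_population_stays_zero(self):
        mean, _, closed = bootstrap_standardized_H([15], k=6, B=100, seed=1)
        assert mean == 0.0 and closed == 0.0

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ParameterError):
            bootstrap_standardized_H([3, 2], k=6)

    def test_simulation_matches_closed_form_within_3se(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            nh = int(rng.integers(2, 8))
            counts = rng.integers(1, 12, size=nh)
            if counts.sum() < 6:
                counts[0] += 6
            mean, se, closed = bootstrap_standardized_H(
                counts, k=6, B=100_000, seed=int(rng.integers(2**31))
            )
            assert abs(mean - closed) <= 3 * se + 1e-12

    def test_closed_form_expectation_formula(self):
        # E = (1 - 1/k) * H * (n-1)/n
        assert expected_standardized_H(0.6, 15, 6) == pytest.approx((5 / 6) * 0.6 * (14 / 15))


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        assert nucleotide_diversity(["ACGT"] * 4) == 0.0

    def test_single_pair_one_difference(self):
        a = "A" * 100
        b = "G" + "A" * 99
        assert nucleotide_diversity([a, b]) == pytest.approx(0.01)

    def test_matches_brute_force_enumeration(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(4)]
        brute = sum(
            sum(c1 != c2 for c1, c2 in zip(seqs[i], seqs[j]))
            for i in range(4)
            for j in range(i + 1, 4)
        ) / (6 * 10)
        assert nucleotide_diversity(seqs) == pytest.approx(brute)


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p_distance("ACGT" * 5, "ACGT" * 5) == 0.0

    @pytest.mark.parametrize(
        "P,Q,expected",
        [
            (0.1, 0.05, 0.17018),
            # -1/2 ln(0.95) - 1/4 ln(0.9)
            (0.0, 0.05, 0.05199),
        ],
    )
    def test_closed_form_values(self, P, Q, expected):
        assert k2p_from_proportions(P, Q) == pytest.approx(expected, abs=1e-5)

    def test_sequence_path_agrees_with_proportions(self):
        # 2 transitions + 1 transversion over 20 sites
        a = "A" * 20
        b = "G" + "G" + "C" + "A" * 17
        assert k2p_distance(a, b) == pytest.approx(k2p_from_proportions(0.1, 0.05))

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_from_proportions(0.5, 0.0)

    def test_ambiguous_sites_excluded(self):
        a = "ANGT" + "A" * 6
        b = "ACGT" + "A" * 4 + "G" * 2
        # N column dropped: 9 comparable sites, 2 transitions
        assert k2p_distance(a, b) == pytest.approx(k2p_from_proportions(2 / 9, 0))


class TestPairwiseMatrices:
    def test_fixed_for_different_haplotypes_gives_fst_one(self):
        seqs = ["AAAA"] * 3 + ["GAAA"] * 3
        t = table_from_records([f"s{i}" for i in range(6)], seqs, ["A"] * 3 + ["B"] * 3)
        m = pairwise_matrices(t)
        assert m.fst.loc["A", "B"] == pytest.approx(1.0)

    def test_identical_frequencies_give_fst_zero(self):
        seqs = ["AAAA", "GAAA"] * 2
        t = table_from_records([f"s{i}" for i in range(4)], seqs, ["A", "A", "B", "B"])
        m = pairwise_matrices(t)
        assert m.fst.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_enumerated_hudson_example(self, two_pop_table):
        # A = {h1 x3, h2 x1}, B = {h1 x1, h2 x3}: Hw = 0.5 d, Hb = 0.625 d
        m = pairwise_matrices(two_pop_table)
        d = k2p_from_proportions(0.1, 0.0)
        assert m.dxy.loc["A", "B"] == pytest.approx(0.625 * d)
        assert m.fst.loc["A", "B"] == pytest.approx(0.2)

    def test_symmetry_and_zero_diagonal(self, long_distance_hap):
        m = pairwise_matrices(long_distance_hap)
        f = m.fst.to_numpy()
        assert np.allclose(f, f.T)
        assert np.allclose(np.diag(f), 0)
        assert np.nanmin(f) >= 0 and np.nanmax(f) <= 1

    def test_group_medians_keys(self, long_distance_hap, long_distance_dataset):
        med = pairwise_matrices(long_distance_hap).group_medians(long_distance_dataset.popmap)
        assert set(med) == {"native-native", "invasive-invasive", "native-invasive"}


class TestTheta:
    def test_no_segregating_sites(self):
        est = theta_and_ne(["ACGT" * 25] * 5, mu=1e-8)
        assert est.theta_w == 0.0 and est.ne_w == 0.0

    def test_two_sequences_three_differences(self):
        a = "A" * 100
        b = "G" * 3 + "A" * 97
        est = theta_and_ne([a, b], mu=1e-8)
        assert est.theta_w == pytest.approx(0.03)

    def test_watterson_harmonic_denominator(self):
        # n = 10, L = 700, S = 14
        seqs = ["A" * 700 for _ in range(10)]
        seqs[0] = "G" * 14 + "A" * 686
        est = theta_and_ne(seqs, mu=5e-9, c=2.0)
        assert est.theta_w == pytest.approx(14 / (harmonic_number(9) * 700))
        assert est.ne_w == pytest.approx(est.theta_w / 1e-8)

    def test_negative_mu_rejected(self):
        with pytest.raises(ParameterError):
            theta_and_ne(["AA", "AG"], mu=0.0)


class TestGroupCompare:
    def test_identical_groups_p_near_one(self):
        _, p = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_all_tied_values(self):
        U, p = group_compare([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_exact_small_sample_enumeration(self):
        U, p = group_compare([1, 2], [3, 4], alternative="less")
        assert U == 0.0
        assert p == pytest.approx(1 / 6)
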