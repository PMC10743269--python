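import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crckit import (
    AlphabetError,
    DegenerateDataError,
    JointProbDist,
    OutOfRangeError,
    PairingError,
    ProbDist,
    cross_entropy,
    entropy,
    hist_prob,
    joint_entropy,
    joint_hist_prob,
    make_binning,
    mutual_information,
)
from crckit.infotheory import BinningSpec


def dist_from_counts(counts):
    counts = np.asarray(counts, dtype=float)
    return ProbDist(counts / counts.sum(), int(counts.sum()), counts=counts)


class TestMakeBinning:
    def test_equal_width_edges(self):
        spec = make_binning([0.3, 0.7], [1.0, 3.0], n_bins=4)
        np.testing.assert_allclose(spec.edges_rr, [0.3, 0.4, 0.5, 0.6, 0.7])
        assert spec.n_bins == 4

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateDataError):
            make_binning([0.5, 0.5, 0.5], [1.0, 2.0])

    def test_pooled_range_spans_both_conditions(self):
        b_rr = np.linspace(0.6, 0.9, 10)
        nb_rr = np.linspace(0.3, 0.5, 10)
        spec = make_binning(np.concatenate([b_rr, nb_rr]), [1.0, 2.0], n_bins=8)
        assert spec.edges_rr[0] == pytest.approx(0.3)
        assert spec.edges_rr[-1] == pytest.approx(0.9)


class TestHistProb:
    def test_counting(self):
        d = hist_prob([0.35, 0.45, 0.45, 0.65], [0.3, 0.4, 0.5, 0.6, 0.7])
        np.testing.assert_allclose(d.p, [0.25, 0.5, 0.0, 0.25])
        assert d.n_samples == 4

    def test_single_value_is_delta(self):
        d = hist_prob([0.45], [0.3, 0.4, 0.5, 0.6])
        np.testing.assert_allclose(d.p, [0.0, 1.0, 0.0])

    def test_last_edge_belongs_to_last_bin(self):
        d = hist_prob([0.7], [0.3, 0.5, 0.7])
        np.testing.assert_allclose(d.p, [0.0, 1.0])

    def test_inner_edges_are_left_closed(self):
        d = hist_prob([0.5], [0.3, 0.5, 0.7])
        np.testing.assert_allclose(d.p, [0.0, 1.0])

    def test_out_of_range_value(self):
        with pytest.raises(OutOfRangeError):
            hist_prob([0.2], [0.3, 0.5, 0.7])


class TestEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (np.full(8, 0.125), 3.0),
            ([0.0, 1.0, 0.0], 0.0),
            ([0.5, 0.25, 0.25], 1.5),
        ],
    )
    def test_closed_forms(self, p, expected):
        assert entropy(ProbDist(np.asarray(p), 1)) == pytest.approx(expected, abs=1e-12)


class TestCrossEntropy:
    def test_identical_uniform_gives_log2_n(self):
        u = dist_from_counts([2, 2, 2, 2])
        assert cross_entropy(u, u) == pytest.approx(2.0, abs=1e-12)

    def test_delta_against_fair_coin(self):
        p = dist_from_counts([1, 0])
        q = dist_from_counts([1, 1])
        assert cross_entropy(p, q) == pytest.approx(1.0, abs=1e-12)

    def test_asymmetric_counts(self):
        p = dist_from_counts([3, 1])
        q = dist_from_counts([1, 3])
        expected = -(0.75 * np.log2(0.25) + 0.25 * np.log2(0.75))
        assert expected == pytest.approx(1.6038, abs=5e-5)
        assert cross_entropy(p, q) == pytest.approx(expected, abs=1e-12)

    def test_smoothing_only_on_infinite_terms(self):
        p = dist_from_counts([1, 1])
        q = dist_from_counts([2, 0])
        # q empty where p positive -> Jeffreys smoothing: (2.5, 0.5)/3
        expected = -(0.5 * np.log2(2.5 / 3) + 0.5 * np.log2(0.5 / 3))
        assert cross_entropy(p, q) == pytest.approx(expected, abs=1e-12)

    def test_self_cross_entropy_is_entropy_without_zeros(self):
        p = dist_from_counts([3, 2, 5])
        assert cross_entropy(p, p) == pytest.approx(entropy(p), abs=1e-12)

    def test_mismatched_alphabets(self):
        with pytest.raises(AlphabetError):
            cross_entropy(dist_from_counts([1, 1]), dist_from_counts([1, 1, 1]))

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.integers(1, 50), min_size=2, max_size=6),
        st.lists(st.integers(1, 50), min_size=2, max_size=6),
    )
    def test_gibbs_inequality(self, cp, cq):
        """cH(p, q) >= H(p) on a common alphabet with no empty bins."""
        n = min(len(cp), len(cq))
        p, q = dist_from_counts(cp[:n]), dist_from_counts(cq[:n])
        assert cross_entropy(p, q) >= entropy(p) - 1e-12


class TestJointAndMI:
    def test_diagonal_pairs(self):
        spec = BinningSpec(np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.5, 1.0]))
        j = joint_hist_prob([0.2, 0.8], [0.2, 0.8], spec)
        np.testing.assert_allclose(j.p_xy, [[0.5, 0.0], [0.0, 0.5]])

    def test_marginals_match_1d_histograms(self, rng):
        spec = BinningSpec(np.linspace(0.3, 0.9, 5), np.linspace(1.0, 3.0, 5))
        rr = rng.uniform(0.3, 0.9, 50)
        ibi = rng.uniform(1.0, 3.0, 50)
        j = joint_hist_prob(rr, ibi, spec)
        np.testing.assert_allclose(j.marginal_x.p, hist_prob(rr, spec.edges_rr).p)
        np.testing.assert_allclose(j.marginal_y.p, hist_prob(ibi, spec.edges_ibi).p)

    def test_four_distinct_cells(self):
        spec = BinningSpec(np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.5, 1.0]))
        j = joint_hist_prob([0.2, 0.2, 0.8, 0.8], [0.2, 0.8, 0.2, 0.8], spec)
        np.testing.assert_allclose(j.p_xy, 0.25)

    def test_length_mismatch(self):
        spec = BinningSpec(np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.5, 1.0]))
        with pytest.raises(PairingError):
            joint_hist_prob([0.2, 0.8], [0.2], spec)

    def test_product_joint_has_zero_mi(self, rng):
        px = rng.dirichlet(np.ones(4))
        py = rng.dirichlet(np.ones(4))
        j = JointProbDist(np.outer(px, py), 100)
        assert mutual_information(j) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_joint_mi_equals_marginal_entropy(self):
        j = JointProbDist(np.diag(np.full(4, 0.25)), 4)
        assert mutual_information(j) == pytest.approx(2.0, abs=1e-12)

    def test_correlated_two_by_two(self):
        j = JointProbDist(np.array([[0.4, 0.1], [0.1, 0.4]]), 10)
        # direct evaluation: H(X)=H(Y)=1, H(X,Y)=-2(0.4 lg 0.4 + 0.1 lg 0.1)
        hxy = -2 * (0.4 * np.log2(0.4) + 0.1 * np.log2(0.1))
        assert mutual_information(j) == pytest.approx(2.0 - hxy, abs=1e-12)
        assert mutual_information(j) == pytest.approx(0.2781, abs=5e-5)

    def test_mi_symmetric_under_transpose(self, rng):
        p = rng.dirichlet(np.ones(16)).reshape(4, 4)
        j = JointProbDist(p, 100)
        jt = JointProbDist(p.T, 100)
        assert mutual_information(j) == pytest.approx(mutual_information(jt), abs=1e-12)

    def test_mi_bounded_by_marginal_entropies(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(9)).reshape(3, 3)
            j = JointProbDist(p, 50)
            mi = mutual_information(j)
            assert mi >= -1e-12
            assert mi <= min(entropy(j.marginal_x), entropy(j.marginal_y)) + 1e-12

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(0, 20), min_size=4, max_size=12).filter(lambda c: sum(c) > 0))
    def test_merging_adjacent_bins_never_increases_entropy(self, counts):
        counts = np.asarray(counts, dtype=float)
        p = counts / counts.sum()
        h_fine = entropy(ProbDist(p, int(counts.sum())))
        k = len(p) // 2
        merged = p[: 2 * k].reshape(k, 2).sum(axis=1)
        if len(p) > 2 * k:
            merged = np.concatenate([merged, p[2 * k:]])
        merged /= merged.sum()
        h_coarse = entropy(ProbDist(merged, int(counts.sum())))
        assert h_coarse <= h_fine + 1e-12
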