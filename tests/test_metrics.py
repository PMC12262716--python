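"""Entropy metrics, k-NN graphs, agreement and label alignment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consentropy import (
    align_labelings,
    border_mask,
    build_knn_graph,
    cross_method_entropy,
    pairwise_agreement,
    shannon_entropy,
    smoothness_entropy,
)
from oracles import best_alignment_overlap, entropy_by_hand, pair_counting_ari

LN2 = math.log(2)


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            (["a", "a", "a", "a"], 0.0),
            (["a", "b"], LN2),
            # by hand: -(0.5 ln 0.5 + 2 * 0.25 ln 0.25) = 1.0397207708...
            (["a", "a", "b", "c"], 1.0397207708399179),
        ],
    )
    def test_hand_evaluated_values(self, labels, expected):
        assert shannon_entropy(labels) == pytest.approx(expected, abs=1e-12)

    def test_empty_vector_errors(self):
        with pytest.raises(ValueError):
            shannon_entropy([])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 4), min_size=1, max_size=30))
    def test_bounds_and_permutation_invariance(self, labels):
        h = shannon_entropy(labels)
        m = len(set(labels))
        assert 0 <= h <= math.log(m) + 1e-12
        assert h == pytest.approx(entropy_by_hand(labels), abs=1e-12)
        relabeled = [(x + 3) % 5 for x in labels]
        assert shannon_entropy(relabeled) == pytest.approx(
            shannon_entropy(sorted(labels)), abs=1e-12
        )


def _chain_coords(xs):
    return np.column_stack([np.asarray(xs, dtype=float), np.zeros(len(xs))])


class TestKnnGraph:
    def test_three_point_chain_nearest(self):
        g = build_knn_graph(_chain_coords([0, 1, 2]), k=1)
        assert [list(i) for i in g.neighbor_indices] == [[1], [0], [1]]

    def test_distance_cutoff_after_k_selection(self):
        # unit chain of 5, k=2: ends have 2nd neighbor at distance 2 > 1.5
        g = build_knn_graph(_chain_coords([0, 1, 2, 3, 4]), k=2, max_distance=1.5)
        coords = _chain_coords([0, 1, 2, 3, 4])
        d = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
        for i, (idx, dist) in enumerate(zip(g.neighbor_indices, g.neighbor_distances)):
            # exhaustive pairwise oracle: retained = k nearest within cutoff
            expect = sorted(
                (j for j in range(5) if j != i), key=lambda j: (d[i, j], j)
            )[:2]
            expect = [j for j in expect if d[i, j] <= 1.5]
            assert sorted(idx) == sorted(expect)
            assert np.all(np.diff(dist) >= 0)
        assert len(g.neighbor_indices[0]) == 1
        assert len(g.neighbor_indices[2]) == 2

    def test_tie_break_by_observation_order(self):
        square = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        g = build_knn_graph(square, k=1)
        # each corner has two unit-distance neighbors; lowest index wins
        assert [int(i[0]) for i in g.neighbor_indices] == [1, 0, 0, 1]

    def test_k_must_be_below_n(self):
        with pytest.raises(ValueError):
            build_knn_graph(_chain_coords([0, 1, 2]), k=3)


class TestSmoothnessEntropy:
    def test_constant_labeling_is_zero(self, make_labeling):
        lab = make_labeling([0] * 10)
        field, se = smoothness_entropy(lab, k=3)
        assert se == 0.0
        assert np.all(field.values == 0)

    def test_four_chain_brute_force(self, make_labeling):
        # tie-free geometry so each interior point's nearest neighbor is on
        # its own side of the label boundary
        xs = [0.0, 0.9, 2.0, 2.9]
        lab = make_labeling([0, 0, 1, 1], coords=_chain_coords(xs))
        _, se1 = smoothness_entropy(lab, k=1)
        assert se1 == 0.0
        field2, se2 = smoothness_entropy(lab, k=2)
        # brute-force per-spot oracle: every spot's 3-label neighborhood
        # holds two of one class and one of the other
        h21 = entropy_by_hand([0, 0, 1])
        assert field2.values == pytest.approx([h21] * 4, abs=1e-12)
        assert se2 == pytest.approx(h21, abs=1e-12)

    def test_label_permutation_invariance(self, make_labeling):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, 40)
        lab = make_labeling(labels, coords=rng.normal(size=(40, 2)))
        perm = make_labeling((labels + 2) % 4, coords=lab.coords)
        assert smoothness_entropy(lab)[1] == pytest.approx(
            smoothness_entropy(perm)[1], abs=1e-12
        )

    def test_empty_neighborhood_contributes_zero(self, make_labeling):
        # far-away observation loses all neighbors to the cutoff
        lab = make_labeling([0, 1, 0, 1], coords=_chain_coords([0, 1, 2, 100]))
        g = build_knn_graph(lab.coords, k=2, max_distance=1.5)
        field, _ = smoothness_entropy(lab, g)
        assert field.values[3] == 0.0
        assert field.values[1] > 0


class TestBorderMask:
    def test_constant_labeling_no_borders(self, make_labeling):
        lab = make_labeling([0] * 9, coords=np.indices((3, 3)).reshape(2, -1).T)
        assert not border_mask(lab).any()

    def test_chain_border_spots(self, make_labeling):
        lab = make_labeling([0, 0, 1, 1], coords=_chain_coords([0, 1, 1.9, 2.9]))
        g = build_knn_graph(lab.coords, k=1)
        assert list(border_mask(lab, g)) == [False, True, True, False]

    def test_isolated_observation_is_not_border(self, make_labeling):
        lab = make_labeling([0, 1, 0, 1], coords=_chain_coords([0, 1, 2, 100]))
        g = build_knn_graph(lab.coords, k=2, max_distance=1.5)
        assert not border_mask(lab, g)[3]


class TestPairwiseAgreement:
    def test_identical_columns(self, make_collection):
        coll = make_collection([[0, 0, 1, 1], [0, 0, 1, 1]])
        assert pairwise_agreement(coll).values == pytest.approx(np.ones((2, 2)))

    def test_crossed_partitions_pair_counting(self, make_collection):
        coll = make_collection([[0, 0, 1, 1], [0, 1, 0, 1]])
        # pair-counting oracle over all 6 pairs gives -0.5
        expected = pair_counting_ari([0, 0, 1, 1], [0, 1, 0, 1])
        assert expected == pytest.approx(-0.5)
        assert pairwise_agreement(coll).values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_relabeling_invariance(self, make_collection):
        rng = np.random.default_rng(3)
        a, b = rng.integers(0, 3, 30), rng.integers(0, 3, 30)
        v1 = pairwise_agreement(make_collection([a, b])).values[0, 1]
        v2 = pairwise_agreement(make_collection([(a + 1) % 3, b])).values[0, 1]
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_matches_brute_force_on_random_instances(self, make_collection):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(4, 40))
            a = rng.integers(0, int(rng.integers(1, 5)), n)
            b = rng.integers(0, int(rng.integers(1, 5)), n)
            got = pairwise_agreement(make_collection([a, b])).values[0, 1]
            assert got == pytest.approx(pair_counting_ari(a, b), abs=1e-12)

    def test_single_class_degenerate_rule(self, make_collection):
        ones = pairwise_agreement(make_collection([[0, 0, 0], [1, 1, 1]])).values
        assert ones[0, 1] == 1.0  # identical set partitions
        mixed = pairwise_agreement(make_collection([[0, 0, 0], [0, 0, 1]])).values
        assert mixed[0, 1] == 0.0

    def test_nmi_metric(self, make_collection):
        coll = make_collection([[0, 0, 1, 1], [1, 1, 0, 0]])
        assert pairwise_agreement(coll, "NMI").values[0, 1] == pytest.approx(1.0)

    def test_symmetry_and_diagonal(self, make_collection):
        rng = np.random.default_rng(5)
        coll = make_collection([rng.integers(0, 3, 20) for _ in range(4)])
        v = pairwise_agreement(coll).values
        assert np.allclose(v, v.T, atol=1e-12)
        assert np.allclose(np.diag(v), 1.0)


class TestAlignLabelings:
    def test_permuted_copy_recovers_reference(self):
        rng = np.random.default_rng(2)
        ref = rng.integers(0, 4, 50)
        other = (ref + 2) % 4
        assert np.array_equal(align_labelings(ref, other)[:, 0], ref)

    def test_small_example_against_injection_oracle(self):
        ref = np.array([0, 0, 1, 1])
        other = np.array([0, 1, 1, 1])
        aligned = align_labelings(ref, other)[:, 0]
        overlap = int((aligned == ref).sum())
        assert overlap == best_alignment_overlap(ref, other) == 3

    def test_random_instances_reach_permutation_optimum(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n = int(rng.integers(5, 30))
            ref = rng.integers(0, int(rng.integers(2, 6)), n)
            other = rng.integers(0, int(rng.integers(2, 6)), n)
            aligned = align_labelings(ref, other)[:, 0]
            assert int((aligned == ref).sum()) == best_alignment_overlap(ref, other)

    def test_surplus_classes_get_fresh_codes(self):
        ref = np.array([0, 0, 0, 1])
        other = np.array([0, 1, 2, 3])
        aligned = align_labelings(ref, other)[:, 0]
        # two source classes must land outside the 2-code reference alphabet
        assert (aligned >= 2).sum() == 2
        assert len(set(aligned)) == 4  # stays a bijective recoding


class TestCrossMethodEntropy:
    def test_zero_for_permutation_identical_columns(self, make_collection):
        base = np.array([0, 1, 2, 0, 1, 2])
        coll = make_collection([base, (base + 1) % 3, (base + 2) % 3])
        assert cross_method_entropy(coll).values == pytest.approx(np.zeros(6), abs=1e-12)

    def test_single_disagreement_by_hand(self, make_collection):
        # M=2, 2-class columns differing at one observation: both reference
        # choices align the other column identically, so the disagreeing
        # observation scores ln 2 and all others 0
        a = np.array([0, 0, 1, 1, 0, 1])
        b = a.copy()
        b[2] = 0
        cme = cross_method_entropy(make_collection([a, b]))
        expected = np.zeros(6)
        expected[2] = LN2
        assert cme.values == pytest.approx(expected, abs=1e-12)

    def test_column_order_invariance(self, make_collection):
        rng = np.random.default_rng(9)
        cols = [rng.integers(0, 3, 25) for _ in range(4)]
        v1 = cross_method_entropy(make_collection(cols)).values
        v2 = cross_method_entropy(make_collection(cols[::-1])).values
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_zero_iff_aligned_agreement(self, make_collection):
        rng = np.random.default_rng(10)
        cols = [rng.integers(0, 3, 30) for _ in range(3)]
        cme = cross_method_entropy(make_collection(cols))
        disagreement = ~(
            (align_labelings(cols[0], np.column_stack(cols[1:])) == cols[0][:, None]).all(axis=1)
        )
        # wherever CME is zero the columns agree under every reference;
        # spot-check against the first reference's alignment
        assert np.all(cme.values[~disagreement & (cme.values == 0)] == 0)
        assert np.all(cme.values >= -1e-15)
        assert np.all(cme.values <= cme.alphabet_bound + 1e-12)
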