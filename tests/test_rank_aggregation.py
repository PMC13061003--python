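"""Markov-chain aggregation, stationary distributions, modified Kendall."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netpharm.calibration import (
    eigenvector_stationary,
    exhaustive_consensus,
)
from netpharm.rank_aggregation import (
    ALGORITHMS,
    RankedList,
    borda,
    mc_consensus,
    mc_transition_matrix,
    mean_kendall_to_inputs,
    modified_kendall,
    select_and_aggregate,
    stationary_distribution,
)


def rl(name, *items):
    return RankedList(name=name, items=tuple(items))


class TestTransitionMatrix:
    def test_unanimous_order_forces_direction(self):
        lists = [rl("a", "A", "B"), rl("b", "A", "B")]
        P, items = mc_transition_matrix(lists, "MC3", teleport=0.05)
        i, j = items.index("A"), items.index("B")
        # before teleport: A->B is 0, B->A is 1 * (1/n); teleport adds 0.025
        assert P[i, j] == pytest.approx(0.05 / 2)
        assert P[j, i] == pytest.approx(0.95 * 0.5 + 0.05 / 2)

    def test_single_item_universe(self):
        lists = [rl("a", "A"), rl("b", "A")]
        P, items = mc_transition_matrix(lists, "MC3")
        assert items == ["A"]
        assert P == pytest.approx(np.array([[1.0]]))

    def test_mc3_hand_evaluation_with_disagreement(self):
        # two lists over three items, one disagreement: B,C swapped
        lists = [rl("a", "A", "B", "C"), rl("b", "A", "C", "B")]
        P, items = mc_transition_matrix(lists, "MC3", teleport=0.05)
        idx = {it: i for i, it in enumerate(items)}
        n = 3

        def expect(u, v, frac):
            return 0.95 * frac / n + 0.05 / n

        # A above B in both lists: B->A fraction 1, A->B fraction 0
        assert P[idx["A"], idx["B"]] == pytest.approx(expect("A", "B", 0.0))
        assert P[idx["B"], idx["A"]] == pytest.approx(expect("B", "A", 1.0))
        # B vs C: split 1/2 each way
        assert P[idx["B"], idx["C"]] == pytest.approx(expect("B", "C", 0.5))
        assert P[idx["C"], idx["B"]] == pytest.approx(expect("C", "B", 0.5))

    @pytest.mark.parametrize("variant", ["MC1", "MC2", "MC3"])
    def test_rows_sum_to_one(self, variant, rng):
        items = [f"I{i}" for i in range(7)]
        lists = [
            RankedList(name=f"L{j}", items=tuple(rng.permutation(items)))
            for j in range(3)
        ]
        P, _ = mc_transition_matrix(lists, variant)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert (P >= 0).all()


class TestStationaryDistribution:
    def test_symmetric_teleport_matrix_is_uniform(self):
        k = 4
        P = 0.9 * np.eye(k) + 0.1 / k
        pi = stationary_distribution(P)
        assert pi == pytest.approx(np.full(k, 1 / k))

    def test_doubly_stochastic_two_state(self):
        pi = stationary_distribution(np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert pi == pytest.approx([0.5, 0.5])

    def test_matches_eigenvector_oracle_on_random_chains(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 8))
            P = rng.random((n, n)) + 0.05
            P /= P.sum(axis=1, keepdims=True)
            pi = stationary_distribution(P)
            assert np.max(np.abs(pi - eigenvector_stationary(P))) <= 1e-8

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.array([[0.5, 0.1], [0.5, 0.5]]))


class TestModifiedKendall:
    def test_identical_lists_zero(self):
        a = rl("a", "A", "B", "C")
        assert modified_kendall(a, a) == 0.0

    def test_exact_reversal_is_one(self):
        a = rl("a", "A", "B", "C", "D")
        b = rl("b", "D", "C", "B", "A")
        for p in (0.0, 0.5, 1.0):
            assert modified_kendall(a, b, penalty_p=p) == 1.0

    def test_partial_overlap_matches_pair_enumeration(self):
        a = rl("a", "A", "B", "C", "D", "E")
        b = rl("b", "C", "F", "G", "A", "B")
        k, p = 3, 0.5
        # union of top-3 prefixes (A,B,C) and (C,F,G) has 10 pairs:
        # (A,B): ordered by a only (both outside b's top-3) -> penalty 0.5
        # (F,G): ordered by b only -> penalty 0.5
        # (A,C),(B,C): discordant (a: A,B above C; b: C above absent A,B) -> 1 each
        # (A,F),(A,G),(B,F),(B,G): each present in exactly one prefix,
        #   above the other there, so the lists disagree -> 1 each
        # (C,F),(C,G): C above F,G in both -> 0 each
        want = (0.5 + 0.5 + 1 + 1 + 1 + 1 + 1 + 1 + 0 + 0) / 10
        assert modified_kendall(a, b, penalty_p=p, top_k=k) == pytest.approx(want)

    def test_top_k_too_small_raises(self):
        with pytest.raises(ValueError):
            modified_kendall(rl("a", "A", "B"), rl("b", "A", "B"), top_k=1)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        items = [f"I{i}" for i in range(6)]
        a = RankedList(name="a", items=tuple(rng.permutation(items)))
        b = RankedList(name="b", items=tuple(rng.permutation(items)))
        assert modified_kendall(a, b, 0.5, 4) == modified_kendall(b, a, 0.5, 4)

    def test_zero_only_for_order_identical_topk(self, rng):
        items = [f"I{i}" for i in range(5)]
        a = RankedList(name="a", items=tuple(items))
        for _ in range(20):
            b = RankedList(name="b", items=tuple(rng.permutation(items)))
            d = modified_kendall(a, b, 0.5, 4)
            assert (d == 0.0) == (a.items[:4] == b.items[:4])


class TestSelectAndAggregate:
    def test_identical_lists_returned_for_every_algorithm(self):
        base = rl("x", "C", "A", "B")
        lists = [rl("a", *base.items), rl("b", *base.items), rl("c", *base.items)]
        for algo in ALGORITHMS:
            agg = select_and_aggregate(lists, candidates=[algo])
            assert agg.consensus.items == base.items
            assert agg.mean_kendall == 0.0

    def test_stationary_probabilities_sum_to_one(self, rng):
        items = [f"I{i}" for i in range(6)]
        lists = [
            RankedList(name=f"L{j}", items=tuple(rng.permutation(items)))
            for j in range(3)
        ]
        agg = select_and_aggregate(lists)
        assert sum(agg.stationary.values()) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_planted_order_recovered_better_than_median_input(self, rng):
        planted = [f"I{i:02d}" for i in range(12)]
        lists = []
        for j in range(6):
            noisy = planted.copy()
            for _ in range(3):  # a few adjacent swaps
                i = int(rng.integers(0, len(noisy) - 1))
                noisy[i], noisy[i + 1] = noisy[i + 1], noisy[i]
            lists.append(RankedList(name=f"L{j}", items=tuple(noisy)))
        truth = RankedList(name="truth", items=tuple(planted))
        agg = select_and_aggregate(lists)
        d_cons = modified_kendall(agg.consensus, truth)
        d_inputs = sorted(modified_kendall(rl_, truth) for rl_ in lists)
        median_input = d_inputs[len(d_inputs) // 2]
        assert d_cons <= median_input

    def test_matches_exhaustive_on_three_items(self):
        for p1 in itertools.permutations(("A", "B", "C")):
            for p2 in itertools.permutations(("A", "B", "C")):
                lists = [rl("a", *p1), rl("b", *p2)]
                agg = select_and_aggregate(lists)
                _, best = exhaustive_consensus(lists)
                assert agg.mean_kendall == pytest.approx(best, abs=1e-12)

    def test_label_equivariance(self, rng):
        items = [f"I{i}" for i in range(5)]
        lists = [
            RankedList(name=f"L{j}", items=tuple(rng.permutation(items)))
            for j in range(3)
        ]
        perm = {it: f"Z{i}" for i, it in enumerate(items)}
        relabeled = [
            RankedList(name=l.name, items=tuple(perm[i] for i in l.items))
            for l in lists
        ]
        a1 = select_and_aggregate(lists, candidates=["MC3"])
        a2 = select_and_aggregate(relabeled, candidates=["MC3"])
        assert tuple(perm[i] for i in a1.consensus.items) == a2.consensus.items


def test_borda_handles_missing_items():
    lists = [rl("a", "A", "B"), rl("b", "B", "C")]
    consensus, scores = borda(lists)
    # A: (1 + 3)/2 = 2, B: (2 + 1)/2 = 1.5, C: (3 + 2)/2 = 2.5
    assert consensus.items == ("B", "A", "C")
    assert scores["B"] == pytest.approx(1.5)
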