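import numpy as np
import pytest
from hypothesis import given, strategies as st

from srpomb import pomb
from srpomb.pomb import MBCandidate

from oracles import pareto_front_bruteforce, rank_bruteforce


def cand(fperf, fred, name="c"):
    return MBCandidate(variables={name}, fperf=fperf, fred=fred)


def random_cands(rng, n):
    return [MBCandidate(variables={f"v{i}"},
                        fperf=float(np.round(rng.uniform(), 3)),
                        fred=float(np.round(rng.uniform(), 3)))
            for i in range(n)]


class TestDominance:
    def test_better_in_both_dominates(self):
        assert pomb.pareto_dominates(cand(0.8, 0.1), cand(0.7, 0.3))

    def test_trade_off_is_incomparable(self):
        a, b = cand(0.9, 0.2), cand(0.8, 0.1)
        assert not pomb.pareto_dominates(a, b)
        assert not pomb.pareto_dominates(b, a)

    def test_identical_scores_do_not_dominate(self):
        assert not pomb.pareto_dominates(cand(0.5, 0.5), cand(0.5, 0.5))

    def test_unscored_rejected(self):
        with pytest.raises(ValueError):
            pomb.pareto_dominates(MBCandidate(variables={"a"}), cand(0.5, 0.5))


class TestFront:
    def test_single_candidate_is_its_own_front(self):
        c = cand(0.5, 0.5)
        assert pomb.pareto_front([c]) == [c]

    def test_three_candidate_example(self):
        a, b, c = cand(0.9, 0.2, "a"), cand(0.8, 0.1, "b"), cand(0.7, 0.3, "c")
        assert pomb.pareto_front([a, b, c]) == [a, b]

    def test_empty_input_gives_empty_front(self):
        assert pomb.pareto_front([]) == []

    def test_matches_bruteforce_on_random_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            cands = random_cands(rng, int(rng.integers(2, 50)))
            mine = pomb.pareto_front(cands)
            ref_idx = pareto_front_bruteforce(
                [(c.fperf, c.fred) for c in cands])
            assert mine == [cands[i] for i in ref_idx]

    @given(st.integers(0, 10 ** 6))
    def test_front_members_mutually_nondominated(self, seed):
        rng = np.random.default_rng(seed)
        cands = random_cands(rng, 12)
        front = pomb.pareto_front(cands)
        for a in front:
            for b in front:
                if a is not b:
                    assert not pomb.pareto_dominates(a, b)


class TestCrowding:
    def test_two_members_both_infinite(self):
        cds = pomb.crowding_distances([cand(0.9, 0.2), cand(0.8, 0.1)])
        assert cds == [float("inf"), float("inf")]

    def test_hand_evaluated_interior_distance(self):
        front = [cand(0.9, 0.2, "a"), cand(0.8, 0.1, "b"), cand(0.7, 0.05, "c")]
        cds = pomb.crowding_distances(front)
        assert cds[0] == float("inf") and cds[2] == float("inf")
        # |0.9 - 0.7| + |0.2 - 0.05|
        assert cds[1] == pytest.approx(0.35)

    def test_interior_duplicate_gets_zero(self):
        front = [cand(0.9, 0.1, "a"), cand(0.9, 0.1, "b"), cand(0.9, 0.1, "c")]
        cds = pomb.crowding_distances(front)
        assert cds[1] == 0.0
        assert cds[0] == float("inf") and cds[2] == float("inf")


class TestRanking:
    def test_single_candidate_rank_one(self):
        entries = pomb.rank_markov_blankets([cand(0.5, 0.5)])
        assert entries[0].rank == 1 and entries[0].in_front

    def test_dominance_degree_orders_front(self):
        # two incomparable front members; "a" dominates 3 others, "b" only 1
        a = cand(0.9, 0.2, "a")
        b = cand(0.95, 0.5, "b")
        dominated = [cand(0.8, 0.3, "d1"), cand(0.7, 0.25, "d2"),
                     cand(0.6, 0.3, "d3"), cand(0.9, 0.6, "d4")]
        entries = pomb.rank_markov_blankets([b, a] + dominated)
        assert entries[0].candidate is a
        assert entries[0].dominance_degree > entries[1].dominance_degree

    def test_matches_independent_sort_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            cands = random_cands(rng, 30)
            entries = pomb.rank_markov_blankets(cands)
            front_idx = pareto_front_bruteforce([(c.fperf, c.fred) for c in cands])
            degrees = [sum(pomb.pareto_dominates(c, o)
                           for o in cands if o is not c) for c in cands]
            # oracle crowding computed per group, mirroring the contract
            crowding = [0.0] * len(cands)
            for group in (front_idx,
                          [i for i in range(len(cands)) if i not in front_idx]):
                cds = pomb.crowding_distances([cands[i] for i in group])
                for i, cd in zip(group, cds):
                    crowding[i] = cd
            names = [tuple(sorted(c.variables)) for c in cands]
            ref = rank_bruteforce([(c.fperf, c.fred) for c in cands],
                                  names, front_idx, degrees, crowding)
            assert [e.candidate for e in entries] == [cands[i] for i in ref]

    def test_order_is_deterministic_across_runs(self):
        rng = np.random.default_rng(5)
        cands = random_cands(rng, 20)
        r1 = [e.candidate.sort_name() for e in pomb.rank_markov_blankets(cands)]
        r2 = [e.candidate.sort_name()
              for e in pomb.rank_markov_blankets(list(cands))]
        assert r1 == r2


class TestUpdateFront:
    def test_dominated_newcomer_leaves_front_unchanged(self):
        front = [cand(0.9, 0.1, "a")]
        out = pomb.update_front(front, [cand(0.5, 0.5, "b")])
        assert out == front

    def test_dominating_newcomer_replaces_member(self):
        a, b = cand(0.5, 0.5, "a"), cand(0.9, 0.1, "b")
        out = pomb.update_front([a], [b])
        assert out == [b]

    def test_incremental_equals_batch(self):
        rng = np.random.default_rng(77)
        all_cands = random_cands(rng, 60)
        front = []
        for i in range(0, 60, 3):
            front = pomb.update_front(front, all_cands[i:i + 3])
        batch = pomb.pareto_front(all_cands)
        assert {c.sort_name() for c in front} == {c.sort_name() for c in batch}
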