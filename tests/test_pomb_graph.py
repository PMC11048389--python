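import itertools

import networkx as nx
import numpy as np
import pytest

from srpomb import pomb
from srpomb.pomb import HyperNet, MBCandidate

from oracles import (blanket_bruteforce, dsep_bruteforce, enumerate_paths,
                     random_dag)


def net_from(g: nx.DiGraph) -> HyperNet:
    return HyperNet(edges=list(g.edges), nodes=list(g.nodes))


class TestVStructures:
    def test_chain_has_no_collider(self):
        net = HyperNet(edges=[("A", "B"), ("B", "C")])
        assert pomb.detect_v_structures(net) == []

    def test_unshielded_collider_detected(self):
        net = HyperNet(edges=[("A", "C"), ("B", "C")])
        assert pomb.detect_v_structures(net) == [("A", "C", "B")]

    def test_shielded_collider_excluded(self):
        net = HyperNet(edges=[("A", "C"), ("B", "C"), ("A", "B")])
        assert pomb.detect_v_structures(net) == []


class TestDSeparation:
    def test_chain_blocked_by_middle(self):
        net = HyperNet(edges=[("A", "B"), ("B", "C")])
        assert pomb.d_separated(net, "A", "C", {"B"})
        assert not pomb.d_separated(net, "A", "C", set())

    def test_fork_blocked_by_middle(self):
        net = HyperNet(edges=[("B", "A"), ("B", "C")])
        assert pomb.d_separated(net, "A", "C", {"B"})
        assert not pomb.d_separated(net, "A", "C", set())

    def test_collider_open_only_when_conditioned(self):
        net = HyperNet(edges=[("A", "C"), ("B", "C")])
        assert pomb.d_separated(net, "A", "B", set())
        assert not pomb.d_separated(net, "A", "B", {"C"})

    def test_collider_descendant_opens_path(self):
        net = HyperNet(edges=[("A", "C"), ("B", "C"), ("C", "D")])
        assert not pomb.d_separated(net, "A", "B", {"D"})

    def test_agrees_with_path_enumeration_oracle_on_random_dags(self):
        rng = np.random.default_rng(2024)
        mismatches = 0
        for _ in range(60):
            g = random_dag(rng, n_nodes=int(rng.integers(4, 8)), edge_p=0.3)
            net = net_from(g)
            desc = {n: nx.descendants(g, n) for n in g.nodes}
            nodes = sorted(g.nodes)
            for x, y in itertools.combinations(nodes, 2):
                paths = enumerate_paths(g, x, y)
                others = [n for n in nodes if n not in (x, y)]
                for size in range(0, min(3, len(others)) + 1):
                    for S in itertools.combinations(others, size):
                        mine = pomb.d_separated(net, x, y, set(S))
                        ref = dsep_bruteforce(g, x, y, set(S), paths, desc)
                        mismatches += mine != ref
        assert mismatches == 0

    def test_agrees_with_networkx(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = random_dag(rng, 6, edge_p=0.35)
            net = net_from(g)
            nodes = sorted(g.nodes)
            for x, y in itertools.combinations(nodes, 2):
                for S in ([], [n for n in nodes if n not in (x, y)][:2]):
                    assert pomb.d_separated(net, x, y, set(S)) == \
                        nx.is_d_separator(g, {x}, {y}, set(S))

    def test_invalid_queries_rejected(self):
        net = HyperNet(edges=[("A", "B")])
        with pytest.raises(ValueError):
            pomb.d_separated(net, "A", "Z", set())
        with pytest.raises(ValueError):
            pomb.d_separated(net, "A", "B", {"A"})


class TestMarkovBlanket:
    def test_parent_child_spouse(self):
        net = HyperNet(edges=[("P", "T"), ("T", "C"), ("S", "C")])
        assert pomb.markov_blanket(net, "T") == {"P", "C", "S"}

    def test_isolated_target_is_empty(self):
        net = HyperNet(edges=[("A", "B")], nodes=["T"])
        assert pomb.markov_blanket(net, "T") == frozenset()

    def test_blanket_separates_and_is_minimal_on_random_dags(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            g = random_dag(rng, int(rng.integers(4, 8)), edge_p=0.35)
            net = net_from(g)
            for t in sorted(g.nodes):
                mb = pomb.markov_blanket(net, t)
                assert mb == blanket_bruteforce(g, t)
                outside = set(g.nodes) - mb - {t}
                # separation: T _||_ X | MB for every outside X
                for x in outside:
                    assert pomb.d_separated(net, t, x, mb)
                # minimality: no single removal preserves the property
                for drop in mb:
                    sub = mb - {drop}
                    assert not all(
                        pomb.d_separated(net, t, x, sub)
                        for x in (outside | {drop}))


class TestClassification:
    def test_parent_is_strongly_relevant(self, demo_net):
        assert pomb.classify_hyperparameter(demo_net, "h1", "accuracy").kind \
            == "strongly_relevant"

    def test_disconnected_is_irrelevant(self, demo_net):
        assert pomb.classify_hyperparameter(demo_net, "h4", "accuracy").kind \
            == "irrelevant"

    def test_copy_variable_is_redundant(self, demo_net):
        assert pomb.classify_hyperparameter(demo_net, "h3", "accuracy").kind \
            == "redundant"

    def test_mediated_variable_reports_separating_set(self):
        net = HyperNet(edges=[("X", "Z"), ("Z", "T"), ("W", "Z"), ("W", "Q"),
                              ("Q", "T")])
        role = pomb.classify_hyperparameter(net, "X", "T")
        assert role.kind == "conditionally_independent"
        assert pomb.d_separated(net, "X", "T", role.separating_set)

    def test_consistent_with_dsep_sweep_on_random_dags(self):
        rng = np.random.default_rng(31)
        for _ in range(15):
            g = random_dag(rng, 6, edge_p=0.3)
            net = net_from(g)
            nodes = sorted(g.nodes)
            t = nodes[0]
            mb = pomb.markov_blanket(net, t)
            for x in nodes[1:]:
                role = pomb.classify_hyperparameter(net, x, t)
                if role.kind == "strongly_relevant":
                    assert x in mb
                elif role.kind == "irrelevant":
                    others = [n for n in nodes if n not in (x, t)]
                    for size in range(min(3, len(others)) + 1):
                        for S in itertools.combinations(others, size):
                            assert pomb.d_separated(net, x, t, set(S))
                elif role.kind == "conditionally_independent":
                    assert pomb.d_separated(net, x, t, role.separating_set)


class TestRefineAndValidate:
    def test_exact_blanket_unchanged(self, demo_net):
        mb = MBCandidate(variables=pomb.markov_blanket(demo_net, "accuracy"))
        out = pomb.refine_and_validate(demo_net, mb, "accuracy")
        assert out.variables == {"h1", "h2"}

    def test_disconnected_extra_removed(self, demo_net):
        mb = MBCandidate(variables={"h1", "h2", "h4"})
        out = pomb.refine_and_validate(demo_net, mb, "accuracy")
        assert out.variables == {"h1", "h2"}

    def test_blanket_plus_extras_recovers_blanket_on_random_dags(self):
        rng = np.random.default_rng(55)
        for _ in range(30):
            g = random_dag(rng, int(rng.integers(4, 8)), edge_p=0.35)
            net = net_from(g)
            nodes = sorted(g.nodes)
            t = nodes[int(rng.integers(len(nodes)))]
            mb = pomb.markov_blanket(net, t)
            extras = [n for n in nodes if n != t and n not in mb]
            rng.shuffle(extras)
            cand = MBCandidate(variables=set(mb) | set(extras[:2]))
            out = pomb.refine_and_validate(net, cand, t)
            assert out.variables == mb
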