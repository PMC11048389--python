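"""Pareto-optimal Markov blanket (POMB) hyperparameter selection.

A hyperparameter search space is modelled as a Bayesian network: a DAG whose
nodes are hyperparameters plus one (or more) performance-metric variables,
with edges encoding conditional dependence.  Under the faithfulness
assumption, the Markov blanket of the target metric ``T`` — its parents,
children and spouses (co-parents of its children) — is the minimal variable
set rendering ``T`` conditionally independent of everything else, and is
therefore the natural candidate set for tuning.

Candidate blankets are scored on two objectives measured from a table of
past trials:

* ``fperf`` — cross-validated explained variance of predicting ``T`` from
  the joint (discrete) assignment of the candidate's variables with a
  Laplace-smoothed conditional-mean predictor, and
* ``fred`` — mean pairwise normalized mutual information among the
  candidate's variables (0 for singletons).

Candidates are then ranked by Pareto optimality: the non-dominated front
first, ordered within by dominance degree (how many candidates each
dominates), then crowding distance, then lexicographic variable names; the
top entry is the POMB.

Graph machinery (d-separation via Bayes-ball reachability, V-structure
detection, blanket construction, refinement) lives here as well, all
operating on :class:`HyperNet`.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .phantoms import TrialTable

__all__ = [
    "HyperNet",
    "MBCandidate",
    "ParetoRankEntry",
    "Role",
    "POMBResult",
    "detect_v_structures",
    "d_separated",
    "markov_blanket",
    "pareto_dominates",
    "pareto_front",
    "crowding_distances",
    "rank_markov_blankets",
    "evaluate_candidate",
    "identify_pomb",
    "refine_and_validate",
    "classify_hyperparameter",
    "update_front",
    "fit_cpts",
    "check_faithfulness",
]


# --------------------------------------------------------------------------
# network container
# --------------------------------------------------------------------------

class HyperNet:
    """DAG over hyperparameter and metric variables with optional CPTs.

    Parameters
    ----------
    edges : iterable of (parent, child) pairs
    nodes : optional iterable of extra (possibly isolated) node names
    target : optional name of the target metric node
    cpts : optional map node -> conditional probability table, where a table
        maps a tuple of parent values to a ``{state: probability}`` dict;
        every row must sum to 1 within 1e-9.
    """

    def __init__(self, edges, nodes=None, target=None, cpts=None):
        g = nx.DiGraph()
        g.add_nodes_from(nodes or [])
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("hyperparameter network must be a DAG")
        if target is not None and target not in g:
            raise ValueError(f"target {target!r} not a node of the network")
        self.graph = g
        self.target = target
        self.cpts = dict(cpts or {})
        for node, table in self.cpts.items():
            if node not in g:
                raise ValueError(f"CPT for unknown node {node!r}")
            for row_key, row in table.items():
                total = sum(row.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"CPT row {row_key!r} of {node!r} sums to {total}, not 1")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def parents(self, n) -> set:
        return set(self.graph.predecessors(n))

    def children(self, n) -> set:
        return set(self.graph.successors(n))

    def _require(self, *names) -> None:
        for n in names:
            if n not in self.graph:
                raise ValueError(f"unknown node {n!r}")

    def to_json(self) -> str:
        return json.dumps({"nodes": self.nodes, "edges": self.edges,
                           "target": self.target}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "HyperNet":
        d = json.loads(text)
        return cls(edges=[tuple(e) for e in d.get("edges", [])],
                   nodes=d.get("nodes", []), target=d.get("target"))


# --------------------------------------------------------------------------
# candidate containers
# --------------------------------------------------------------------------

@dataclass
class MBCandidate:
    """A candidate Markov blanket with its two objective scores."""

    variables: frozenset
    fperf: float | None = None
    fred: float | None = None
    provenance: str = "supplied"

    def __post_init__(self) -> None:
        self.variables = frozenset(self.variables)
        if self.fred is not None and self.fred < -1e-12:
            raise ValueError("fred must be >= 0")

    @property
    def scored(self) -> bool:
        return self.fperf is not None and self.fred is not None

    def sort_name(self) -> tuple:
        return tuple(sorted(self.variables))


@dataclass
class ParetoRankEntry:
    candidate: MBCandidate
    in_front: bool
    dominance_degree: int
    crowding: float
    rank: int


@dataclass
class Role:
    """Relevance classification of a hyperparameter w.r.t. the target."""

    kind: str                       # strongly_relevant | redundant | irrelevant
    #                               # | conditionally_independent
    separating_set: frozenset | None = None

    def __str__(self) -> str:
        if self.kind == "conditionally_independent":
            return f"conditionally_independent_given({sorted(self.separating_set)})"
        return self.kind


@dataclass
class POMBResult:
    entries: list[ParetoRankEntry]
    pomb: MBCandidate | None

    @property
    def pomb_variables(self) -> frozenset:
        return self.pomb.variables if self.pomb is not None else frozenset()


# --------------------------------------------------------------------------
# graph criteria
# --------------------------------------------------------------------------

def detect_v_structures(net: HyperNet) -> list[tuple[str, str, str]]:
    """All unshielded colliders ``a -> c <- b`` (no a-b edge either way),
    returned as (a, c, b) triples with a < b, sorted for determinism."""
    g = net.graph
    out = []
    for c in g.nodes:
        parents = sorted(g.predecessors(c))
        for a, b in itertools.combinations(parents, 2):
            if not (g.has_edge(a, b) or g.has_edge(b, a)):
                out.append((a, c, b))
    return sorted(out)


def d_separated(net: HyperNet, X: str, Y: str, S) -> bool:
    """Standard d-separation via Bayes-ball reachability.

    True iff every undirected path between ``X`` and ``Y`` is blocked given
    ``S``: chains and forks are blocked when their middle node is in ``S``;
    a collider blocks unless the collider or one of its descendants is in
    ``S``.
    """
    S = frozenset(S)
    net._require(X, Y, *S)
    if X == Y:
        raise ValueError("X and Y must differ")
    if X in S or Y in S:
        raise ValueError("X and Y must not be in the conditioning set")
    g = net.graph

    ancestors_of_S = set(S)
    for z in S:
        ancestors_of_S |= nx.ancestors(g, z)

    # Bayes-ball: traverse (node, direction) states; "up" = arrived from a
    # child (moving against edges), "down" = arrived from a parent.
    visited = set()
    reachable = set()
    frontier = [(X, "up")]
    while frontier:
        node, direction = frontier.pop()
        if (node, direction) in visited:
            continue
        visited.add((node, direction))
        if node not in S:
            reachable.add(node)
        if direction == "up" and node not in S:
            for p in g.predecessors(node):
                frontier.append((p, "up"))
            for c in g.successors(node):
                frontier.append((c, "down"))
        elif direction == "down":
            if node not in S:
                for c in g.successors(node):
                    frontier.append((c, "down"))
            if node in ancestors_of_S:
                for p in g.predecessors(node):
                    frontier.append((p, "up"))
    return Y not in reachable


def markov_blanket(net: HyperNet, T: str) -> frozenset:
    """Parents, children, and spouses (other parents of children) of ``T``."""
    net._require(T)
    g = net.graph
    parents = set(g.predecessors(T))
    children = set(g.successors(T))
    spouses = set()
    for c in children:
        spouses |= set(g.predecessors(c))
    return frozenset((parents | children | spouses) - {T})


def classify_hyperparameter(net: HyperNet, X: str, T: str) -> Role:
    """Relevance taxonomy of ``X`` for target ``T``.

    * strongly relevant: ``X`` is in the Markov blanket of ``T``;
    * irrelevant: ``X`` is graph-disconnected from ``T`` (d-separated under
      every conditioning set);
    * redundant: weakly relevant with ``MB(X)`` contained in
      ``MB(T) + {T}``;
    * otherwise: conditionally independent given the smallest separating set
      found (subsets searched in increasing size, lexicographic order).
    """
    net._require(X, T)
    if X == T:
        raise ValueError("X must differ from the target")
    mb_t = markov_blanket(net, T)
    if X in mb_t:
        return Role("strongly_relevant")
    und = net.graph.to_undirected(as_view=True)
    if not nx.has_path(und, X, T):
        return Role("irrelevant")
    if markov_blanket(net, X) <= (mb_t | {T}):
        return Role("redundant")
    others = sorted(set(net.graph.nodes) - {X, T})
    for size in range(len(others) + 1):
        for S in itertools.combinations(others, size):
            if d_separated(net, X, T, S):
                return Role("conditionally_independent", frozenset(S))
    # connected but never separable: treat as strongly coupled
    return Role("strongly_relevant")


def refine_and_validate(net: HyperNet, mb: MBCandidate, T: str) -> MBCandidate:
    """Refine a candidate blanket against the DAG.

    Members forming V-structures pointing into ``T`` (or into ``T``'s
    children) keep their spouses included; members that are d-separated from
    ``T`` given the rest of the candidate are removed, iterating to a fixed
    point.  For any candidate containing the structural blanket the result
    is exactly ``MB(T)``.
    """
    net._require(T, *mb.variables)
    g = net.graph
    result = set(mb.variables) - {T}

    parents_t = set(g.predecessors(T))
    children_t = set(g.successors(T))
    for X in sorted(result):
        if X in parents_t and len(parents_t) > 1:
            result |= parents_t            # co-parents in a collider at T
        for c in children_t:
            if X in g.predecessors(c):
                result |= set(g.predecessors(c)) - {T}   # spouses through c
    result -= {T}

    changed = True
    while changed:
        changed = False
        for X in sorted(result):
            if d_separated(net, T, X, result - {X}):
                result.remove(X)
                changed = True
                break
    return MBCandidate(variables=frozenset(result), provenance=mb.provenance)


# --------------------------------------------------------------------------
# Pareto machinery
# --------------------------------------------------------------------------

def _require_scored(*cands: MBCandidate) -> None:
    for c in cands:
        if not c.scored:
            raise ValueError(f"candidate {sorted(c.variables)} is unscored")


def pareto_dominates(a: MBCandidate, b: MBCandidate) -> bool:
    """True iff ``a`` is no worse in both objectives (fperf higher-better,
    fred lower-better) and strictly better in at least one."""
    _require_scored(a, b)
    ge = a.fperf >= b.fperf and a.fred <= b.fred
    strict = a.fperf > b.fperf or a.fred < b.fred
    return ge and strict


def pareto_front(cands: list[MBCandidate]) -> list[MBCandidate]:
    """Exactly the non-dominated candidates, in input order."""
    _require_scored(*cands)
    return [c for c in cands
            if not any(pareto_dominates(o, c) for o in cands if o is not c)]


def crowding_distances(front: list[MBCandidate]) -> list[float]:
    """Crowding distance per front member, aligned with the input list.

    Per objective the front is sorted; boundary members receive ``+inf`` and
    interior members accumulate the absolute gap between their neighbours'
    objective values, summed over both objectives.
    """
    _require_scored(*front)
    n = len(front)
    cd = [0.0] * n
    if n == 0:
        return cd
    for key in (lambda c: c.fperf, lambda c: c.fred):
        order = sorted(range(n), key=lambda i: (key(front[i]), i))
        cd[order[0]] = float("inf")
        cd[order[-1]] = float("inf")
        for pos in range(1, n - 1):
            i = order[pos]
            if cd[i] != float("inf"):
                gap = abs(key(front[order[pos + 1]]) - key(front[order[pos - 1]]))
                cd[i] += gap
    return cd


def _dominance_degrees(cands: list[MBCandidate]) -> list[int]:
    return [sum(pareto_dominates(c, o) for o in cands if o is not c)
            for c in cands]


def rank_markov_blankets(cands: list[MBCandidate]) -> list[ParetoRankEntry]:
    """Deterministic total order over candidates.

    Front members first.  Within each group (front, then dominated) the sort
    keys are: dominance degree (descending), crowding distance within the
    group (descending), then lexicographic variable names.
    """
    _require_scored(*cands)
    if not cands:
        return []
    front = set(id(c) for c in pareto_front(cands))
    degrees = _dominance_degrees(cands)

    groups = {True: [], False: []}
    for i, c in enumerate(cands):
        groups[id(c) in front].append(i)

    entries: list[ParetoRankEntry] = []
    for is_front in (True, False):
        idx = groups[is_front]
        group = [cands[i] for i in idx]
        cds = crowding_distances(group)
        ordered = sorted(
            zip(idx, cds),
            key=lambda t: (-degrees[t[0]], -t[1], cands[t[0]].sort_name()),
        )
        for i, cd in ordered:
            entries.append(ParetoRankEntry(
                candidate=cands[i], in_front=is_front,
                dominance_degree=degrees[i], crowding=cd,
                rank=len(entries) + 1))
    return entries


def update_front(front: list[MBCandidate], new_cands: list[MBCandidate]) -> list[MBCandidate]:
    """Integrate new candidates: equals the batch front of the union."""
    return pareto_front(list(front) + list(new_cands))


# --------------------------------------------------------------------------
# data-driven scoring
# --------------------------------------------------------------------------

def evaluate_candidate(vars, trials: TrialTable, T: str, folds: int = 5,
                       seed: int = 0, smoothing: float = 1.0) -> tuple[float, float]:
    """Score a variable set on (fperf, fred) from a trial table.

    fperf: K-fold cross-validated explained variance of predicting ``T``
    from the joint assignment of ``vars`` with conditional means shrunk
    toward the training mean by ``smoothing`` pseudo-observations; unseen
    assignments fall back to the training mean.  fred: mean pairwise
    normalized mutual information among ``vars`` (0 for singletons).  Fold
    assignment is a seeded permutation, so the result is deterministic.
    """
    from sklearn.metrics import normalized_mutual_info_score

    names = sorted(vars)
    if not names:
        raise ValueError("variable set must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    missing = [v for v in names if v not in trials.frame.columns]
    if missing:
        raise ValueError(f"variables missing from trials: {missing}")
    if T not in trials.frame.columns:
        raise ValueError(f"target {T!r} missing from trials")

    y = trials.frame[T].to_numpy(dtype=float)
    n = len(y)
    keys = [tuple(row) for row in trials.frame[names].to_numpy()]

    rng = np.random.default_rng(seed)
    fold_id = np.empty(n, dtype=int)
    fold_id[rng.permutation(n)] = np.arange(n) % folds

    sse = 0.0
    grand_mean = float(y.mean())
    for f in range(folds):
        train = fold_id != f
        y_tr = y[train]
        mean_tr = float(y_tr.mean())
        sums: dict[tuple, float] = {}
        counts: dict[tuple, int] = {}
        for k, v in zip([keys[i] for i in np.flatnonzero(train)], y_tr):
            sums[k] = sums.get(k, 0.0) + v
            counts[k] = counts.get(k, 0) + 1
        for i in np.flatnonzero(~train):
            k = keys[i]
            if k in counts:
                pred = (sums[k] + smoothing * mean_tr) / (counts[k] + smoothing)
            else:
                pred = mean_tr
            sse += (y[i] - pred) ** 2
    sst = float(np.sum((y - grand_mean) ** 2))
    fperf = 1.0 - sse / sst if sst > 0 else 0.0

    if len(names) < 2:
        fred = 0.0
    else:
        labels = {v: pd.factorize(trials.frame[v])[0] for v in names}
        pair_scores = [
            normalized_mutual_info_score(labels[a], labels[b])
            for a, b in itertools.combinations(names, 2)
        ]
        fred = float(np.mean(pair_scores))
    return float(fperf), fred


def identify_pomb(net: HyperNet, trials: TrialTable, T: str, folds: int = 5,
                  seed: int = 0) -> POMBResult:
    """Enumerate, score and rank candidate blankets; select the POMB.

    Candidates are, per hyperparameter node ``h``, the set
    ``{h} + parents(h) + children(h) + spouses(h)`` restricted to
    hyperparameter columns of the trial table (target and metric nodes
    dropped), plus the Markov blanket of ``T`` itself.  Each candidate is
    scored with :func:`evaluate_candidate` and the full list is ranked with
    :func:`rank_markov_blankets`; the top entry is the POMB.
    """
    net._require(T)
    hyper_cols = set(trials.hyperparameters)
    candidate_sets: dict[frozenset, str] = {}

    mb_t = markov_blanket(net, T) & hyper_cols
    if mb_t:
        candidate_sets[frozenset(mb_t)] = "algorithm2"

    for h in sorted(set(net.graph.nodes) & hyper_cols):
        if h == T:
            continue
        pc = net.parents(h) | net.children(h)
        spouses = set()
        for c in net.children(h):
            spouses |= net.parents(c)
        cand = ({h} | pc | spouses) & hyper_cols - {T}
        if cand:
            candidate_sets.setdefault(frozenset(cand), "algorithm2")

    if not candidate_sets:
        warnings.warn(f"no candidate blankets found for target {T!r}",
                      RuntimeWarning, stacklevel=2)
        return POMBResult(entries=[], pomb=None)

    cands = []
    for vars_, prov in sorted(candidate_sets.items(), key=lambda kv: sorted(kv[0])):
        fperf, fred = evaluate_candidate(vars_, trials, T, folds=folds, seed=seed)
        cands.append(MBCandidate(variables=vars_, fperf=fperf, fred=fred,
                                 provenance=prov))
    entries = rank_markov_blankets(cands)
    return POMBResult(entries=entries, pomb=entries[0].candidate)


# --------------------------------------------------------------------------
# CPTs and faithfulness diagnostics
# --------------------------------------------------------------------------

def fit_cpts(net: HyperNet, trials: TrialTable, n_bins: int = 3,
             alpha: float = 1.0) -> dict:
    """Estimate P(node | parents) tables from trials by Laplace-smoothed
    counting; continuous columns are discretized into quantile bins.

    Returns the table map and attaches it to ``net.cpts``.
    """
    frame = trials.frame
    disc: dict[str, np.ndarray] = {}
    for col in trials.schema:
        vals = frame[col]
        if col in trials.metrics:
            disc[col] = pd.qcut(vals, q=n_bins, labels=False, duplicates="drop")
        else:
            disc[col] = pd.factorize(vals)[0]
    cpts: dict = {}
    for node in net.graph.nodes:
        if node not in disc:
            continue
        parents = sorted(p for p in net.parents(node) if p in disc)
        states = sorted(set(int(v) for v in np.asarray(disc[node])))
        table: dict = {}
        if parents:
            parent_keys = [tuple(int(disc[p][i]) for p in parents)
                           for i in range(len(frame))]
        else:
            parent_keys = [() for _ in range(len(frame))]
        node_vals = np.asarray(disc[node], dtype=int)
        for key in sorted(set(parent_keys)):
            idx = [i for i, k in enumerate(parent_keys) if k == key]
            counts = {s: alpha for s in states}
            for i in idx:
                counts[int(node_vals[i])] += 1
            total = sum(counts.values())
            table[key] = {s: c / total for s, c in counts.items()}
        cpts[node] = table
    net.cpts = cpts
    return cpts


def check_faithfulness(net: HyperNet, trials: TrialTable, alpha: float = 0.01,
                       max_cond: int = 1) -> list[dict]:
    """Diagnostic only: compare graph separations with chi-squared
    conditional-independence tests on the trial data and warn on
    disagreement.  Returns the list of disagreement records."""
    from scipy.stats import chi2_contingency

    cols = [c for c in trials.hyperparameters if c in net.graph.nodes]
    labels = {c: pd.factorize(trials.frame[c])[0] for c in cols}

    def ci_pvalue(x, y, S) -> float:
        strata: dict[tuple, list[int]] = {}
        for i in range(len(labels[x])):
            strata.setdefault(tuple(labels[s][i] for s in S), []).append(i)
        pvals = []
        for idx in strata.values():
            tab = pd.crosstab(labels[x][idx], labels[y][idx])
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                continue
            pvals.append(chi2_contingency(tab.to_numpy())[1])
        if not pvals:
            return 1.0
        return min(1.0, min(pvals) * len(pvals))   # Bonferroni across strata

    disagreements = []
    for x, y in itertools.combinations(cols, 2):
        rest = [c for c in cols if c not in (x, y)]
        for size in range(min(max_cond, len(rest)) + 1):
            for S in itertools.combinations(rest, size):
                sep = d_separated(net, x, y, S)
                p = ci_pvalue(x, y, S)
                dependent = p < alpha
                if sep == dependent:   # graph says independent but data says not
                    disagreements.append(
                        {"x": x, "y": y, "given": S, "graph_separated": sep,
                         "p_value": p})
    if disagreements:
        warnings.warn(
            f"{len(disagreements)} graph/data independence disagreement(s); "
            "the faithfulness assumption may not hold",
            RuntimeWarning, stacklevel=2)
    return disagreements
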