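"""Independent brute-force oracles used to validate the implementation.

These deliberately re-derive results from first principles (path
enumeration, all-pairs dominance, straight formula transcription) and share
no code with the package internals they check.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


# ---- d-separation by exhaustive path enumeration --------------------------

def enumerate_paths(g: nx.DiGraph, x, y) -> list[list]:
    """All simple undirected paths between x and y."""
    return [list(p) for p in nx.all_simple_paths(g.to_undirected(as_view=True), x, y)]


def path_blocked(g: nx.DiGraph, path: list, S: set,
                 descendants: dict | None = None) -> bool:
    """Apply the three blocking rules to one path."""
    if descendants is None:
        descendants = {n: nx.descendants(g, n) for n in g.nodes}
    for i in range(1, len(path) - 1):
        prev, mid, nxt = path[i - 1], path[i], path[i + 1]
        collider = g.has_edge(prev, mid) and g.has_edge(nxt, mid)
        if collider:
            if mid not in S and not (descendants[mid] & S):
                return True
        else:
            if mid in S:
                return True
    return False


def dsep_bruteforce(g: nx.DiGraph, x, y, S,
                    paths: list | None = None,
                    descendants: dict | None = None) -> bool:
    S = set(S)
    if descendants is None:
        descendants = {n: nx.descendants(g, n) for n in g.nodes}
    if paths is None:
        paths = enumerate_paths(g, x, y)
    return all(path_blocked(g, p, S, descendants) for p in paths)


def random_dag(rng: np.random.Generator, n_nodes: int, edge_p: float = 0.3) -> nx.DiGraph:
    """Random DAG: edges only from earlier to later in a shuffled order."""
    names = [f"n{i}" for i in range(n_nodes)]
    order = [names[i] for i in rng.permutation(n_nodes)]
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.uniform() < edge_p:
            g.add_edge(order[i], order[j])
    return g


def blanket_bruteforce(g: nx.DiGraph, t) -> frozenset:
    parents = set(g.predecessors(t))
    children = set(g.successors(t))
    spouses = set()
    for c in children:
        spouses |= set(g.predecessors(c))
    return frozenset((parents | children | spouses) - {t})


# ---- Pareto machinery ------------------------------------------------------

def pareto_front_bruteforce(scores: list[tuple[float, float]]) -> list[int]:
    """Indices of non-dominated (fperf max, fred min) score pairs."""

    def dominates(a, b):
        return (a[0] >= b[0] and a[1] <= b[1]
                and (a[0] > b[0] or a[1] < b[1]))

    return [i for i, s in enumerate(scores)
            if not any(dominates(o, s) for j, o in enumerate(scores) if j != i)]


def rank_bruteforce(scores, names, front_idx, degrees, crowding):
    """Three-key sort re-derived independently: front first, then degree
    desc, crowding desc, lexicographic names."""
    front = set(front_idx)
    return sorted(range(len(scores)),
                  key=lambda i: (i not in front, -degrees[i], -crowding[i],
                                 names[i]))


# ---- metrics ---------------------------------------------------------------

def ssim_global_formula(x: np.ndarray, y: np.ndarray, C1: float, C2: float,
                        C3: float) -> float:
    """Straight transcription of the luminance/contrast/structure product on
    global statistics."""
    mx, my = x.mean(), y.mean()
    sx, sy = x.std(), y.std()
    sxy = ((x - mx) * (y - my)).mean()
    l = (2 * mx * my + C1) / (mx ** 2 + my ** 2 + C1)
    c = (2 * sx * sy + C2) / (sx ** 2 + sy ** 2 + C2)
    s = (sxy + C3) / (sx * sy + C3)
    return float(l * c * s)


def dft_amp_phase(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """O(N^2) direct DFT, amplitude and phase per bin."""
    m, n = img.shape
    F = np.zeros((m, n), dtype=complex)
    for u in range(m):
        for v in range(n):
            acc = 0.0 + 0.0j
            for i in range(m):
                for j in range(n):
                    acc += img[i, j] * np.exp(-2j * np.pi * (u * i / m + v * j / n))
            F[u, v] = acc
    return np.abs(F), np.angle(F)
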