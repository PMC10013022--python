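"""Independent brute-force oracles, deliberately kept naive and separate
from the implementations they check."""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np


def brute_visibility_edges(t, y, collinear_blocks: bool = True) -> set[tuple[int, int]]:
    """All-pairs / all-intermediates visibility check in the division form.

    Edge (i, j) iff every intermediate sample lies strictly below (or, when
    collinear is admissible, not above) the chord from i to j.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            slope = (y[j] - y[i]) / (t[j] - t[i])
            ok = True
            for r in range(i + 1, j):
                line = y[i] + slope * (t[r] - t[i])
                if (y[r] >= line) if collinear_blocks else (y[r] > line):
                    ok = False
                    break
            if ok:
                edges.add((i, j))
    return edges


def exhaustive_cliques(g: nx.Graph) -> list[frozenset]:
    """Every clique of g (all complete node subsets), by subset DP on bitmasks.

    A nonempty subset S is a clique iff S minus its lowest node is a clique
    and that node is adjacent to all the rest.  Enumerates all 2^n subsets,
    so only usable for small n.
    """
    nodes = sorted(g.nodes())
    n = len(nodes)
    adj = [0] * n
    idx = {v: i for i, v in enumerate(nodes)}
    for u, v in g.edges():
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    is_clique = [False] * (1 << n)
    cliques: list[int] = []
    for mask in range(1, 1 << n):
        low = (mask & -mask).bit_length() - 1
        rest = mask & (mask - 1)
        if rest == 0:
            ok = True
        else:
            ok = is_clique[rest] and (adj[low] & rest) == rest
        is_clique[mask] = ok
        if ok:
            cliques.append(mask)
    out = []
    for mask in cliques:
        out.append(frozenset(nodes[i] for i in range(n) if mask >> i & 1))
    return out


def exhaustive_maximal_cliques(g: nx.Graph) -> set[frozenset]:
    """Maximal cliques from the exhaustive enumeration."""
    cliques = exhaustive_cliques(g)
    clique_set = set(cliques)
    nodes = set(g.nodes())
    maximal = set()
    for c in cliques:
        if not any((c | {v}) in clique_set for v in nodes - c):
            maximal.add(c)
    return maximal


def exhaustive_f_vector(g: nx.Graph, convention: str = "all_faces") -> tuple[int, ...]:
    """f-vector from exhaustive subset enumeration."""
    faces = (
        exhaustive_cliques(g)
        if convention == "all_faces"
        else exhaustive_maximal_cliques(g)
    )
    q_max = max(len(c) for c in faces) - 1
    counts = [0] * (q_max + 1)
    for c in faces:
        counts[len(c) - 1] += 1
    return tuple(counts)


def bron_kerbosch_no_pivot(g: nx.Graph) -> set[frozenset]:
    """Plain Bron-Kerbosch recursion, no pivoting, no vertex ordering."""
    adj = {v: set(g[v]) for v in g.nodes()}
    out: set[frozenset] = set()

    def rec(r: set, p: set, x: set) -> None:
        if not p and not x:
            out.add(frozenset(r))
            return
        for v in list(p):
            rec(r | {v}, p & adj[v], x & adj[v])
            p.remove(v)
            x.add(v)

    rec(set(), set(adj), set())
    return out


def distances_by_matrix_powering(g: nx.Graph) -> np.ndarray:
    """All-pairs hop distances via boolean powers of the adjacency matrix."""
    nodes = sorted(g.nodes())
    n = len(nodes)
    a = nx.to_numpy_array(g, nodelist=nodes) > 0
    dist = np.full((n, n), -1, dtype=int)
    np.fill_diagonal(dist, 0)
    reach = np.eye(n, dtype=bool)
    power = np.eye(n, dtype=bool)
    for k in range(1, n):
        power = power @ a
        newly = power & ~reach
        dist[newly] = k
        reach |= newly
        if reach.all():
            break
    return dist
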