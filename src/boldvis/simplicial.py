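"""Maximal-clique enumeration and the f-vector of the clique complex.

A clique of ``k+1`` nodes is viewed as a ``k``-dimensional simplex; the set
of all cliques of a graph is its clique complex.  The f-vector
``(f_0, f_1, ..., f_qmax)`` counts the simplices of each dimension ``q`` and
``q_max`` is the dimension of the largest simplex present.  For a visibility
graph of a time series, nodes are temporal labels, so high ``q_max`` signals
high-order short-term temporal correlation in the series.

Two counting conventions are supported and both are always emitted by the
pipeline:

``all_faces``
    the classical f-vector of the clique complex: ``f_q`` counts every
    clique of ``q+1`` nodes (so ``f_0 = n`` and ``f_1 = |E|``);
``maximal_only``
    ``f_q`` counts only the MAXIMAL cliques of ``q+1`` nodes (entries sum to
    the number of maximal cliques).

``q_max`` is identical under both conventions.

Maximal cliques are enumerated with the Bron-Kerbosch algorithm using a
degeneracy-ordering outer loop and pivoting, the worst-case-optimal variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx

__all__ = [
    "FVector",
    "maximal_cliques",
    "f_vector",
    "euler_characteristic",
    "qmax",
    "write_fvector",
    "read_fvector",
]

Convention = Literal["all_faces", "maximal_only"]


@dataclass(frozen=True)
class FVector:
    """Simplex counts per dimension, ``counts[q] = f_q`` for ``q = 0..q_max``."""

    counts: tuple[int, ...]
    convention: Convention = "all_faces"

    def __post_init__(self):
        counts = tuple(int(c) for c in self.counts)
        if not counts:
            raise ValueError("f-vector must have at least one entry")
        if any(c < 0 for c in counts):
            raise ValueError("f-vector entries must be nonnegative")
        if counts[-1] == 0:
            raise ValueError("last f-vector entry must be positive (defines q_max)")
        if self.convention not in ("all_faces", "maximal_only"):
            raise ValueError(f"unknown convention {self.convention!r}")
        object.__setattr__(self, "counts", counts)

    @property
    def q_max(self) -> int:
        return len(self.counts) - 1

    def __getitem__(self, q: int) -> int:
        return self.counts[q]

    def __len__(self) -> int:
        return len(self.counts)


# ---------------------------------------------------------------------------
# Bron-Kerbosch
# ---------------------------------------------------------------------------


def _degeneracy_order(adj: dict[int, set[int]]) -> list[int]:
    """Node order by repeated minimum-degree removal (degeneracy ordering)."""
    degrees = {v: len(nbrs) for v, nbrs in adj.items()}
    buckets: dict[int, set[int]] = {}
    for v, d in degrees.items():
        buckets.setdefault(d, set()).add(v)
    order: list[int] = []
    removed: set[int] = set()
    n = len(adj)
    while len(order) < n:
        d = min(k for k, b in buckets.items() if b)
        # deterministic tie-break for reproducible clique ordering
        v = min(buckets[d])
        buckets[d].remove(v)
        order.append(v)
        removed.add(v)
        for u in adj[v]:
            if u in removed:
                continue
            du = degrees[u]
            buckets[du].remove(u)
            degrees[u] = du - 1
            buckets.setdefault(du - 1, set()).add(u)
    return order


def _bron_kerbosch_pivot(
    adj: dict[int, set[int]],
    r: set[int],
    p: set[int],
    x: set[int],
    out: list[frozenset[int]],
) -> None:
    if not p and not x:
        out.append(frozenset(r))
        return
    # pivot on the vertex of P|X with the most neighbours in P
    pivot = max(p | x, key=lambda u: len(p & adj[u]))
    for v in list(p - adj[pivot]):
        _bron_kerbosch_pivot(adj, r | {v}, p & adj[v], x & adj[v], out)
        p.remove(v)
        x.add(v)


def maximal_cliques(g: nx.Graph) -> list[tuple[int, ...]]:
    """All maximal cliques of ``g``, each exactly once.

    Returns sorted node tuples, canonically ordered by size then
    lexicographically, so output is reproducible across runs.
    """
    adj = {v: set(g[v]) for v in g.nodes()}
    if not adj:
        return []
    order = _degeneracy_order(adj)
    pos = {v: i for i, v in enumerate(order)}
    out: list[frozenset[int]] = []
    for v in order:
        later = {u for u in adj[v] if pos[u] > pos[v]}
        earlier = {u for u in adj[v] if pos[u] < pos[v]}
        _bron_kerbosch_pivot(adj, {v}, later, earlier, out)
    cliques = [tuple(sorted(c)) for c in out]
    cliques.sort(key=lambda c: (len(c), c))
    return cliques


# ---------------------------------------------------------------------------
# f-vectors
# ---------------------------------------------------------------------------


def f_vector(g: nx.Graph, convention: Convention = "all_faces") -> FVector:
    """f-vector of the clique complex of ``g``.

    ``all_faces`` counts are obtained by expanding every maximal clique into
    all of its nonempty subsets with deduplication, which reuses the
    Bron-Kerbosch enumerator.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("f-vector of the empty graph is undefined")
    maximal = maximal_cliques(g)
    q_max = max(len(c) for c in maximal) - 1
    counts = [0] * (q_max + 1)
    if convention == "maximal_only":
        for c in maximal:
            counts[len(c) - 1] += 1
    elif convention == "all_faces":
        faces: set[frozenset[int]] = set()
        for c in maximal:
            for k in range(1, len(c) + 1):
                faces.update(frozenset(s) for s in combinations(c, k))
        for f in faces:
            counts[len(f) - 1] += 1
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return FVector(tuple(counts), convention=convention)


def euler_characteristic(f: FVector) -> int:
    """Alternating sum ``sum_q (-1)^q f_q`` (all_faces convention only)."""
    if f.convention != "all_faces":
        raise ValueError("Euler characteristic requires the all_faces convention")
    return sum((-1) ** q * c for q, c in enumerate(f.counts))


def qmax(f: FVector) -> int:
    """Dimension of the highest-dimensional simplex, ``len(counts) - 1``."""
    return f.q_max


# ---------------------------------------------------------------------------
# I/O: two-column CSV (q, count) with a machine-readable summary trailer.
# ---------------------------------------------------------------------------


def write_fvector(f: FVector, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("q,count\n")
        for q, c in enumerate(f.counts):
            fh.write(f"{q},{c}\n")
        fh.write(f"# q_max={f.q_max}\n")
        fh.write(f"# convention={f.convention}\n")


def read_fvector(path: str | Path) -> FVector:
    path = Path(path)
    counts: list[int] = []
    convention = "all_faces"
    with path.open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line == "q,count":
                continue
            if line.startswith("#"):
                if "convention=" in line:
                    convention = line.split("convention=")[1].strip()
                continue
            q_str, c_str = line.split(",")
            q = int(q_str)
            if q != len(counts):
                raise ValueError(f"{path}: non-contiguous q values")
            counts.append(int(c_str))
    return FVector(tuple(counts), convention=convention)  # type: ignore[arg-type]
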