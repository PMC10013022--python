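"""Natural visibility graph construction.

Two samples ``(t_i, y_i)`` and ``(t_j, y_j)`` of a time series are linked
iff the straight line between them clears every intermediate sample: for all
``r`` with ``i < r < j``,

    y_r < y_i + (y_j - y_i) * (t_r - t_i) / (t_j - t_i).

Equivalently, the slope from ``i`` to every intermediate ``r`` is smaller
than the slope from ``i`` to ``j``.  The comparison is evaluated in the
cross-multiplied form (no division), so exact for integer/rational inputs
and tolerance-free for floats.

By default an intermediate point exactly on the line BLOCKS visibility
(strict inequality), the convention of the visibility-algorithm literature;
``collinear_blocks=False`` switches to the at-or-below (non-strict) reading,
under which a straight ramp becomes a complete graph.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .series import TimeSeries

__all__ = [
    "visibility_graph",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "read_graphml",
]


def visibility_graph(ts: TimeSeries, collinear_blocks: bool = True) -> nx.Graph:
    """Build the natural visibility graph of a time series.

    Nodes are the 0-based time indices; every consecutive pair ``(i, i+1)``
    is an edge (the intermediate condition is vacuous), so the graph is
    connected and contains the Hamiltonian path ``0-1-...-(n-1)``.

    The sweep from each anchor ``i`` keeps the running maximum slope to any
    intermediate point; ``j`` is visible from ``i`` iff the slope ``i -> j``
    exceeds that maximum (ties block when ``collinear_blocks``).  O(n^2)
    overall, ample for series of a few hundred samples.
    """
    n = len(ts)
    if n < 2:
        raise ValueError(f"need at least 2 samples to build a graph, got {n}")
    t = np.asarray(ts.times, dtype=float)
    y = np.asarray(ts.values, dtype=float)

    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n - 1):
        g.add_edge(i, i + 1)
        # running max slope from i over intermediates, kept as a (dy, dt)
        # pair and compared by cross-multiplication
        best_dy = y[i + 1] - y[i]
        best_dt = t[i + 1] - t[i]
        for j in range(i + 2, n):
            dy = y[j] - y[i]
            dt = t[j] - t[i]
            # slope(i,j) vs max slope(i,r): dy/dt <> best_dy/best_dt
            lhs = dy * best_dt
            rhs = best_dy * dt
            visible = lhs > rhs if collinear_blocks else lhs >= rhs
            if visible:
                g.add_edge(i, j)
            if lhs > rhs:
                best_dy, best_dt = dy, dt
    return g


# ---------------------------------------------------------------------------
# Graph I/O: whitespace edge list with an explicit node-count header (so
# isolated nodes survive a round trip), plus GraphML for interoperability.
# ---------------------------------------------------------------------------


def write_edgelist(g: nx.Graph, path: str | Path) -> None:
    """Write ``g`` as a two-column whitespace edge list with a ``# n_nodes=N`` header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# n_nodes={g.number_of_nodes()}\n")
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u} {v}\n")


def read_edgelist(path: str | Path) -> nx.Graph:
    """Read an edge list written by :func:`write_edgelist`."""
    path = Path(path)
    g = nx.Graph()
    n_nodes = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "n_nodes=" in line:
                    n_nodes = int(line.split("n_nodes=")[1].split()[0])
                continue
            toks = line.split()
            if len(toks) != 2:
                raise ValueError(f"{path}:{lineno}: expected two node ids, got {line!r}")
            g.add_edge(int(toks[0]), int(toks[1]))
    if n_nodes is None:
        raise ValueError(f"{path}: missing '# n_nodes=N' header")
    g.add_nodes_from(range(n_nodes))
    return g


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path), node_type=int)
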