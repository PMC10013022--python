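"""Classical network characterisers: degree, clustering, path length, diameter.

Conventions (fixed because the literature varies):

* the local clustering coefficient of a node with degree < 2 is defined as 0
  and INCLUDED in the mean;
* the average shortest path length is the mean hop distance over unordered
  distinct node pairs (equivalently the ordered-pair mean, by symmetry).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx

__all__ = ["NetworkSummary", "network_summary"]


@dataclass(frozen=True)
class NetworkSummary:
    """One row of summary statistics for a connected graph."""

    d_avg: float  #: mean node degree, 2|E|/n
    c_avg: float  #: mean local clustering coefficient
    l_avg: float  #: mean shortest-path length over unordered pairs
    diameter: int  #: maximum shortest-path length in hops

    def as_dict(self) -> dict:
        return asdict(self)


def network_summary(g: nx.Graph) -> NetworkSummary:
    """Compute the summary for a connected graph with >= 2 nodes.

    Visibility graphs are always connected (consecutive samples are linked),
    so for pipeline graphs the connectivity check is a safety net; arbitrary
    user graphs with several components are rejected explicitly.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError(f"need at least 2 nodes, got {n}")
    if not nx.is_connected(g):
        k = nx.number_connected_components(g)
        raise ValueError(
            f"graph is disconnected ({k} components); path statistics undefined"
        )
    d_avg = 2.0 * g.number_of_edges() / n
    c_avg = nx.average_clustering(g, count_zeros=True)
    l_avg = nx.average_shortest_path_length(g)
    diameter = nx.diameter(g)
    return NetworkSummary(d_avg=d_avg, c_avg=c_avg, l_avg=l_avg, diameter=int(diameter))
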