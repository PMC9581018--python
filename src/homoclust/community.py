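"""Sequential, deterministic Louvain community detection.

Communities in the similarity graph are homologous sub-clusters.  Louvain
greedily maximizes weighted modularity

    Q = sum_c [ w_in(c)/m  -  (d(c) / (2 m))^2 ]

where ``m`` is the total edge weight, ``w_in(c)`` the weight of edges inside
community ``c`` and ``d(c)`` the sum of weighted degrees of its members:
the fraction of edge weight inside communities minus the fraction expected
if edges were rewired at random preserving degrees.

The implementation is the classic two-phase scheme.  Phase 1 sweeps the
vertices in ascending input order and moves each vertex to the neighboring
community with the largest strictly positive modularity gain (ties: the
vertex stays put; among distinct better communities the smallest community
index wins).  Phase 2 aggregates each community into a meta-vertex and the
two phases repeat on the condensed graph.  The process stops when a full
level improves Q by less than ``gain_threshold`` (default 1e-6).  Every
choice is deterministic, so the same graph always yields the same partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO

from .simgraph import SimGraph

__all__ = ["Partition", "modularity", "louvain", "DEFAULT_GAIN_THRESHOLD"]

DEFAULT_GAIN_THRESHOLD = 1e-6


@dataclass
class Partition:
    """Assignment of every graph vertex to a 0-based contiguous community index."""

    community_of: dict[str, int]

    def __post_init__(self) -> None:
        idx = set(self.community_of.values())
        if idx and idx != set(range(len(idx))):
            raise ValueError("community indices must be contiguous from 0")

    @property
    def n_communities(self) -> int:
        return len(set(self.community_of.values()))

    def communities(self) -> list[list[str]]:
        """Members per community, insertion-ordered within each community."""
        out: list[list[str]] = [[] for _ in range(self.n_communities)]
        for v, c in self.community_of.items():
            out[c].append(v)
        return out

    def write_tsv(self, stream: IO[str] | str | Path) -> None:
        if isinstance(stream, (str, Path)):
            with open(stream, "w") as fh:
                self.write_tsv(fh)
            return
        stream.write("seq_id\tcommunity\n")
        for v, c in self.community_of.items():
            stream.write(f"{v}\t{c}\n")


def modularity(graph: SimGraph, partition: Partition) -> float:
    """Weighted modularity Q of a partition (see module docstring).

    Undefined (raises) for an edgeless graph.
    """
    if set(partition.community_of) != set(graph.vertices):
        raise ValueError("partition does not cover exactly the graph's vertices")
    if graph.n_edges == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    m = sum(graph.edges.values())
    n_comm = partition.n_communities
    w_in = [0.0] * n_comm
    d = [0.0] * n_comm
    for (u, v), w in graph.edges.items():
        cu, cv = partition.community_of[u], partition.community_of[v]
        d[cu] += w
        d[cv] += w
        if cu == cv:
            w_in[cu] += w
    return sum(
        w_in[c] / m - (d[c] / (2.0 * m)) ** 2 for c in range(n_comm)
    )


def _singleton_partition(graph: SimGraph) -> Partition:
    return Partition({v: i for i, v in enumerate(graph.vertices)})


def _phase1(
    adj: list[dict[int, float]], deg: list[float], m: float
) -> list[int]:
    """One level of local moves; returns community label per node (non-contiguous)."""
    n = len(adj)
    comm = list(range(n))
    comm_tot = deg.copy()
    moved = True
    while moved:
        moved = False
        for u in range(n):
            cu = comm[u]
            links: dict[int, float] = {}
            for v, w in adj[u].items():
                if v != u:
                    links[comm[v]] = links.get(comm[v], 0.0) + w
            comm_tot[cu] -= deg[u]
            # gain of (re)insertion into community c, up to a constant:
            #   k_{u,c} - tot(c) * k_u / (2m)
            best_c = cu
            best_gain = links.get(cu, 0.0) - comm_tot[cu] * deg[u] / (2.0 * m)
            for c in sorted(links):
                if c == cu:
                    continue
                gain = links[c] - comm_tot[c] * deg[u] / (2.0 * m)
                if gain > best_gain:
                    best_gain = gain
                    best_c = c
            comm_tot[best_c] += deg[u]
            if best_c != cu:
                comm[u] = best_c
                moved = True
    return comm


def _renumber(comm: list[int]) -> tuple[list[int], int]:
    """Relabel communities contiguously in order of first appearance."""
    mapping: dict[int, int] = {}
    out = []
    for c in comm:
        if c not in mapping:
            mapping[c] = len(mapping)
        out.append(mapping[c])
    return out, len(mapping)


def louvain(
    graph: SimGraph, gain_threshold: float = DEFAULT_GAIN_THRESHOLD
) -> Partition:
    """Louvain modularity optimization; deterministic for a fixed graph.

    An edgeless graph returns the all-singleton partition.  For any graph
    with edges, Q(result) >= Q(singleton partition).
    """
    if gain_threshold <= 0:
        raise ValueError("gain_threshold must be positive")
    if graph.n_edges == 0:
        return _singleton_partition(graph)

    index_of = {v: i for i, v in enumerate(graph.vertices)}
    n = graph.n_vertices
    # adjacency with self-loop entries adj[u][u] holding intra weight once;
    # degrees count self-loops twice
    adj: list[dict[int, float]] = [dict() for _ in range(n)]
    for (a, b), w in graph.edges.items():
        u, v = index_of[a], index_of[b]
        adj[u][v] = adj[u].get(v, 0.0) + w
        adj[v][u] = adj[v].get(u, 0.0) + w
    m = sum(graph.edges.values())

    node_of = list(range(n))  # original vertex -> current meta-node
    q_prev = modularity(graph, _singleton_partition(graph))

    while True:
        deg = [
            sum(w for v, w in adj[u].items() if v != u)
            + 2.0 * adj[u].get(u, 0.0)
            for u in range(len(adj))
        ]
        comm = _phase1(adj, deg, m)
        comm, n_comm = _renumber(comm)

        flat = [comm[node_of[i]] for i in range(n)]
        partition = Partition(
            {v: flat[i] for i, v in enumerate(graph.vertices)}
        )
        q_new = modularity(graph, partition)
        assert q_new >= q_prev - 1e-12, "modularity must not decrease"
        if q_new - q_prev < gain_threshold or n_comm == len(adj):
            # contiguous renumber by first appearance over input vertex order
            final, _ = _renumber(flat)
            return Partition(
                {v: final[i] for i, v in enumerate(graph.vertices)}
            )
        q_prev = q_new

        # phase 2: aggregate communities into a condensed graph
        new_adj: list[dict[int, float]] = [dict() for _ in range(n_comm)]
        for u in range(len(adj)):
            cu = comm[u]
            for v, w in adj[u].items():
                cv = comm[v]
                if u == v:
                    # existing self-loop, already stored once
                    new_adj[cu][cu] = new_adj[cu].get(cu, 0.0) + w
                elif u < v:
                    if cu == cv:
                        new_adj[cu][cu] = new_adj[cu].get(cu, 0.0) + w
                    else:
                        new_adj[cu][cv] = new_adj[cu].get(cv, 0.0) + w
                        new_adj[cv][cu] = new_adj[cv].get(cu, 0.0) + w
        adj = new_adj
        node_of = [comm[c] for c in node_of]
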