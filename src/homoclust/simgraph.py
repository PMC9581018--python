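"""Sequence similarity graph construction.

Vertices are sequences; an undirected edge joins two sequences whose
aligned-region length ratio (``len_ratio``) is strictly greater than the
threshold, and carries that ratio as its weight.  The default threshold is
0.80, which keeps only pairs whose semi-global alignment covers more than
80% of the longer sequence — a stringent overlap requirement that keeps
edges between genuinely homologous, near-full-length matches.

``len_ratio`` alone weights the edges.  A secondary identity gate is applied
as well: an edge also requires ``match_ratio >= min_match_ratio`` (default
0.40 — the classic floor below which sequence similarity stops being
reliable evidence of homology).  The gate is needed because free-end-gap
alignment with affine 11/1 penalties lets unrelated sequences of similar
length reach full-span, gap-riddled alignments whose coverage exceeds 80%
by chance; such alignments have near-random identity and are rejected by
the gate, while genuinely homologous pairs sit far above it.  Set
``min_match_ratio=0`` to threshold on coverage alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import networkx as nx

from .pairalign import AlignStats, ScoringParams, align_stats
from .seqio import SeqRecord

__all__ = ["SimGraph", "build_graph", "DEFAULT_THRESHOLD", "DEFAULT_MIN_MATCH_RATIO"]

DEFAULT_THRESHOLD = 0.80
DEFAULT_MIN_MATCH_RATIO = 0.40


@dataclass
class SimGraph:
    """Undirected weighted similarity graph over sequence ids.

    ``vertices`` preserves input order (the order drives deterministic
    community detection); ``edges`` maps each unordered id pair, stored as a
    sorted tuple, to its weight.  Every stored weight exceeds ``threshold``.
    """

    vertices: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        vset = set(self.vertices)
        if len(vset) != len(self.vertices):
            raise ValueError("duplicate vertex ids")
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError(f"self-edge on {u!r}")
            if u not in vset or v not in vset:
                raise ValueError(f"edge ({u!r},{v!r}) references unknown vertex")
            if not w > self.threshold:
                raise ValueError(
                    f"edge ({u!r},{v!r}) weight {w} does not exceed "
                    f"threshold {self.threshold}"
                )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def add_edge(self, u: str, v: str, weight: float) -> None:
        if u == v:
            raise ValueError("self-edges are not allowed")
        key = (u, v) if u <= v else (v, u)
        self.edges[key] = weight

    def weight(self, u: str, v: str) -> float | None:
        key = (u, v) if u <= v else (v, u)
        return self.edges.get(key)

    def neighbors(self, u: str) -> list[str]:
        return [v if a == u else a for (a, v) in self.edges if u in (a, v)]

    def adjacency(self) -> dict[str, dict[str, float]]:
        adj: dict[str, dict[str, float]] = {v: {} for v in self.vertices}
        for (u, v), w in self.edges.items():
            adj[u][v] = w
            adj[v][u] = w
        return adj

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(threshold=self.threshold)
        g.add_nodes_from(self.vertices)
        g.add_weighted_edges_from((u, v, w) for (u, v), w in self.edges.items())
        return g

    def write_edgelist(self, stream: IO[str] | str | Path) -> None:
        """Write a TSV edge list: id_a, id_b, weight (6 decimals)."""
        if isinstance(stream, (str, Path)):
            with open(stream, "w") as fh:
                self.write_edgelist(fh)
            return
        stream.write("id_a\tid_b\tweight\n")
        for (u, v), w in sorted(self.edges.items()):
            stream.write(f"{u}\t{v}\t{w:.6f}\n")

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def build_graph(
    records: list[SeqRecord],
    scoring: ScoringParams | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    min_match_ratio: float = DEFAULT_MIN_MATCH_RATIO,
    stats_log: list[tuple[str, str, AlignStats]] | None = None,
) -> SimGraph:
    """Evaluate all sequence pairs and keep edges passing both gates.

    An edge requires ``len_ratio`` strictly greater than ``threshold`` and
    ``match_ratio`` of at least ``min_match_ratio``; the weight is
    ``len_ratio``.  ``records`` should already be filtered (unique residues,
    no hypothetical proteins).  If ``stats_log`` is given, every evaluated
    pair's full statistics triple is appended to it.
    """
    if len(records) < 1:
        raise ValueError("need at least one record to build a graph")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly between 0 and 1")
    if not 0 <= min_match_ratio <= 1:
        raise ValueError("min_match_ratio must lie in [0, 1]")
    scoring = scoring or ScoringParams()
    ids = [r.seq_id for r in records]
    graph = SimGraph(vertices=ids, threshold=threshold)
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            stats = align_stats(records[i], records[j], scoring)
            if stats_log is not None:
                stats_log.append((ids[i], ids[j], stats))
            if stats.len_ratio > threshold and stats.match_ratio >= min_match_ratio:
                graph.add_edge(ids[i], ids[j], stats.len_ratio)
    return graph
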