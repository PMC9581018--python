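"""k-mer distances and sequence similarity networks (SSNs).

Homology does not guarantee identical molecular function, so after a
cluster query the user can compare a handful of chosen cluster members
against the query directly.  The comparison is alignment-free: two
sequences are summarized by their k-mer (length-k substring) content and

    F(a, b) = sum_t min(count_a(t), count_b(t)) / (min(|a|, |b|) - k + 1)
    d(a, b) = 1 - F(a, b)

i.e. one minus the fraction of shared k-mers relative to the shorter
sequence's k-mer count.  d = 0 means a perfect match (identical sequences
share every k-mer); d = 1 means no k-mer in common.  The distance is
symmetric and bounded in [0, 1] but is not a metric (no triangle
inequality is claimed).

An SSN is the complete weighted graph over the query plus the selected
sequences, with k-mer distances as edge weights; the best match is the
non-query node at minimum distance from the query.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import networkx as nx
import numpy as np

from .seqio import SeqRecord

__all__ = [
    "DistMatrix",
    "SSN",
    "kmer_distance",
    "distance_matrix",
    "build_ssn",
    "DEFAULT_K",
]

DEFAULT_K = 3


def _kmer_counts(seq: str, k: int) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def kmer_distance(a: str, b: str, k: int = DEFAULT_K) -> float:
    """Fractional-common-k-mer distance in [0, 1]; 0 iff every k-mer is shared."""
    if len(a) < k or len(b) < k:
        raise ValueError(f"both sequences must be at least k={k} residues long")
    ca, cb = _kmer_counts(a, k), _kmer_counts(b, k)
    shared = sum(min(ca[t], cb[t]) for t in ca.keys() & cb.keys())
    denom = min(len(a), len(b)) - k + 1
    return 1.0 - shared / denom


@dataclass
class DistMatrix:
    """Symmetric pairwise distance matrix with a zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match the id list")
        if not np.allclose(self.d, self.d.T) or not np.allclose(
            np.diag(self.d), 0.0
        ):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.d[i, j])

    def write_phylip(self, stream: IO[str] | str | Path) -> None:
        """PHYLIP square distance matrix format (6-decimal distances)."""
        if isinstance(stream, (str, Path)):
            with open(stream, "w") as fh:
                self.write_phylip(fh)
            return
        stream.write(f"{len(self.ids)}\n")
        for i, name in enumerate(self.ids):
            row = " ".join(f"{self.d[i, j]:.6f}" for j in range(len(self.ids)))
            stream.write(f"{name} {row}\n")


def distance_matrix(records: list[SeqRecord], k: int = DEFAULT_K) -> DistMatrix:
    """All-pairs k-mer distances; requires >= 2 records, all of length >= k."""
    if len(records) < 2:
        raise ValueError("need at least two records for a distance matrix")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kmer_distance(
                records[i].residues, records[j].residues, k
            )
    return DistMatrix(ids=[r.seq_id for r in records], d=d)


@dataclass
class SSN:
    """Sequence similarity network around one query sequence.

    Node order is deterministic: the query first, then the selected records
    in input order.  ``validated`` carries per-node validation flags (the
    query itself is never validated).
    """

    node_ids: list[str]
    query_id: str
    dist: DistMatrix
    best_match: tuple[str, float]
    validated: dict[str, int] = field(default_factory=dict)

    def edge_weight(self, u: str, v: str) -> float:
        return self.dist[u, v]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(query=self.query_id)
        for nid in self.node_ids:
            g.add_node(nid, validated=int(self.validated.get(nid, 0)),
                       is_query=nid == self.query_id)
        for i, u in enumerate(self.node_ids):
            for v in self.node_ids[i + 1 :]:
                g.add_edge(u, v, weight=round(self.dist[u, v], 6))
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_edgelist(self, stream: IO[str] | str | Path) -> None:
        if isinstance(stream, (str, Path)):
            with open(stream, "w") as fh:
                self.write_edgelist(fh)
            return
        stream.write("id_a\tid_b\tdistance\n")
        for i, u in enumerate(self.node_ids):
            for v in self.node_ids[i + 1 :]:
                stream.write(f"{u}\t{v}\t{self.dist[u, v]:.6f}\n")


def build_ssn(
    query: SeqRecord,
    selected: list[SeqRecord],
    k: int = DEFAULT_K,
    validated: dict[str, int] | None = None,
) -> SSN:
    """Build the complete SSN over the query and >= 2 selected sequences.

    The best match is the selected node with minimum distance to the query
    (ties broken by input order).
    """
    if len(selected) < 2:
        raise ValueError("select at least two sequences for an SSN")
    records = [query, *selected]
    ids = [r.seq_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate node ids in SSN")
    dist = distance_matrix(records, k)
    best_idx = 1 + int(np.argmin(dist.d[0, 1:]))
    return SSN(
        node_ids=ids,
        query_id=query.seq_id,
        dist=dist,
        best_match=(ids[best_idx], float(dist.d[0, best_idx])),
        validated=dict(validated or {}),
    )
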