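"""Sub-cluster merging: from an iteration trace to final homologous clusters.

The final iteration's communities are defined over representative and
carried-over sequences.  Each such sequence stands for an entire lineage of
earlier sub-clusters and singletons; merging expands these lineages
recursively back to iteration-1 inputs:

* an original sequence expands to itself;
* a carried singleton expands to whatever it expands to in its source batch;
* a representative expands to the union of the expansions of every member
  of the sub-cluster it represents.

Each final-iteration sub-cluster therefore becomes one homologous cluster
(the union of its members' expansions).  A final-iteration *singleton* may
still expand to several sequences — it can represent a sub-cluster formed
at an intermediate iteration whose representative never clustered again;
those sequences stay together as a cluster.  Only a final singleton whose
expansion is a single original sequence remains a singleton in the result.
Exact duplicates dropped when batches were combined were recorded as merges
onto the kept sequence, so their lineages are folded into its expansion and
no sequence is lost: the clusters and singletons always partition the
iteration-1 input exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO

from .iterclust import IterationTrace, Provenance

__all__ = ["ClusterSet", "expand_member", "merge_all"]


@dataclass
class ClusterSet:
    """Final homologous clusters (>= 2 members each) plus singletons."""

    clusters: list[list[str]]
    singletons: list[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for members in self.clusters:
            if len(members) < 2:
                raise ValueError("clusters must have >= 2 members")
            for m in members:
                if m in seen:
                    raise ValueError(f"sequence {m!r} assigned twice")
                seen.add(m)
        for s in self.singletons:
            if s in seen:
                raise ValueError(f"sequence {s!r} is both clustered and singleton")
            seen.add(s)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_singletons(self) -> int:
        return len(self.singletons)

    @property
    def n_sequences(self) -> int:
        return sum(len(c) for c in self.clusters) + len(self.singletons)

    def cluster_sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def as_sets(self) -> set[frozenset[str]]:
        """Membership as a set of frozensets (clusters and singletons alike)."""
        return {frozenset(c) for c in self.clusters} | {
            frozenset([s]) for s in self.singletons
        }

    # -- persistence: one JSON line per cluster, cluster_id null = singleton

    def to_jsonl(self, stream: IO[str] | str | Path) -> None:
        if isinstance(stream, (str, Path)):
            with open(stream, "w") as fh:
                self.to_jsonl(fh)
            return
        for cid, members in enumerate(self.clusters):
            stream.write(
                json.dumps({"cluster_id": cid, "member_ids": members}) + "\n"
            )
        for s in self.singletons:
            stream.write(
                json.dumps({"cluster_id": None, "member_ids": [s]}) + "\n"
            )

    @classmethod
    def from_jsonl(cls, stream: IO[str] | str | Path) -> "ClusterSet":
        if isinstance(stream, (str, Path)):
            with open(stream) as fh:
                return cls.from_jsonl(fh)
        clusters: list[tuple[int, list[str]]] = []
        singletons: list[str] = []
        for line in stream:
            if not line.strip():
                continue
            row = json.loads(line)
            if row["cluster_id"] is None:
                singletons.extend(row["member_ids"])
            else:
                clusters.append((row["cluster_id"], row["member_ids"]))
        clusters.sort(key=lambda t: t[0])
        return cls(
            clusters=[members for _, members in clusters],
            singletons=singletons,
        )


def _expand_provenance(
    trace: IterationTrace, prov: Provenance, out: dict[str, None]
) -> None:
    if prov.kind == "original":
        out[prov.seq_id] = None
        return
    src = trace.batches.get(prov.source_batch)
    if src is None:
        raise KeyError(f"provenance references unknown batch {prov.source_batch!r}")
    if prov.kind == "singleton":
        _expand_input(trace, prov.source_batch, prov.seq_index, out)
    elif prov.kind == "representative":
        members = src.result.subclusters[prov.cluster_index]
        for m in members:
            _expand_input(trace, prov.source_batch, m, out)
    else:  # pragma: no cover - Provenance validates kind
        raise ValueError(f"unknown provenance kind {prov.kind!r}")


def _expand_input(
    trace: IterationTrace, batch_name: str, seq_index: int, out: dict[str, None]
) -> None:
    batch = trace.batches[batch_name]
    if not 0 <= seq_index < len(batch.inputs):
        raise KeyError(
            f"batch {batch_name!r} has no input sequence {seq_index}"
        )
    _expand_provenance(trace, batch.inputs[seq_index], out)
    for dup in batch.dedup_merges.get(seq_index, ()):
        _expand_provenance(trace, dup, out)


def expand_member(
    trace: IterationTrace, batch_name: str, seq_index: int
) -> list[str]:
    """All original sequence ids that one batch-input sequence stands for.

    Deterministic order: depth-first through the lineage, sub-cluster
    members in within-batch index order.
    """
    out: dict[str, None] = {}
    _expand_input(trace, batch_name, seq_index, out)
    return list(out)


def merge_all(trace: IterationTrace) -> ClusterSet:
    """Expand the final iteration's communities into the final ClusterSet."""
    if trace.final_batch not in trace.batches:
        raise ValueError("trace is incomplete: final batch missing")
    final = trace.batches[trace.final_batch]

    clusters: list[list[str]] = []
    singletons: list[str] = []
    for members in final.result.subclusters:
        out: dict[str, None] = {}
        for m in members:
            _expand_input(trace, trace.final_batch, m, out)
        clusters.append(list(out))
    for s in final.result.singletons:
        expanded = expand_member(trace, trace.final_batch, s)
        if len(expanded) >= 2:
            clusters.append(expanded)
        else:
            singletons.extend(expanded)

    result = ClusterSet(clusters=clusters, singletons=singletons)
    if result.n_sequences != trace.n_original:
        raise AssertionError(
            f"merge lost sequences: {result.n_sequences} covered of "
            f"{trace.n_original}"
        )
    return result
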