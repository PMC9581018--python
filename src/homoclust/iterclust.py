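"""Iterative batch clustering of large protein sequence sets.

Clustering millions of sequences in one pass is memory-bound, so the set is
divided into batches and clustered in iterations:

1. Each input batch is clustered independently; communities of size >= 2
   become *sub-clusters*, size-1 communities become *singletons*.
2. For the next iteration, each batch is condensed to its representatives —
   the first sequence (lowest within-batch index) of every sub-cluster —
   plus all its singletons.  A schedule groups several condensed batches
   into new, larger-coverage batches, which are clustered again.  Batch
   outputs not consumed by a grouping carry forward unchanged.
3. The final iteration clusters a single batch.  The recorded provenance of
   every intermediate sequence (which sub-cluster or singleton it came from)
   lets the merging step expand the final communities back to the original
   sequences.

Labels follow a compact grammar: batches are lettered A, B, ... (base-26
beyond Z), sequences within a batch are indexed from 0 in input order, and

* ``A_11#a_15``  — sequence 15 of batch A sits in sub-cluster 11 of batch A;
* ``Sa_1#a_1``   — sequence 1 of batch A is a singleton.

Cross-batch duplicate removal: when condensed batches are combined, exact
duplicate residue strings may be dropped (keeping the first, default on).
Each drop is recorded as a merge onto the kept sequence so that the dropped
sequence's entire lineage still lands in the kept sequence's final cluster.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Literal

import yaml

from .community import louvain
from .pairalign import ScoringParams
from .seqio import SeqRecord
from .simgraph import DEFAULT_THRESHOLD, build_graph

__all__ = [
    "Label",
    "BatchResult",
    "IterationSchedule",
    "Provenance",
    "TraceBatch",
    "IterationTrace",
    "render_label",
    "parse_label",
    "batch_letters",
    "cluster_batch",
    "representatives",
    "run_iterations",
]


# ---------------------------------------------------------------- labels


def batch_letters(batch_index: int) -> str:
    """Bijective base-26 letters for a 0-based batch index: A..Z, AA, AB, ..."""
    if batch_index < 0:
        raise ValueError("batch index must be >= 0")
    n = batch_index + 1
    out = []
    while n:
        n, r = divmod(n - 1, 26)
        out.append(chr(ord("A") + r))
    return "".join(reversed(out))


def _letters_to_index(letters: str) -> int:
    n = 0
    for ch in letters:
        n = n * 26 + (ord(ch) - ord("A") + 1)
    return n - 1


@dataclass(frozen=True)
class Label:
    """A sub-cluster membership or singleton label within one batch."""

    kind: Literal["member", "singleton"]
    batch_index: int
    seq_index: int
    cluster_index: int | None = None

    def __post_init__(self) -> None:
        if self.batch_index < 0 or self.seq_index < 0:
            raise ValueError("indices must be >= 0")
        if self.kind == "member":
            if self.cluster_index is None or self.cluster_index < 0:
                raise ValueError("member labels need a cluster index >= 0")
        elif self.kind == "singleton":
            if self.cluster_index is not None:
                raise ValueError("singleton labels carry no cluster index")
        else:
            raise ValueError(f"unknown label kind {self.kind!r}")


_MEMBER_RE = re.compile(r"^([A-Z]+)_(\d+)#([a-z]+)_(\d+)$")
_SINGLETON_RE = re.compile(r"^S([a-z]+)_(\d+)#([a-z]+)_(\d+)$")


def render_label(label: Label) -> str:
    upper = batch_letters(label.batch_index)
    lower = upper.lower()
    if label.kind == "member":
        return f"{upper}_{label.cluster_index}#{lower}_{label.seq_index}"
    return f"S{lower}_{label.seq_index}#{lower}_{label.seq_index}"


def parse_label(text: str) -> Label:
    m = _MEMBER_RE.match(text)
    if m:
        upper, cluster, lower, seq = m.groups()
        if lower != upper.lower():
            raise ValueError(f"label {text!r}: batch letters disagree")
        return Label(
            kind="member",
            batch_index=_letters_to_index(upper),
            cluster_index=int(cluster),
            seq_index=int(seq),
        )
    m = _SINGLETON_RE.match(text)
    if m:
        l1, s1, l2, s2 = m.groups()
        if l1 != l2 or s1 != s2:
            raise ValueError(f"label {text!r}: singleton halves disagree")
        return Label(
            kind="singleton",
            batch_index=_letters_to_index(l1.upper()),
            seq_index=int(s1),
        )
    raise ValueError(f"malformed label {text!r}")


# ---------------------------------------------------------- batch results


@dataclass
class BatchResult:
    """Clustering outcome of one batch.

    Sub-clusters are communities of size >= 2, ordered by community index,
    members ordered by within-batch sequence index; singletons are the
    size-1 communities' members in index order.
    """

    batch_index: int
    n_sequences: int
    subclusters: list[list[int]]
    singletons: list[int]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for sc in self.subclusters:
            if len(sc) < 2:
                raise ValueError("sub-clusters must have >= 2 members")
            seen.update(sc)
        seen.update(self.singletons)
        covered = sum(len(sc) for sc in self.subclusters) + len(self.singletons)
        if covered != self.n_sequences or seen != set(range(self.n_sequences)):
            raise ValueError("batch result does not partition the input")

    @property
    def n_subclusters(self) -> int:
        return len(self.subclusters)

    @property
    def n_singletons(self) -> int:
        return len(self.singletons)

    @property
    def n_output(self) -> int:
        """Sequences this batch contributes to the next iteration."""
        return self.n_subclusters + self.n_singletons

    def labels(self) -> list[str]:
        """Rendered label for every input sequence, in index order."""
        out = [""] * self.n_sequences
        for c, members in enumerate(self.subclusters):
            for s in members:
                out[s] = render_label(
                    Label("member", self.batch_index, s, cluster_index=c)
                )
        for s in self.singletons:
            out[s] = render_label(Label("singleton", self.batch_index, s))
        return out


def cluster_batch(
    records: list[SeqRecord],
    scoring: ScoringParams | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    batch_index: int = 0,
    gain_threshold: float = 1e-6,
) -> BatchResult:
    """Cluster one batch: similarity graph -> Louvain -> sub-clusters/singletons."""
    if not records:
        raise ValueError("cannot cluster an empty batch")
    ids = [r.seq_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate seq_ids within a batch")
    graph = build_graph(records, scoring, threshold)
    partition = louvain(graph, gain_threshold)
    members_of: dict[int, list[int]] = {}
    for idx, seq_id in enumerate(ids):
        members_of.setdefault(partition.community_of[seq_id], []).append(idx)
    subclusters = [
        sorted(m) for c, m in sorted(members_of.items()) if len(m) >= 2
    ]
    singletons = sorted(
        m[0] for m in members_of.values() if len(m) == 1
    )
    return BatchResult(
        batch_index=batch_index,
        n_sequences=len(records),
        subclusters=subclusters,
        singletons=singletons,
    )


def representatives(
    result: BatchResult, records: list[SeqRecord]
) -> list[SeqRecord]:
    """The first sequence (lowest within-batch index) of each sub-cluster."""
    if len(records) != result.n_sequences:
        raise ValueError("record list does not match the batch result")
    return [records[min(members)] for members in result.subclusters]


# ------------------------------------------------------------- schedules


@dataclass
class IterationSchedule:
    """Which batch outputs combine into which new batches, per iteration.

    ``input_batches`` names the iteration-1 batches.  Each entry of
    ``groupings`` describes one later iteration as a list of
    ``(new_batch_name, [source_batch_names])`` pairs.  Every batch output
    must be consumed by exactly one later grouping, except the final batch;
    outputs not consumed at the next iteration simply wait (they carry
    forward unchanged, like a batch skipping an iteration).  The final
    iteration must form exactly one batch.
    """

    input_batches: list[str]
    groupings: list[list[tuple[str, list[str]]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = list(self.input_batches)
        if len(set(names)) != len(names) or not names:
            raise ValueError("input batch names must be unique and non-empty")
        if not self.groupings and len(names) > 1:
            raise ValueError(
                "multiple input batches need groupings ending in one batch"
            )
        unconsumed = set(names)
        for level, groups in enumerate(self.groupings, start=2):
            if not groups:
                raise ValueError(f"iteration {level} has no batches")
            for new_name, sources in groups:
                if new_name in names:
                    raise ValueError(f"duplicate batch name {new_name!r}")
                if not sources:
                    raise ValueError(f"batch {new_name!r} has no sources")
                for src in sources:
                    if src not in unconsumed:
                        raise ValueError(
                            f"batch {new_name!r} consumes unknown or "
                            f"already-consumed batch {src!r}"
                        )
                    unconsumed.discard(src)
                names.append(new_name)
                unconsumed.add(new_name)
        if self.groupings and len(self.groupings[-1]) != 1:
            raise ValueError("the final iteration must form exactly one batch")
        final = names[-1]
        if unconsumed != {final}:
            raise ValueError(
                f"outputs never consumed by the final batch: "
                f"{sorted(unconsumed - {final})}"
            )

    @property
    def n_iterations(self) -> int:
        return 1 + len(self.groupings)

    @property
    def final_batch(self) -> str:
        if self.groupings:
            return self.groupings[-1][0][0]
        return self.input_batches[0]

    # -- config round-trip ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "input_batches": list(self.input_batches),
            "iterations": [
                [{"name": n, "sources": list(s)} for n, s in groups]
                for groups in self.groupings
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "IterationSchedule":
        return cls(
            input_batches=[str(x) for x in data["input_batches"]],
            groupings=[
                [(str(g["name"]), [str(s) for s in g["sources"]])
                 for g in groups]
                for groups in data.get("iterations", [])
            ],
        )

    @classmethod
    def from_yaml(cls, stream: IO[str] | str | Path) -> "IterationSchedule":
        if isinstance(stream, (str, Path)):
            with open(stream) as fh:
                return cls.from_yaml(fh)
        return cls.from_dict(yaml.safe_load(stream))

    def to_yaml(self, stream: IO[str] | str | Path) -> None:
        if isinstance(stream, (str, Path)):
            with open(stream, "w") as fh:
                self.to_yaml(fh)
            return
        yaml.safe_dump(self.to_dict(), stream, sort_keys=False)


def paper_schedule_example() -> IterationSchedule:
    """The 11-batch, 4-iteration schedule used for the full RefSeq build.

    Batches 1-3, 4-7 and 8-11 combine at iteration 2; only batches 123 and
    4567 combine at iteration 3 while 891011 waits; the final iteration
    clusters everything together.
    """
    return IterationSchedule(
        input_batches=[str(i) for i in range(1, 12)],
        groupings=[
            [
                ("123", ["1", "2", "3"]),
                ("4567", ["4", "5", "6", "7"]),
                ("891011", ["8", "9", "10", "11"]),
            ],
            [("1234567", ["123", "4567"])],
            [("1234567891011", ["1234567", "891011"])],
        ],
    )


# ------------------------------------------------------------- the trace


@dataclass(frozen=True)
class Provenance:
    """Where one batch-input sequence came from.

    * ``original``       — an iteration-1 input; ``seq_id`` identifies it.
    * ``representative``  — stands for sub-cluster ``cluster_index`` of
      ``source_batch`` in an earlier iteration.
    * ``singleton``       — carried over as sequence ``seq_index`` of
      ``source_batch``.
    """

    kind: Literal["original", "representative", "singleton"]
    seq_id: str | None = None
    source_batch: str | None = None
    cluster_index: int | None = None
    seq_index: int | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "Provenance":
        return cls(**d)


@dataclass
class TraceBatch:
    """One clustered batch with the provenance of each of its inputs."""

    name: str
    iteration: int
    inputs: list[Provenance]
    result: BatchResult
    #: kept input index -> provenances of exact duplicates dropped onto it
    dedup_merges: dict[int, list[Provenance]] = field(default_factory=dict)


@dataclass
class IterationTrace:
    """Full record of an iterative clustering run; input to merging."""

    batches: dict[str, TraceBatch]
    iterations: list[list[str]]
    final_batch: str
    original_ids: list[str]

    @property
    def n_original(self) -> int:
        return len(self.original_ids)

    # -- persistence: one JSON line per batch -----------------------------

    def to_jsonl(self, stream: IO[str] | str | Path) -> None:
        if isinstance(stream, (str, Path)):
            with open(stream, "w") as fh:
                self.to_jsonl(fh)
            return
        header = {
            "iterations": self.iterations,
            "final_batch": self.final_batch,
            "original_ids": self.original_ids,
        }
        stream.write(json.dumps({"trace": header}) + "\n")
        for name in (b for it in self.iterations for b in it):
            tb = self.batches[name]
            row = {
                "batch": tb.name,
                "iteration": tb.iteration,
                "inputs": [p.to_dict() for p in tb.inputs],
                "result": {
                    "batch_index": tb.result.batch_index,
                    "n_sequences": tb.result.n_sequences,
                    "subclusters": tb.result.subclusters,
                    "singletons": tb.result.singletons,
                },
                "dedup_merges": {
                    str(k): [p.to_dict() for p in v]
                    for k, v in tb.dedup_merges.items()
                },
            }
            stream.write(json.dumps(row) + "\n")

    @classmethod
    def from_jsonl(cls, stream: IO[str] | str | Path) -> "IterationTrace":
        if isinstance(stream, (str, Path)):
            with open(stream) as fh:
                return cls.from_jsonl(fh)
        lines = [json.loads(line) for line in stream if line.strip()]
        if not lines or "trace" not in lines[0]:
            raise ValueError("not an iteration trace stream")
        header = lines[0]["trace"]
        batches: dict[str, TraceBatch] = {}
        for row in lines[1:]:
            res = row["result"]
            batches[row["batch"]] = TraceBatch(
                name=row["batch"],
                iteration=row["iteration"],
                inputs=[Provenance.from_dict(d) for d in row["inputs"]],
                result=BatchResult(
                    batch_index=res["batch_index"],
                    n_sequences=res["n_sequences"],
                    subclusters=[list(sc) for sc in res["subclusters"]],
                    singletons=list(res["singletons"]),
                ),
                dedup_merges={
                    int(k): [Provenance.from_dict(d) for d in v]
                    for k, v in row["dedup_merges"].items()
                },
            )
        return cls(
            batches=batches,
            iterations=[list(it) for it in header["iterations"]],
            final_batch=header["final_batch"],
            original_ids=list(header["original_ids"]),
        )


# ---------------------------------------------------------------- driver


def run_iterations(
    batches: list[list[SeqRecord]],
    schedule: IterationSchedule,
    scoring: ScoringParams | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    cross_batch_dedup: bool = True,
    gain_threshold: float = 1e-6,
) -> IterationTrace:
    """Run the full iterative clustering scheme and record its trace.

    ``batches`` pair positionally with ``schedule.input_batches`` and must
    already be filtered; seq_ids must be unique across all batches.  When
    ``cross_batch_dedup`` is on, exact duplicate residue strings arising
    from combining batch outputs are dropped (first kept) and logged as
    merges, so no lineage is lost.
    """
    if len(batches) != len(schedule.input_batches):
        raise ValueError(
            f"schedule names {len(schedule.input_batches)} input batches, "
            f"got {len(batches)}"
        )
    all_ids = [r.seq_id for batch in batches for r in batch]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("seq_ids must be unique across input batches")
    scoring = scoring or ScoringParams()

    trace_batches: dict[str, TraceBatch] = {}
    iterations: list[list[str]] = []
    # per live batch: the records behind each input index, for carry-forward
    records_of: dict[str, list[SeqRecord]] = {}

    first_level: list[str] = []
    for bi, (name, recs) in enumerate(zip(schedule.input_batches, batches)):
        if not recs:
            raise ValueError(f"input batch {name!r} is empty")
        result = cluster_batch(
            recs, scoring, threshold, batch_index=bi,
            gain_threshold=gain_threshold,
        )
        trace_batches[name] = TraceBatch(
            name=name,
            iteration=1,
            inputs=[Provenance("original", seq_id=r.seq_id) for r in recs],
            result=result,
        )
        records_of[name] = recs
        first_level.append(name)
    iterations.append(first_level)

    for level_idx, groups in enumerate(schedule.groupings, start=2):
        level_names: list[str] = []
        for gi, (new_name, sources) in enumerate(groups):
            inputs: list[Provenance] = []
            recs: list[SeqRecord] = []
            for src in sources:
                src_result = trace_batches[src].result
                src_records = records_of[src]
                for ci, members in enumerate(src_result.subclusters):
                    inputs.append(
                        Provenance("representative", source_batch=src,
                                   cluster_index=ci)
                    )
                    recs.append(src_records[min(members)])
                for si in src_result.singletons:
                    inputs.append(
                        Provenance("singleton", source_batch=src,
                                   seq_index=si)
                    )
                    recs.append(src_records[si])
            dedup_merges: dict[int, list[Provenance]] = {}
            if cross_batch_dedup:
                kept_of: dict[str, int] = {}
                keep_inputs: list[Provenance] = []
                keep_recs: list[SeqRecord] = []
                for prov, rec in zip(inputs, recs):
                    if rec.residues in kept_of:
                        dedup_merges.setdefault(
                            kept_of[rec.residues], []
                        ).append(prov)
                    else:
                        kept_of[rec.residues] = len(keep_recs)
                        keep_inputs.append(prov)
                        keep_recs.append(rec)
                inputs, recs = keep_inputs, keep_recs
            result = cluster_batch(
                recs, scoring, threshold, batch_index=gi,
                gain_threshold=gain_threshold,
            )
            trace_batches[new_name] = TraceBatch(
                name=new_name,
                iteration=level_idx,
                inputs=inputs,
                result=result,
                dedup_merges=dedup_merges,
            )
            records_of[new_name] = recs
            level_names.append(new_name)
        iterations.append(level_names)

    return IterationTrace(
        batches=trace_batches,
        iterations=iterations,
        final_batch=schedule.final_batch,
        original_ids=all_ids,
    )
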