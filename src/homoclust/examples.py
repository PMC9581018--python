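"""Miniature worked examples of the iterative-clustering data structures.

These fixtures are small enough to verify by hand and are used in the
documentation and test-suite to pin down the merging semantics exactly.
"""

from __future__ import annotations

from .iterclust import BatchResult, IterationTrace, Provenance, TraceBatch

__all__ = ["toy_trace"]


def toy_trace() -> IterationTrace:
    """A hand-built 11-batch, 4-iteration trace exercising every merge rule.

    Iteration 1: batch 1 holds one sub-cluster {b1_s1, b1_s2}; batches 2-11
    each hold a single singleton (b2_S1 ... b11_S1).

    Iteration 2 groups the condensed batches into 123, 4567 and 891011:
    b1_s1 (representing its sub-cluster) clusters with b2_S1; b4_S1 clusters
    with b7_s1; b8_S1 clusters with b9_S1.

    Iteration 3 combines only 123 and 4567 (891011 waits): the two
    representatives b1_s1 and b4_S1 cluster together.

    Iteration 4 clusters everything: b1_s1 meets b8_S1, so the final merge
    yields a single 7-member homologous cluster
    {b1_s1, b1_s2, b2_S1, b4_S1, b7_s1, b8_S1, b9_S1} and five surviving
    singletons {b3_S1, b5_S1, b6_S1, b10_S1, b11_S1}.
    """
    batches: dict[str, TraceBatch] = {}

    batches["1"] = TraceBatch(
        name="1",
        iteration=1,
        inputs=[
            Provenance("original", seq_id="b1_s1"),
            Provenance("original", seq_id="b1_s2"),
        ],
        result=BatchResult(0, 2, subclusters=[[0, 1]], singletons=[]),
    )
    # batch 7's lone sequence is labeled b7_s1 (a sequence label rather than
    # a singleton label) to keep the example's ids exactly as documented
    for i in range(2, 12):
        batches[str(i)] = TraceBatch(
            name=str(i),
            iteration=1,
            inputs=[
                Provenance("original",
                           seq_id="b7_s1" if i == 7 else f"b{i}_S1")
            ],
            result=BatchResult(i - 1, 1, subclusters=[], singletons=[0]),
        )

    batches["123"] = TraceBatch(
        name="123",
        iteration=2,
        inputs=[
            Provenance("representative", source_batch="1", cluster_index=0),
            Provenance("singleton", source_batch="2", seq_index=0),
            Provenance("singleton", source_batch="3", seq_index=0),
        ],
        result=BatchResult(0, 3, subclusters=[[0, 1]], singletons=[2]),
    )
    batches["4567"] = TraceBatch(
        name="4567",
        iteration=2,
        inputs=[
            Provenance("singleton", source_batch=str(i), seq_index=0)
            for i in (4, 5, 6, 7)
        ],
        result=BatchResult(1, 4, subclusters=[[0, 3]], singletons=[1, 2]),
    )
    batches["891011"] = TraceBatch(
        name="891011",
        iteration=2,
        inputs=[
            Provenance("singleton", source_batch=str(i), seq_index=0)
            for i in (8, 9, 10, 11)
        ],
        result=BatchResult(2, 4, subclusters=[[0, 1]], singletons=[2, 3]),
    )

    batches["1234567"] = TraceBatch(
        name="1234567",
        iteration=3,
        inputs=[
            Provenance("representative", source_batch="123", cluster_index=0),
            Provenance("singleton", source_batch="123", seq_index=2),
            Provenance("representative", source_batch="4567", cluster_index=0),
            Provenance("singleton", source_batch="4567", seq_index=1),
            Provenance("singleton", source_batch="4567", seq_index=2),
        ],
        result=BatchResult(0, 5, subclusters=[[0, 2]], singletons=[1, 3, 4]),
    )

    batches["1234567891011"] = TraceBatch(
        name="1234567891011",
        iteration=4,
        inputs=[
            Provenance("representative", source_batch="1234567",
                       cluster_index=0),
            Provenance("singleton", source_batch="1234567", seq_index=1),
            Provenance("singleton", source_batch="1234567", seq_index=3),
            Provenance("singleton", source_batch="1234567", seq_index=4),
            Provenance("representative", source_batch="891011",
                       cluster_index=0),
            Provenance("singleton", source_batch="891011", seq_index=2),
            Provenance("singleton", source_batch="891011", seq_index=3),
        ],
        result=BatchResult(0, 7, subclusters=[[0, 4]],
                           singletons=[1, 2, 3, 5, 6]),
    )

    original_ids = ["b1_s1", "b1_s2"] + [
        "b7_s1" if i == 7 else f"b{i}_S1" for i in range(2, 12)
    ]
    return IterationTrace(
        batches=batches,
        iterations=[
            [str(i) for i in range(1, 12)],
            ["123", "4567", "891011"],
            ["1234567"],
            ["1234567891011"],
        ],
        final_batch="1234567891011",
        original_ids=original_ids,
    )
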