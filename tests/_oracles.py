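"""Independent reference implementations used only to check the package.

Everything here is deliberately brute-force: exhaustive enumeration of
alignments, of set partitions, and bottom-up transitive closure of traces.
None of it shares code with the implementation under test.
"""

from __future__ import annotations

import itertools

import networkx as nx
from networkx.algorithms.community import modularity as nx_modularity

# ---------------------------------------------------------------------------
# exhaustive semi-global alignment


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment as a list of columns (x, y), '-' = gap."""
    if not a and not b:
        yield []
        return
    if a:
        for rest in enumerate_alignments(a[1:], b):
            yield [(a[0], "-")] + rest
    if b:
        for rest in enumerate_alignments(a, b[1:]):
            yield [("-", b[0])] + rest
    if a and b:
        for rest in enumerate_alignments(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest


def _gap_runs(gapped: str):
    """(start, length) of each maximal gap run."""
    runs = []
    i = 0
    while i < len(gapped):
        if gapped[i] == "-":
            j = i
            while j < len(gapped) and gapped[j] == "-":
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def score_alignment(columns, pair_score, gap_open: int, gap_extend: int) -> int:
    """Free-end-gap affine score: a terminal gap run costs 0, an internal run
    of length L costs gap_open + L * gap_extend."""
    ga = "".join(c[0] for c in columns)
    gb = "".join(c[1] for c in columns)
    score = sum(pair_score(x, y) for x, y in columns if x != "-" and y != "-")
    n = len(columns)
    for gapped in (ga, gb):
        for start, length in _gap_runs(gapped):
            if start == 0 or start + length == n:
                continue
            score -= gap_open + length * gap_extend
    return score


def alignment_region_stats(columns) -> tuple[int, int]:
    """(aligned_region_length, n_exact_matches) of one alignment."""
    pair_cols = [
        i for i, (x, y) in enumerate(columns) if x != "-" and y != "-"
    ]
    if not pair_cols:
        return 0, 0
    region = pair_cols[-1] - pair_cols[0] + 1
    matches = sum(
        1 for x, y in columns if x != "-" and y != "-" and x == y
    )
    return region, matches


def best_alignments(a: str, b: str, pair_score, gap_open=11, gap_extend=1):
    """Max free-end-gap score and the set of (region, matches) of all optima."""
    best = None
    optima: set[tuple[int, int]] = set()
    for cols in enumerate_alignments(a, b):
        s = score_alignment(cols, pair_score, gap_open, gap_extend)
        if best is None or s > best:
            best = s
            optima = {alignment_region_stats(cols)}
        elif s == best:
            optima.add(alignment_region_stats(cols))
    return best, optima


# ---------------------------------------------------------------------------
# exhaustive modularity maximization


def set_partitions(items: list):
    """All partitions of a list into non-empty blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for p in set_partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [p[i] + [first]] + p[i + 1 :]
        yield p + [[first]]


def max_modularity(graph_nx: nx.Graph) -> float:
    """Exhaustive maximum weighted modularity over all vertex partitions."""
    best = float("-inf")
    nodes = list(graph_nx.nodes)
    for p in set_partitions(nodes):
        q = nx_modularity(graph_nx, [set(block) for block in p], weight="weight")
        best = max(best, q)
    return best


# ---------------------------------------------------------------------------
# bottom-up trace expansion (transitive closure)


def closure_expansions(trace) -> dict[tuple[str, int], set[str]]:
    """Expansion of every (batch, input index), built iteratively bottom-up."""
    out: dict[tuple[str, int], set[str]] = {}
    for level in trace.iterations:
        for name in level:
            tb = trace.batches[name]
            for idx, prov in enumerate(tb.inputs):
                if prov.kind == "original":
                    ids = {prov.seq_id}
                elif prov.kind == "singleton":
                    ids = set(out[(prov.source_batch, prov.seq_index)])
                else:  # representative
                    members = trace.batches[prov.source_batch].result.subclusters[
                        prov.cluster_index
                    ]
                    ids = set().union(
                        *(out[(prov.source_batch, m)] for m in members)
                    )
                out[(name, idx)] = ids
            for kept, dropped in tb.dedup_merges.items():
                for prov in dropped:
                    if prov.kind == "original":
                        out[(name, kept)] |= {prov.seq_id}
                    elif prov.kind == "singleton":
                        out[(name, kept)] |= out[
                            (prov.source_batch, prov.seq_index)
                        ]
                    else:
                        members = trace.batches[
                            prov.source_batch
                        ].result.subclusters[prov.cluster_index]
                        for m in members:
                            out[(name, kept)] |= out[(prov.source_batch, m)]
    return out
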