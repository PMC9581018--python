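"""Semi-global pairwise protein alignment and its three similarity statistics.

Semi-global (free-end-gap) alignment is global alignment in which gaps at
either end of either sequence cost nothing.  It is the right mode when one
sequence overlaps the end of another, or when two homologs differ strongly
in length: terminal overhangs should not be penalized, internal gaps should.

For every aligned pair, three ratio statistics are computed:

* ``len_ratio``   — length of the aligned region over the length of the
  longer sequence.  The aligned region spans the columns between the first
  and the last column that pair two residues, inclusive: terminal free-gap
  overhangs are excluded, internal gaps are included.
* ``match_ratio`` — number of exactly matching columns over the aligned
  region length.
* ``score_ratio`` — alignment score over the smaller of the two self scores
  (the score of aligning a sequence with itself, i.e. the sum of diagonal
  substitution-matrix entries).

All three equal 1.0 for identical sequences.  Downstream graph construction
thresholds and weights edges by ``len_ratio`` alone; the other two are kept
for reporting.

The dynamic-programming engine is biotite's affine-gap aligner; gap costs
here follow the BLAST convention (a gap of length L costs
``gap_open + L * gap_extend``) and are translated internally.  Traceback is
deterministic: biotite returns a fixed first-ranked alignment, so repeated
runs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import biotite.sequence as _bseq
import biotite.sequence.align as _balign

from .seqio import SeqRecord

__all__ = [
    "ScoringParams",
    "AlignResult",
    "AlignStats",
    "self_score",
    "semiglobal_align",
    "align_stats",
    "load_matrix",
]


def _blosum62() -> _balign.SubstitutionMatrix:
    return _balign.SubstitutionMatrix.std_protein_matrix()


def load_matrix(path: str | Path) -> _balign.SubstitutionMatrix:
    """Load a substitution matrix from NCBI matrix text format."""
    with open(path) as fh:
        text = fh.read()
    scores = _balign.SubstitutionMatrix.dict_from_str(text)
    alph = _bseq.ProteinSequence.alphabet
    return _balign.SubstitutionMatrix(alph, alph, scores)


@dataclass(frozen=True)
class ScoringParams:
    """Substitution matrix plus affine gap penalties (BLAST convention).

    A gap of length L costs ``gap_open + L * gap_extend``; both penalties are
    non-negative.  Defaults are the BLASTP protein defaults: BLOSUM62 with
    gap open 11, gap extend 1.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    matrix: _balign.SubstitutionMatrix | None = field(
        default=None, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.matrix is None:
            if self.matrix_name.upper() != "BLOSUM62":
                raise ValueError(
                    f"matrix {self.matrix_name!r} is not bundled; "
                    "pass an explicit matrix (see load_matrix)"
                )
            object.__setattr__(self, "matrix", _blosum62())

    # biotite charges `open` for the first gap position and `extend` for each
    # further one; shifting by gap_extend converts to the BLAST convention.
    @property
    def _biotite_gap(self) -> tuple[int, int]:
        return (-(self.gap_open + self.gap_extend), -self.gap_extend)

    def pair_score(self, x: str, y: str) -> int:
        try:
            return int(self.matrix.get_score(x, y))
        except Exception as exc:  # alphabet miss
            raise ValueError(f"residue pair ({x!r},{y!r}) absent from "
                             f"{self.matrix_name}") from exc


@dataclass(frozen=True)
class AlignResult:
    """One pairwise semi-global alignment.

    ``aligned_region_length`` counts the columns between the first and last
    column pairing two residues, inclusive; it is 0 when the optimal
    alignment pairs no residues at all (possible for very dissimilar short
    sequences, since terminal gaps are free).
    """

    aligned_a: str
    aligned_b: str
    score: int
    aligned_region_length: int
    n_exact_matches: int

    def __post_init__(self) -> None:
        assert self.n_exact_matches <= max(self.aligned_region_length, 1)


@dataclass(frozen=True)
class AlignStats:
    """The three pairwise similarity statistics (see module docstring)."""

    len_ratio: float
    match_ratio: float
    score_ratio: float


def _as_protein(seq: str) -> _bseq.ProteinSequence:
    if not seq:
        raise ValueError("empty sequence")
    try:
        return _bseq.ProteinSequence(seq)
    except Exception as exc:
        raise ValueError(f"sequence contains letters outside the protein "
                         f"alphabet: {seq[:30]!r}") from exc


def self_score(seq: str, scoring: ScoringParams | None = None) -> int:
    """Score of aligning a sequence with itself: sum of matrix diagonal entries."""
    if not seq:
        raise ValueError("empty sequence has no self score")
    scoring = scoring or ScoringParams()
    return sum(scoring.pair_score(x, x) for x in seq)


def semiglobal_align(
    a: str, b: str, scoring: ScoringParams | None = None
) -> AlignResult:
    """Optimal semi-global alignment of two residue strings.

    Terminal gaps on either sequence are free; internal gaps pay affine
    penalties.  Returns a single deterministic optimal alignment; the
    result is invariant under argument swap (up to mirroring the two
    gapped strings), because the pair is aligned in a canonical order.

    Two refinements on top of the raw aligner: the empty-overlap alignment
    (every residue against a terminal gap, score 0) is admitted, since for
    incompatible sequences it beats any forced residue pairing; and
    adjacent insert/delete gap runs never being optimal internally (two gap
    opens always cost more than one substitution), the score returned is
    the true free-end-gap optimum.
    """
    scoring = scoring or ScoringParams()
    if b < a:  # canonical order; mirror the gapped strings on return
        res = semiglobal_align(b, a, scoring)
        return AlignResult(
            aligned_a=res.aligned_b,
            aligned_b=res.aligned_a,
            score=res.score,
            aligned_region_length=res.aligned_region_length,
            n_exact_matches=res.n_exact_matches,
        )
    pa, pb = _as_protein(a), _as_protein(b)
    alignment = _balign.align_optimal(
        pa, pb, scoring.matrix,
        gap_penalty=scoring._biotite_gap,
        terminal_penalty=False,
        max_number=1,
    )[0]
    if alignment.score < 0:
        return AlignResult(
            aligned_a=a + "-" * len(b),
            aligned_b="-" * len(a) + b,
            score=0,
            aligned_region_length=0,
            n_exact_matches=0,
        )
    gapped_a, gapped_b = alignment.get_gapped_sequences()

    first = last = -1
    n_match = 0
    for i, (x, y) in enumerate(zip(gapped_a, gapped_b)):
        if x != "-" and y != "-":
            if first < 0:
                first = i
            last = i
            if x == y:
                n_match += 1
    region = (last - first + 1) if first >= 0 else 0
    return AlignResult(
        aligned_a=gapped_a,
        aligned_b=gapped_b,
        score=int(alignment.score),
        aligned_region_length=region,
        n_exact_matches=n_match,
    )


def align_stats(
    a: SeqRecord | str, b: SeqRecord | str, scoring: ScoringParams | None = None,
    result: AlignResult | None = None,
) -> AlignStats:
    """Compute the three similarity statistics for a sequence pair.

    Pass ``result`` to reuse an alignment already computed for this pair.
    """
    scoring = scoring or ScoringParams()
    sa = a.residues if isinstance(a, SeqRecord) else a
    sb = b.residues if isinstance(b, SeqRecord) else b
    res = result if result is not None else semiglobal_align(sa, sb, scoring)
    len_ratio = res.aligned_region_length / max(len(sa), len(sb))
    match_ratio = (
        res.n_exact_matches / res.aligned_region_length
        if res.aligned_region_length
        else 0.0
    )
    denom = min(self_score(sa, scoring), self_score(sb, scoring))
    score_ratio = res.score / denom if denom else float("nan")
    return AlignStats(len_ratio=len_ratio, match_ratio=match_ratio,
                      score_ratio=score_ratio)
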