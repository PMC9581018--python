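"""Protein FASTA I/O and pre-clustering filters.

Sequence records carry an accession (the first whitespace-delimited token of
the FASTA header) and the remainder of the header as free-text annotation.
Before clustering, each batch is filtered: records annotated as hypothetical
proteins are dropped, and exact duplicate residue strings are collapsed to
their first occurrence.

The parser is deliberately strict — malformed headers, empty bodies and
illegal residue letters are reported with the offending line number, because
silent acceptance of a corrupt batch would poison every downstream cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

__all__ = [
    "SeqRecord",
    "FilterReport",
    "FastaParseError",
    "ALLOWED_RESIDUES",
    "parse_fasta",
    "read_fasta",
    "write_fasta",
    "filter_batch",
]

#: The 20 standard amino acids plus the ambiguity/rare letters B, Z, X and
#: selenocysteine U, which occur in RefSeq protein records.
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "BZXU")

_HYPOTHETICAL_PHRASE = "hypothetical protein"


class FastaParseError(ValueError):
    """Raised on malformed FASTA input; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class SeqRecord:
    """One protein sequence with its header metadata.

    ``seq_id`` is an opaque stable identifier; by default it equals the
    accession, but synthetic generators and batch drivers may assign their
    own ids independent of the header.
    """

    seq_id: str
    accession: str
    annotation: str
    residues: str
    source_organism: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.seq_id!r}: empty residue string")
        bad = set(self.residues) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.seq_id!r}: illegal residue letter(s) "
                f"{''.join(sorted(bad))!r}"
            )

    @property
    def header(self) -> str:
        return f"{self.accession} {self.annotation}".rstrip()

    def __len__(self) -> int:
        return len(self.residues)

    def is_hypothetical(self) -> bool:
        """True if the annotation names a hypothetical protein (case-insensitive)."""
        return _HYPOTHETICAL_PHRASE in self.annotation.lower()


@dataclass
class FilterReport:
    """Tally of a pre-clustering filter pass; counts always conserve."""

    n_input: int = 0
    n_hypothetical_removed: int = 0
    n_duplicates_removed: int = 0
    n_kept: int = 0

    def __post_init__(self) -> None:
        assert (
            self.n_input
            == self.n_kept + self.n_hypothetical_removed + self.n_duplicates_removed
        ), "filter counts do not conserve"

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def parse_fasta(stream: IO[str] | str) -> list[SeqRecord]:
    """Parse multi-record protein FASTA from a text stream or string.

    The header format is ``>accession annotation...``; the accession is the
    first whitespace-delimited token, the annotation is the remainder (may be
    empty).  Order is preserved and ``seq_id`` is set to the accession.

    Raises
    ------
    FastaParseError
        On a non-``>`` line before the first header, an empty sequence body,
        or an illegal residue character — each named with its line number.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    records: list[SeqRecord] = []
    accession: str | None = None
    annotation = ""
    chunks: list[str] = []
    header_line = 0

    def flush(at_line: int) -> None:
        nonlocal accession
        if accession is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise FastaParseError(
                f"record {accession!r} has an empty sequence body", header_line
            )
        records.append(
            SeqRecord(seq_id=accession, accession=accession,
                      annotation=annotation, residues=residues)
        )
        accession = None
        chunks.clear()

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(lineno)
            header = line[1:].strip()
            if not header:
                raise FastaParseError("header is empty", lineno)
            parts = header.split(None, 1)
            accession = parts[0]
            annotation = parts[1] if len(parts) > 1 else ""
            header_line = lineno
        else:
            if accession is None:
                raise FastaParseError(
                    f"expected '>' header, got {line[:30]!r}", lineno
                )
            residues = line.upper()
            bad = set(residues) - ALLOWED_RESIDUES
            if bad:
                raise FastaParseError(
                    f"illegal residue character(s) {''.join(sorted(bad))!r}", lineno
                )
            chunks.append(residues)
    flush(len(lines) + 1)
    return records


def read_fasta(path: str | Path) -> list[SeqRecord]:
    with open(path) as fh:
        return parse_fasta(fh)


def write_fasta(records: Iterable[SeqRecord], stream: IO[str] | str | Path,
                width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    if isinstance(stream, (str, Path)):
        with open(stream, "w") as fh:
            write_fasta(records, fh, width=width)
        return
    for rec in records:
        stream.write(f">{rec.header}\n")
        for i in range(0, len(rec.residues), width):
            stream.write(rec.residues[i : i + width] + "\n")


def filter_batch(
    records: list[SeqRecord],
) -> tuple[list[SeqRecord], FilterReport]:
    """Apply the pre-clustering filters to one batch.

    First removes records whose annotation contains the phrase
    "hypothetical protein" (case-insensitive substring), then removes exact
    duplicate residue strings, keeping the first occurrence in input order.
    Duplicate detection looks only at the residues, never at the header.
    """
    n_input = len(records)
    non_hypo = [r for r in records if not r.is_hypothetical()]
    n_hypo = n_input - len(non_hypo)

    seen: set[str] = set()
    kept: list[SeqRecord] = []
    for rec in non_hypo:
        if rec.residues in seen:
            continue
        seen.add(rec.residues)
        kept.append(rec)
    n_dup = len(non_hypo) - len(kept)

    report = FilterReport(
        n_input=n_input,
        n_hypothetical_removed=n_hypo,
        n_duplicates_removed=n_dup,
        n_kept=len(kept),
    )
    return kept, report
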