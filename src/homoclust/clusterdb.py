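"""Persistent cluster-membership store and best-match queries.

The membership of every sequence — identification number, accession,
annotation, cluster id (null for singletons) and a validation flag marking
experimentally verified function — is kept in a single-file SQLite store
next to a FASTA file of the sequences themselves.

A query sequence is answered by ranking all stored sequences by semi-global
alignment score (ties: higher aligned-length ratio, then accession order)
and returning the full membership of the best hit's cluster, so the user
sees every homolog's header and can prefer validated annotations.  A top
hit whose aligned-length ratio falls below ``min_len_ratio`` (default 0.5)
is treated as no match.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path

from .merge import ClusterSet
from .pairalign import AlignStats, ScoringParams, align_stats, semiglobal_align
from .seqio import SeqRecord, write_fasta

__all__ = [
    "ClusterMember",
    "ClusterHit",
    "NoMatch",
    "ClusterDatabase",
    "build_db",
    "load_db",
    "best_match",
    "mark_validated",
]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS members (
    member_id   INTEGER PRIMARY KEY,
    accession   TEXT NOT NULL UNIQUE,
    annotation  TEXT NOT NULL,
    residues    TEXT NOT NULL,
    cluster_id  INTEGER,
    validated   INTEGER NOT NULL DEFAULT 0 CHECK (validated IN (0, 1))
);
CREATE INDEX IF NOT EXISTS idx_members_cluster ON members (cluster_id);
"""


@dataclass(frozen=True)
class ClusterMember:
    member_id: int
    accession: str
    annotation: str
    cluster_id: int | None
    validated: int


@dataclass(frozen=True)
class ClusterHit:
    """Best-match answer: the winning sequence and its whole cluster."""

    query_id: str
    best_hit_accession: str
    best_hit_score: int
    best_hit_stats: AlignStats
    cluster_id: int | None
    cluster_headers: list[tuple[str, str, int]]  # (accession, annotation, validated)


@dataclass(frozen=True)
class NoMatch:
    """Returned when no stored sequence aligns acceptably to the query."""

    query_id: str
    reason: str = "no stored sequence reached the minimum aligned-length ratio"


class ClusterDatabase:
    """Handle on an open membership store."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "ClusterDatabase":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- content ----------------------------------------------------------

    @property
    def n_members(self) -> int:
        (n,) = self._conn.execute("SELECT COUNT(*) FROM members").fetchone()
        return n

    def members(self) -> list[ClusterMember]:
        rows = self._conn.execute(
            "SELECT member_id, accession, annotation, cluster_id, validated "
            "FROM members ORDER BY member_id"
        ).fetchall()
        return [ClusterMember(*row) for row in rows]

    def records(self) -> list[SeqRecord]:
        rows = self._conn.execute(
            "SELECT accession, annotation, residues FROM members "
            "ORDER BY member_id"
        ).fetchall()
        return [
            SeqRecord(seq_id=acc, accession=acc, annotation=ann, residues=res)
            for acc, ann, res in rows
        ]

    def cluster_set(self) -> ClusterSet:
        clusters: dict[int, list[str]] = {}
        singletons: list[str] = []
        for m in self.members():
            if m.cluster_id is None:
                singletons.append(m.accession)
            else:
                clusters.setdefault(m.cluster_id, []).append(m.accession)
        return ClusterSet(
            clusters=[clusters[c] for c in sorted(clusters)],
            singletons=singletons,
        )

    def cluster_headers(self, cluster_id: int | None,
                        accession: str | None = None
                        ) -> list[tuple[str, str, int]]:
        if cluster_id is None:
            rows = self._conn.execute(
                "SELECT accession, annotation, validated FROM members "
                "WHERE cluster_id IS NULL AND accession = ?", (accession,)
            ).fetchall()
        else:
            rows = self._conn.execute(
                "SELECT accession, annotation, validated FROM members "
                "WHERE cluster_id = ? ORDER BY member_id", (cluster_id,)
            ).fetchall()
        return [tuple(r) for r in rows]


def build_db(
    clusters: ClusterSet,
    records: list[SeqRecord],
    path: str | Path,
    fasta_path: str | Path | None = None,
) -> ClusterDatabase:
    """Persist a ClusterSet with its sequences; every member needs a record.

    Member ids are assigned in cluster order then singleton order; all
    validation flags start at 0.  A FASTA copy of all member sequences is
    written next to the store (``<path>.fasta`` unless given).
    """
    by_id = {r.seq_id: r for r in records}
    missing = [
        m
        for group in ([*clusters.clusters, [s for s in clusters.singletons]])
        for m in group
        if m not in by_id
    ]
    if missing:
        raise KeyError(f"no sequence record for member(s) {missing[:5]}")

    path = Path(path)
    if path.exists():
        path.unlink()
    db = ClusterDatabase(path)
    rows = []
    member_id = 0
    ordered_records: list[SeqRecord] = []
    for cid, members in enumerate(clusters.clusters):
        for m in members:
            rec = by_id[m]
            rows.append((member_id, rec.accession, rec.annotation,
                         rec.residues, cid, 0))
            ordered_records.append(rec)
            member_id += 1
    for s in clusters.singletons:
        rec = by_id[s]
        rows.append((member_id, rec.accession, rec.annotation,
                     rec.residues, None, 0))
        ordered_records.append(rec)
        member_id += 1
    db._conn.executemany("INSERT INTO members VALUES (?,?,?,?,?,?)", rows)
    db._conn.commit()

    fasta_path = Path(fasta_path) if fasta_path else path.with_suffix(
        path.suffix + ".fasta")
    write_fasta(ordered_records, fasta_path)
    return db


def load_db(path: str | Path) -> ClusterDatabase:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return ClusterDatabase(path)


def best_match(
    db: ClusterDatabase,
    query: SeqRecord,
    scoring: ScoringParams | None = None,
    min_len_ratio: float = 0.5,
) -> ClusterHit | NoMatch:
    """Rank all stored sequences against the query and return the best cluster.

    Ranking: higher semi-global alignment score, then higher len_ratio,
    then accession order — fully deterministic.
    """
    if db.n_members == 0:
        raise ValueError("cluster database is empty")
    scoring = scoring or ScoringParams()

    best: tuple[int, float, str] | None = None
    best_stats: AlignStats | None = None
    best_cluster: int | None = None
    for m, rec in zip(db.members(), db.records()):
        res = semiglobal_align(query.residues, rec.residues, scoring)
        stats = align_stats(query, rec, scoring, result=res)
        key = (-res.score, -stats.len_ratio, m.accession)
        if best is None or key < best:
            best = key
            best_stats = stats
            best_cluster = m.cluster_id
            best_accession = m.accession
            best_score = res.score
    if best_stats.len_ratio < min_len_ratio:
        return NoMatch(query_id=query.seq_id)
    return ClusterHit(
        query_id=query.seq_id,
        best_hit_accession=best_accession,
        best_hit_score=best_score,
        best_hit_stats=best_stats,
        cluster_id=best_cluster,
        cluster_headers=db.cluster_headers(best_cluster, best_accession),
    )


def mark_validated(db: ClusterDatabase, accession: str) -> int:
    """Set the validation flag of one accession to 1 (idempotent)."""
    cur = db._conn.execute(
        "UPDATE members SET validated = 1 WHERE accession = ?", (accession,)
    )
    if cur.rowcount == 0:
        raise KeyError(f"accession {accession!r} not in database")
    db._conn.commit()
    return 1


def apply_validation_list(db: ClusterDatabase, accessions: list[str]) -> int:
    """Mark a curator-supplied list of accessions as validated; returns count."""
    n = 0
    for acc in accessions:
        mark_validated(db, acc)
        n += 1
    return n
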