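"""Synthetic protein datasets with planted homologous families.

Each family grows from one random seed sequence; members are independent
mutants of the seed with i.i.d. per-site substitutions (uniform over the 19
alternative residues) and optional short indels (single-residue events with
geometric length extension, p = 0.5).  Around the families the generator
plants length-matched random decoys, exact duplicate copies of family
members, and records annotated as hypothetical proteins — the three kinds
of sequence the pre-clustering filters and the clustering itself must
handle.  A truth table maps every record to its family (or "decoy") so
recovered clusters can be scored exactly.

Rate guidance for the default clustering threshold of 0.8 on the
aligned-length ratio: sub_rate <= 0.15 and indel_rate <= 0.02 keep planted
families connected while length-matched decoys stay unconnected.  All
randomness flows through one seeded NumPy generator, so outputs are
byte-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import IO

import numpy as np

from .iterclust import IterationSchedule
from .seqio import SeqRecord

__all__ = [
    "ALPHABET",
    "FamilySpec",
    "TruthSet",
    "make_family",
    "make_dataset",
    "split_batches",
    "flat_schedule",
]

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one planted homologous family."""

    n_members: int = 5
    seed_length: int = 120
    sub_rate: float = 0.05
    indel_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("a family needs at least one member")
        if self.seed_length < 1:
            raise ValueError("seed_length must be positive")
        if not 0 <= self.sub_rate < 1 or not 0 <= self.indel_rate < 1:
            raise ValueError("rates must lie in [0, 1)")


@dataclass
class TruthSet:
    """Ground-truth family assignment: seq_id -> family index or 'decoy'."""

    family_of: dict[str, int | str]

    def families(self) -> set[frozenset[str]]:
        """Planted partition over non-decoy ids, as a set of frozensets."""
        groups: dict[int, list[str]] = {}
        for sid, fam in self.family_of.items():
            if fam != "decoy":
                groups.setdefault(fam, []).append(sid)
        return {frozenset(g) for g in groups.values()}

    def decoys(self) -> set[str]:
        return {s for s, f in self.family_of.items() if f == "decoy"}

    def write_tsv(self, stream: IO[str]) -> None:
        stream.write("seq_id\tfamily\n")
        for sid, fam in self.family_of.items():
            stream.write(f"{sid}\t{fam}\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, len(ALPHABET), length))


def _mutate(rng: np.random.Generator, seed: str, sub_rate: float,
            indel_rate: float) -> str:
    out: list[str] = []
    for ch in seed:
        if indel_rate and rng.random() < indel_rate:
            if rng.random() < 0.5:
                # deletion of this site (plus geometric extension is handled
                # by independent per-site events)
                continue
            out.append(_random_seq(rng, int(rng.geometric(0.5))))
        if sub_rate and rng.random() < sub_rate:
            alt = ALPHABET.replace(ch, "")
            out.append(alt[rng.integers(0, len(alt))])
        else:
            out.append(ch)
    return "".join(out) or seed[:1]


def make_family(
    spec: FamilySpec, family_index: int = 0
) -> tuple[list[SeqRecord], TruthSet]:
    """Generate one family of mutant descendants of a random seed sequence."""
    rng = np.random.default_rng(spec.rng_seed)
    seed = _random_seq(rng, spec.seed_length)
    records = []
    truth: dict[str, int | str] = {}
    for j in range(spec.n_members):
        residues = _mutate(rng, seed, spec.sub_rate, spec.indel_rate)
        acc = f"F{family_index}_M{j}"
        records.append(
            SeqRecord(
                seq_id=acc,
                accession=acc,
                annotation=f"synthetic family {family_index} member {j}",
                residues=residues,
            )
        )
        truth[acc] = family_index
    return records, TruthSet(truth)


def make_dataset(
    n_families: int,
    family_spec: FamilySpec = FamilySpec(),
    n_decoys: int = 0,
    n_duplicates: int = 0,
    n_hypotheticals: int = 0,
    rng_seed: int = 0,
) -> tuple[list[SeqRecord], TruthSet]:
    """Families plus decoys, duplicates and hypothetical-protein records.

    Decoys are unrelated random sequences length-matched to the family seed
    length, so only similarity — not length — separates them.  Duplicates
    are exact residue copies of randomly chosen family members under new
    accessions (they inherit the source's truth label).  Hypothetical
    records are random sequences annotated "hypothetical protein ...".
    The combined list is shuffled deterministically.
    """
    if min(n_families, n_decoys, n_duplicates, n_hypotheticals) < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(rng_seed)
    records: list[SeqRecord] = []
    truth: dict[str, int | str] = {}

    family_members: list[SeqRecord] = []
    for f in range(n_families):
        fam_seed = int(rng.integers(0, 2**31 - 1))
        recs, t = make_family(
            replace(family_spec, rng_seed=fam_seed), family_index=f
        )
        records.extend(recs)
        family_members.extend(recs)
        truth.update(t.family_of)

    for i in range(n_decoys):
        acc = f"DECOY_{i}"
        records.append(
            SeqRecord(seq_id=acc, accession=acc,
                      annotation=f"synthetic decoy {i}",
                      residues=_random_seq(rng, family_spec.seed_length))
        )
        truth[acc] = "decoy"

    if n_duplicates and not family_members:
        raise ValueError("cannot duplicate members of zero families")
    for i in range(n_duplicates):
        src = family_members[int(rng.integers(0, len(family_members)))]
        acc = f"DUP_{i}"
        records.append(
            SeqRecord(seq_id=acc, accession=acc,
                      annotation=f"duplicate of {src.accession}",
                      residues=src.residues)
        )
        truth[acc] = truth[src.seq_id]

    for i in range(n_hypotheticals):
        acc = f"HYP_{i}"
        records.append(
            SeqRecord(seq_id=acc, accession=acc,
                      annotation=f"hypothetical protein SYN_{i}",
                      residues=_random_seq(rng, family_spec.seed_length))
        )
        truth[acc] = "decoy"

    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return records, TruthSet({r.seq_id: truth[r.seq_id] for r in records})


def split_batches(records: list[SeqRecord], n_batches: int) -> list[list[SeqRecord]]:
    """Split into n contiguous, near-equal, non-empty batches."""
    if not 1 <= n_batches <= len(records):
        raise ValueError("need 1 <= n_batches <= n_records")
    bounds = np.linspace(0, len(records), n_batches + 1).round().astype(int)
    return [records[bounds[i] : bounds[i + 1]] for i in range(n_batches)]


def flat_schedule(n_batches: int, final_name: str = "all") -> IterationSchedule:
    """Two-iteration schedule: cluster each batch, then combine everything.

    With a single batch this degenerates to one iteration.
    """
    names = [str(i + 1) for i in range(n_batches)]
    if n_batches == 1:
        return IterationSchedule(input_batches=names)
    return IterationSchedule(
        input_batches=names,
        groupings=[[(final_name, names)]],
    )
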