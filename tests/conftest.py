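import random

import pytest

from homoclust.pairalign import ScoringParams
from homoclust.seqio import SeqRecord
from homoclust.synth import ALPHABET


@pytest.fixture(scope="session")
def scoring() -> ScoringParams:
    return ScoringParams()


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(20240901)


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(ALPHABET) for _ in range(length))


def make_record(seq_id: str, residues: str, annotation: str = "test protein"):
    return SeqRecord(seq_id=seq_id, accession=seq_id, annotation=annotation,
                     residues=residues)
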