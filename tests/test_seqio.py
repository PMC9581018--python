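import io

import pytest
from hypothesis import given, settings, strategies as st

from homoclust.seqio import (
    ALLOWED_RESIDUES,
    FastaParseError,
    FilterReport,
    SeqRecord,
    filter_batch,
    parse_fasta,
    write_fasta,
)

from conftest import make_record, random_protein

residue_text = st.text(alphabet=sorted(ALLOWED_RESIDUES), min_size=1, max_size=150)
accession_text = st.from_regex(r"[A-Z]{2}_[0-9]{6}\.[0-9]", fullmatch=True)
annotation_text = st.text(
    alphabet=st.characters(whitelist_categories=("L", "N"), whitelist_characters=" -_."),
    max_size=60,
).map(lambda s: " ".join(s.split()))


class TestParse:
    def test_empty_stream_gives_empty_list(self):
        assert parse_fasta("") == []

    def test_header_splits_accession_and_annotation(self):
        recs = parse_fasta(
            ">XP_452906.1 uncharacterized protein KLLA0_C15807g\nMKYN\n"
        )
        assert len(recs) == 1
        assert recs[0].accession == "XP_452906.1"
        assert recs[0].annotation == "uncharacterized protein KLLA0_C15807g"
        assert recs[0].residues == "MKYN"

    def test_annotation_may_be_empty(self):
        (rec,) = parse_fasta(">ACC1\nMKY\n")
        assert rec.accession == "ACC1" and rec.annotation == ""

    @pytest.mark.parametrize(
        "text, lineno",
        [
            ("MKYN\n", 1),                      # body before any header
            (">A1 x\n\n>A2 y\nMK\n", 1),        # empty body of first record
            (">A1 x\nMKJ\n", 2),                # J is not an allowed residue
            (">\nMK\n", 1),                     # empty header
        ],
    )
    def test_errors_carry_line_numbers(self, text, lineno):
        with pytest.raises(FastaParseError) as exc:
            parse_fasta(text)
        assert exc.value.line == lineno

    def test_trailing_record_without_body_is_an_error(self):
        with pytest.raises(FastaParseError):
            parse_fasta(">A1 x\nMK\n>A2 y\n")


class TestWrite:
    def test_minimal_record(self):
        buf = io.StringIO()
        write_fasta([make_record("A1", "ACD", annotation="x")], buf)
        assert buf.getvalue() == ">A1 x\nACD\n"

    def test_wraps_at_60_columns(self):
        buf = io.StringIO()
        write_fasta([make_record("A1", "M" * 70)], buf)
        lines = buf.getvalue().splitlines()
        assert [len(l) for l in lines[1:]] == [60, 10]

    def test_empty_record_list_writes_nothing(self):
        buf = io.StringIO()
        write_fasta([], buf)
        assert buf.getvalue() == ""

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(accession_text, annotation_text, residue_text),
        min_size=1, max_size=10, unique_by=lambda t: t[0],
    ))
    def test_round_trip_preserves_content(self, triples):
        records = [
            SeqRecord(seq_id=acc, accession=acc, annotation=ann, residues=res)
            for acc, ann, res in triples
        ]
        buf = io.StringIO()
        write_fasta(records, buf)
        back = parse_fasta(buf.getvalue())
        assert [(r.accession, r.annotation, r.residues) for r in back] == [
            (r.accession, r.annotation, r.residues) for r in records
        ]


class TestRecordValidation:
    def test_empty_residues_rejected(self):
        with pytest.raises(ValueError):
            make_record("A1", "")

    def test_illegal_letter_rejected(self):
        with pytest.raises(ValueError, match="illegal residue"):
            make_record("A1", "MKO")

    def test_ambiguity_letters_accepted(self):
        rec = make_record("A1", "MXBZU")
        assert rec.residues == "MXBZU"


class TestFilterBatch:
    def test_clean_batch_is_untouched(self, rng):
        records = [make_record(f"A{i}", random_protein(rng, 30)) for i in range(4)]
        kept, rep = filter_batch(records)
        assert kept == records
        assert rep == FilterReport(n_input=4, n_hypothetical_removed=0,
                                   n_duplicates_removed=0, n_kept=4)

    @pytest.mark.parametrize(
        "annotation",
        ["hypothetical protein ABC_123", "HYPOTHETICAL PROTEIN",
         "conserved Hypothetical Protein precursor"],
    )
    def test_hypothetical_annotations_removed(self, annotation):
        rec = make_record("A1", "MKY", annotation=annotation)
        kept, rep = filter_batch([rec])
        assert kept == [] and rep.n_hypothetical_removed == 1

    def test_mixed_batch_counts(self, rng):
        seq = random_protein(rng, 40)
        records = [
            make_record("A1", seq),
            make_record("A2", seq),  # exact duplicate, different accession
            make_record("A3", random_protein(rng, 40),
                        annotation="hypothetical protein X"),
            make_record("A4", random_protein(rng, 40)),
            make_record("A5", random_protein(rng, 40)),
        ]
        kept, rep = filter_batch(records)
        assert [r.seq_id for r in kept] == ["A1", "A4", "A5"]
        assert rep.n_hypothetical_removed == 1
        assert rep.n_duplicates_removed == 1
        assert rep.n_input == rep.n_kept + rep.n_hypothetical_removed + \
            rep.n_duplicates_removed

    def test_first_occurrence_of_duplicate_survives(self):
        records = [make_record("LATER", "MKYW"), make_record("EARLIER", "MKYW")]
        kept, _ = filter_batch(records)
        assert [r.seq_id for r in kept] == ["LATER"]

    def test_duplicate_detection_ignores_headers(self):
        records = [
            make_record("A1", "MKYW", annotation="kinase"),
            make_record("A1b", "MKYW", annotation="phosphatase"),
        ]
        kept, rep = filter_batch(records)
        assert len(kept) == 1 and rep.n_duplicates_removed == 1

    def test_idempotent(self, rng):
        records = [make_record(f"A{i}", random_protein(rng, 25)) for i in range(6)]
        records += [make_record("D0", records[0].residues)]
        once, _ = filter_batch(records)
        twice, rep = filter_batch(once)
        assert twice == once
        assert rep.n_duplicates_removed == rep.n_hypothetical_removed == 0

    def test_empty_input(self):
        kept, rep = filter_batch([])
        assert kept == [] and rep.n_input == 0 and rep.n_kept == 0
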