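import io
import random

import pytest
from hypothesis import given, settings, strategies as st

from homoclust.iterclust import (
    BatchResult,
    IterationSchedule,
    IterationTrace,
    Label,
    batch_letters,
    cluster_batch,
    parse_label,
    paper_schedule_example,
    render_label,
    representatives,
    run_iterations,
)
from homoclust.synth import FamilySpec, flat_schedule, make_dataset, make_family

from conftest import make_record, random_protein


class TestLabels:
    @pytest.mark.parametrize(
        "label, text",
        [
            (Label("member", 0, 0, cluster_index=0), "A_0#a_0"),
            (Label("member", 0, 15, cluster_index=11), "A_11#a_15"),
            (Label("singleton", 0, 1), "Sa_1#a_1"),
            (Label("singleton", 0, 1091), "Sa_1091#a_1091"),
            (Label("member", 10, 3, cluster_index=9), "K_9#k_3"),
            (Label("singleton", 27, 2), "Sab_2#ab_2"),
        ],
    )
    def test_render_parse_known_labels(self, label, text):
        assert render_label(label) == text
        assert parse_label(text) == label

    def test_sub_cluster_label_prefix(self):
        # the first sub-cluster of the first batch renders with prefix A_0
        assert render_label(Label("member", 0, 5, cluster_index=0)).startswith("A_0#")

    @pytest.mark.parametrize("text", [
        "A_11#b_15",        # letters disagree
        "Sa_1#a_2",         # singleton halves disagree
        "a_11#a_15",        # lowercase cluster part
        "A11#a_15",         # missing underscore
        "",                 # empty
    ])
    def test_malformed_labels_rejected(self, text):
        with pytest.raises(ValueError):
            parse_label(text)

    def test_letters_extend_beyond_26_batches(self):
        assert batch_letters(0) == "A"
        assert batch_letters(25) == "Z"
        assert batch_letters(26) == "AA"
        assert batch_letters(27 * 26 - 1) == "ZZ"

    def test_round_trip_identity_on_random_labels(self):
        rng = random.Random(7)
        for _ in range(1000):
            if rng.random() < 0.5:
                label = Label("member", rng.randrange(60), rng.randrange(5000),
                              cluster_index=rng.randrange(2000))
            else:
                label = Label("singleton", rng.randrange(60), rng.randrange(5000))
            assert parse_label(render_label(label)) == label


class TestBatchResult:
    def test_rejects_undersized_subcluster(self):
        with pytest.raises(ValueError):
            BatchResult(0, 2, subclusters=[[0]], singletons=[1])

    def test_rejects_non_partition(self):
        with pytest.raises(ValueError):
            BatchResult(0, 3, subclusters=[[0, 1]], singletons=[1])

    def test_output_count_is_subclusters_plus_singletons(self):
        r = BatchResult(0, 5, subclusters=[[0, 2], [1, 4]], singletons=[3])
        assert r.n_output == 3


class TestClusterBatch:
    def test_dissimilar_batch_is_all_singletons(self, rng):
        records = [make_record(f"R{i}", random_protein(rng, 30 + 20 * i))
                   for i in range(5)]
        result = cluster_batch(records)
        assert result.subclusters == [] and result.singletons == [0, 1, 2, 3, 4]

    def test_two_planted_families_and_one_stranger(self, rng):
        fam1, _ = make_family(FamilySpec(n_members=3, seed_length=80,
                                         sub_rate=0.03, rng_seed=11))
        fam2, _ = make_family(FamilySpec(n_members=3, seed_length=80,
                                         sub_rate=0.03, rng_seed=12), family_index=1)
        stranger = make_record("STR", random_protein(rng, 200))
        result = cluster_batch(fam1 + fam2 + [stranger])
        assert result.n_subclusters == 2
        assert result.singletons == [6]
        assert sorted(map(tuple, result.subclusters)) == [(0, 1, 2), (3, 4, 5)]

    def test_conservation_over_random_batches(self):
        for seed in range(10):
            records, _ = make_dataset(
                3, FamilySpec(n_members=3, seed_length=60, sub_rate=0.05),
                n_decoys=2, rng_seed=seed,
            )
            result = cluster_batch(records)
            covered = sum(len(sc) for sc in result.subclusters) + len(
                result.singletons
            )
            assert covered == len(records)

    def test_empty_batch_is_an_error(self):
        with pytest.raises(ValueError):
            cluster_batch([])


class TestRepresentatives:
    def test_first_member_by_index_is_representative(self, rng):
        records = [make_record(f"R{i}", random_protein(rng, 30))
                   for i in range(8)]
        result = BatchResult(0, 8, subclusters=[[1, 3, 7], [2, 5]],
                             singletons=[0, 4, 6])
        reps = representatives(result, records)
        assert [r.seq_id for r in reps] == ["R1", "R2"]

    def test_one_representative_per_subcluster(self, rng):
        records = [make_record(f"R{i}", random_protein(rng, 30))
                   for i in range(6)]
        result = BatchResult(0, 6, subclusters=[[0, 1], [2, 3], [4, 5]],
                             singletons=[])
        assert len(representatives(result, records)) == result.n_subclusters


class TestSchedule:
    def test_paper_style_schedule_is_expressible(self):
        sched = paper_schedule_example()
        assert len(sched.input_batches) == 11
        assert sched.n_iterations == 4
        assert sched.final_batch == "1234567891011"

    def test_yaml_round_trip(self):
        sched = paper_schedule_example()
        buf = io.StringIO()
        sched.to_yaml(buf)
        back = IterationSchedule.from_yaml(io.StringIO(buf.getvalue()))
        assert back.to_dict() == sched.to_dict()

    def test_rejects_unknown_source(self):
        with pytest.raises(ValueError, match="unknown"):
            IterationSchedule(
                input_batches=["1", "2"],
                groupings=[[("x", ["1", "3"])]],
            )

    def test_rejects_double_consumption(self):
        with pytest.raises(ValueError):
            IterationSchedule(
                input_batches=["1", "2"],
                groupings=[[("x", ["1", "1"])]],
            )

    def test_rejects_multi_batch_final_iteration(self):
        with pytest.raises(ValueError):
            IterationSchedule(
                input_batches=["1", "2", "3", "4"],
                groupings=[[("x", ["1", "2"]), ("y", ["3", "4"])]],
            )

    def test_rejects_stranded_outputs(self):
        with pytest.raises(ValueError, match="never consumed"):
            IterationSchedule(
                input_batches=["1", "2", "3"],
                groupings=[[("x", ["1", "2"])]],
            )

    def test_single_batch_degenerate_schedule(self):
        sched = IterationSchedule(input_batches=["1"])
        assert sched.n_iterations == 1 and sched.final_batch == "1"


class TestRunIterations:
    def _dataset(self, seed, n_families=4, members=3):
        records, truth = make_dataset(
            n_families, FamilySpec(n_members=members, seed_length=70,
                                   sub_rate=0.05),
            n_decoys=2, rng_seed=seed,
        )
        return records, truth

    def test_single_batch_trace_matches_cluster_batch(self):
        records, _ = self._dataset(0)
        trace = run_iterations([records], flat_schedule(1))
        direct = cluster_batch(records)
        final = trace.batches[trace.final_batch].result
        assert final.subclusters == direct.subclusters
        assert final.singletons == direct.singletons
        assert len(trace.iterations) == 1

    def test_provenance_totality(self):
        records, _ = self._dataset(1)
        half = len(records) // 2
        trace = run_iterations([records[:half], records[half:]],
                               flat_schedule(2))
        final = trace.batches[trace.final_batch]
        for prov in final.inputs:
            assert prov.kind in {"representative", "singleton"}
            assert prov.source_batch in trace.batches

    def test_next_iteration_input_counting(self):
        records, _ = self._dataset(2)
        half = len(records) // 2
        trace = run_iterations([records[:half], records[half:]],
                               flat_schedule(2))
        expected = sum(
            trace.batches[name].result.n_output
            for name in trace.iterations[0]
        )
        final = trace.batches[trace.final_batch]
        n_dedup = sum(len(v) for v in final.dedup_merges.values())
        assert len(final.inputs) + n_dedup == expected

    def test_duplicate_ids_across_batches_rejected(self):
        records, _ = self._dataset(3)
        with pytest.raises(ValueError, match="unique"):
            run_iterations([records, records], flat_schedule(2))

    def test_trace_jsonl_round_trip(self):
        records, _ = self._dataset(4)
        half = len(records) // 2
        trace = run_iterations([records[:half], records[half:]],
                               flat_schedule(2))
        buf = io.StringIO()
        trace.to_jsonl(buf)
        back = IterationTrace.from_jsonl(io.StringIO(buf.getvalue()))
        assert back.iterations == trace.iterations
        assert back.final_batch == trace.final_batch
        assert back.original_ids == trace.original_ids
        for name, tb in trace.batches.items():
            assert back.batches[name].inputs == tb.inputs
            assert back.batches[name].result.subclusters == tb.result.subclusters
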