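import numpy as np
import pytest
from Bio.Align import substitution_matrices

from ghx.seqio import ProteinRecord, Span, STANDARD_AA
from ghx.segmentation import (
    ReferenceModel,
    align_to_reference,
    classify_cbh,
    find_cbm1,
    find_linker,
    reference_coverage,
    segment_dataset,
)
from ghx.synthetic_data import GeneratorConfig, generate_dataset
from tests.oracles import gotoh_score


class TestAlignToReference:
    def test_self_alignment_is_identity(self, reference_model):
        ref = reference_model.reference
        aln = align_to_reference(ref, reference_model)
        assert list(aln.ref_to_query) == list(range(len(ref)))

    def test_self_alignment_score_is_diagonal_sum(self, reference_model):
        mat = substitution_matrices.load("BLOSUM62")
        ref = reference_model.reference
        aln = align_to_reference(ref, reference_model)
        assert aln.score == pytest.approx(sum(mat[c, c] for c in ref.sequence))

    def test_leading_deletion_shifts_mapping(self, reference_model):
        ref = reference_model.reference
        query = ProteinRecord(id="q", sequence=ref.sequence[5:])
        aln = align_to_reference(query, reference_model)
        assert all(aln.map_ref_position(i) == -1 for i in range(5))
        assert all(aln.map_ref_position(i) == i - 5 for i in range(5, len(ref)))

    def test_matches_dp_oracle_on_short_pairs(self, reference_model):
        mat = substitution_matrices.load("BLOSUM62")
        sub = {(x, y): float(mat[x, y]) for x in STANDARD_AA for y in STANDARD_AA}
        rng = np.random.default_rng(7)
        for _ in range(60):
            a = "".join(rng.choice(list(STANDARD_AA), size=rng.integers(1, 13)))
            b = "".join(rng.choice(list(STANDARD_AA), size=rng.integers(1, 13)))
            model = ReferenceModel(
                reference=ProteinRecord(id="r", sequence="FSNIK" + b),
                loop_windows=[Span(0, 2)],
            )
            aln = align_to_reference(ProteinRecord(id="q", sequence=a), model)
            expected = gotoh_score(a, "FSNIK" + b, sub, 10.0, 1.0)
            assert aln.score == pytest.approx(expected)


class TestReferenceCoverage:
    def test_identity_is_100(self, reference_model):
        aln = align_to_reference(reference_model.reference, reference_model)
        assert reference_coverage(aln) == 100.0

    def test_constructed_deletion_reduces_coverage(self, reference_model):
        ref = reference_model.reference
        n_drop = int(round(0.3 * len(ref)))
        query = ProteinRecord(id="q", sequence=ref.sequence[n_drop:])
        aln = align_to_reference(query, reference_model)
        assert reference_coverage(aln) == pytest.approx(
            100.0 * (len(ref) - n_drop) / len(ref)
        )

    def test_coverage_positive_for_nonempty(self, reference_model):
        query = ProteinRecord(id="q", sequence="MKT")
        aln = align_to_reference(query, reference_model)
        assert reference_coverage(aln) > 0.0


class TestFindCbm1:
    def test_canonical_boundary_example(self):
        rec = ProteinRecord(id="a", sequence="MKLLAAAAAATQSHYGQCGGIGYS")
        span = find_cbm1(rec)
        assert span == Span(10, 24)
        assert rec.sequence[span.start : span.end] == "TQSHYGQCGGIGYS"

    def test_absent_motif(self):
        assert find_cbm1(ProteinRecord(id="a", sequence="MKTLLL")) is None

    def test_motif_too_close_to_n_terminus(self):
        assert find_cbm1(ProteinRecord(id="a", sequence="AQCGGYYYY")) is None

    def test_rightmost_occurrence_anchors(self):
        seq = "A" * 20 + "QCGG" + "A" * 56 + "QCGG" + "YYYY"
        rec = ProteinRecord(id="a", sequence=seq)
        span = find_cbm1(rec)
        # exhaustive scan: rightmost QCGG start
        rightmost = max(i for i in range(len(seq) - 3) if seq[i : i + 4] == "QCGG")
        assert rightmost == 80
        assert span == Span(rightmost - 6, len(seq))

    def test_span_always_reaches_c_terminus(self, small_dataset):
        for rec in small_dataset.records:
            span = find_cbm1(rec)
            assert span is not None and span.end == len(rec)


class TestFindLinker:
    def test_identity_mapping_on_reference(self, reference_model):
        ref = reference_model.reference
        aln = align_to_reference(ref, reference_model)
        cbm1 = find_cbm1(ref)
        span, notes = find_linker(ref, cbm1, aln, reference_model)
        k = reference_model.fsnik_span.end - 1
        assert span == Span(k + 8, cbm1.start)
        assert notes == []

    def test_zero_length_linker_is_absent(self, reference_model):
        ref = reference_model.reference
        cbm1_ref = find_cbm1(ref)
        # candidate = reference with the 30-residue linker excised entirely
        seq = ref.sequence[: cbm1_ref.start - 30] + ref.sequence[cbm1_ref.start :]
        query = ProteinRecord(id="q", sequence=seq)
        aln = align_to_reference(query, reference_model)
        cbm1 = find_cbm1(query)
        span, notes = find_linker(query, cbm1, aln, reference_model)
        assert span is None
        assert "zero-length linker" in notes

    def test_insertion_lengthens_linker(self, reference_model):
        ref = reference_model.reference
        cbm1_ref = find_cbm1(ref)
        ref_linker_len = cbm1_ref.start - (reference_model.fsnik_span.end - 1 + 8)
        insert_at = cbm1_ref.start - 5
        seq = ref.sequence[:insert_at] + "GGG" + ref.sequence[insert_at:]
        query = ProteinRecord(id="q", sequence=seq)
        aln = align_to_reference(query, reference_model)
        cbm1 = find_cbm1(query)
        span, _ = find_linker(query, cbm1, aln, reference_model)
        assert len(span) == ref_linker_len + 3


class TestClassifyCbh:
    def test_identity_fully_occupied(self, reference_model):
        aln = align_to_reference(reference_model.reference, reference_model)
        occ, is_cbh = classify_cbh(aln, reference_model)
        assert occ == 1.0 and is_cbh

    def test_all_loops_deleted(self, reference_model):
        ref = reference_model.reference
        kept, prev = [], 0
        for w in reference_model.loop_windows:
            kept.append(ref.sequence[prev : w.start])
            prev = w.end
        kept.append(ref.sequence[prev:])
        query = ProteinRecord(id="q", sequence="".join(kept))
        aln = align_to_reference(query, reference_model)
        occ, is_cbh = classify_cbh(aln, reference_model)
        assert occ < 0.2 and not is_cbh

    def test_half_of_loop_positions_deleted(self, reference_model):
        ref = reference_model.reference
        w = reference_model.loop_windows[0]  # both windows have equal width
        query = ProteinRecord(id="q", sequence=ref.sequence[: w.start] + ref.sequence[w.end :])
        aln = align_to_reference(query, reference_model)
        occ, is_cbh = classify_cbh(aln, reference_model)
        assert occ == pytest.approx(0.5, abs=0.05) and not is_cbh

    def test_missing_loop_definitions_is_error(self, reference_model):
        model = ReferenceModel(reference=reference_model.reference, loop_windows=[])
        aln = align_to_reference(reference_model.reference, model)
        with pytest.raises(ValueError, match="loop definitions"):
            classify_cbh(aln, model)


class TestReferenceModel:
    def test_motif_must_occur_exactly_once(self):
        with pytest.raises(ValueError, match="exactly one"):
            ReferenceModel(reference=ProteinRecord(id="r", sequence="FSNIKAAFSNIK"))

    def test_yaml_round_trip(self, tmp_path, reference_model):
        from ghx.seqio import write_fasta

        write_fasta([reference_model.reference], tmp_path / "ref.fa")
        reference_model.to_yaml(tmp_path / "model.yaml", "ref.fa")
        again = ReferenceModel.from_yaml(tmp_path / "model.yaml")
        assert again.reference.sequence == reference_model.reference.sequence
        assert again.loop_windows == reference_model.loop_windows
        assert again.fsnik_span == reference_model.fsnik_span


class TestSegmentDataset:
    def test_partition_for_passing_records(self, small_dataset):
        anns = segment_dataset(small_dataset.records, small_dataset.model)
        by_id = {r.id: r for r in small_dataset.records}
        for a in anns:
            assert a.passed_filters
            assert a.catalytic_span.start == 0
            assert a.catalytic_span.end == a.linker_span.start
            assert a.linker_span.end == a.cbm1_span.start
            assert a.cbm1_span.end == len(by_id[a.id])

    def test_decoy_counts_match_truth(self):
        ds = generate_dataset(GeneratorConfig(
            n_class_a=20, n_class_b=20, seed=5,
            decoy_frac_no_qcgg=0.125, decoy_frac_loop_deleted=0.125,
        ))
        assert len(ds.records) == 50
        anns = segment_dataset(ds.records, ds.model)
        assert sum(a.passed_filters for a in anns) == 40
        truth = ds.truth_by_id()
        for a in anns:
            assert a.passed_filters == truth[a.id].passes_filters

    def test_failure_step_recorded(self, decoy_dataset):
        anns = segment_dataset(decoy_dataset.records, decoy_dataset.model)
        truth = decoy_dataset.truth_by_id()
        expected_note = {
            "no_qcgg": "filter:no-QCGG",
            "loop_deleted": "filter:loops-absent",
            "truncated": "filter:low-coverage",
        }
        for a in anns:
            t = truth[a.id]
            if t.decoy_type is not None:
                assert expected_note[t.decoy_type] in a.notes

    def test_order_invariance(self, small_dataset):
        anns1 = segment_dataset(small_dataset.records, small_dataset.model)
        reordered = list(reversed(small_dataset.records))
        anns2 = segment_dataset(reordered, small_dataset.model)
        m1 = {a.id: (a.linker_span, a.cbm1_span, a.passed_filters) for a in anns1}
        m2 = {a.id: (a.linker_span, a.cbm1_span, a.passed_filters) for a in anns2}
        assert m1 == m2

    def test_empty_input(self, reference_model):
        assert segment_dataset([], reference_model) == []

    def test_recovers_planted_spans(self, small_dataset):
        anns = segment_dataset(small_dataset.records, small_dataset.model)
        truth = small_dataset.truth_by_id()
        for a in anns:
            t = truth[a.id]
            assert a.cbm1_span == t.cbm1_span
            assert a.linker_span == t.linker_span
            assert a.catalytic_span == t.catalytic_span
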