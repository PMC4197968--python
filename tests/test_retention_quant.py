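import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intronret.annotation_model import extract_introns
from intronret.retention_quant import (
    BLOCK_COLUMNS,
    SampleQuant,
    apply_analysis_filters,
    compute_rpkm,
    count_features,
    flag_affected,
    fold_retention_change,
    load_fragments_sam,
    load_fragments_tsv,
    retention_index,
    retention_table,
    write_fragments_tsv,
)


def blocks_frame(rows):
    """rows: (fragment_id, chrom, strand, start, end, block_index, n_blocks)"""
    return pd.DataFrame(rows, columns=BLOCK_COLUMNS)


def make_toy_annotation():
    from intronret.annotation_model import GenomeAnnotation, TranscriptModel

    t = TranscriptModel("t1", "g1", "chr1", "+", [(100, 200), (300, 400), (900, 1000)])
    return GenomeAnnotation(transcripts={"t1": t}, chrom_lengths={"chr1": 1200})


@pytest.fixture
def toy_introns(toy_annotation):
    return extract_introns(toy_annotation.transcripts["t1"])


class TestCountFeatures:
    def test_read_inside_an_exon_is_exonic_only(self, toy_annotation, toy_introns):
        blocks = blocks_frame([("f0", "chr1", "+", 320, 370, 0, 1)])
        q = count_features(blocks, toy_annotation, toy_introns)
        assert q.transcript_counts["t1"] == 1
        assert all(v == 0 for v in q.intron_counts.values())

    def test_read_spanning_exon_intron_boundary_is_intronic(
        self, toy_annotation, toy_introns
    ):
        blocks = blocks_frame([("f0", "chr1", "+", 180, 230, 0, 1)])
        q = count_features(blocks, toy_annotation, toy_introns)
        assert q.intron_counts["t1.i1"] == 1
        assert q.transcript_counts["t1"] == 0  # not contained in exons

    def test_single_intronic_base_is_enough(self, toy_annotation, toy_introns):
        blocks = blocks_frame([("f0", "chr1", "+", 150, 201, 0, 1)])
        q = count_features(blocks, toy_annotation, toy_introns)
        assert q.intron_counts["t1.i1"] == 1

    def test_junction_spanning_read_must_match_exon_boundaries(
        self, toy_annotation, toy_introns
    ):
        compatible = blocks_frame(
            [("f0", "chr1", "+", 170, 200, 0, 2), ("f0", "chr1", "+", 300, 330, 1, 2)]
        )
        q = count_features(compatible, toy_annotation, toy_introns)
        assert q.transcript_counts["t1"] == 1
        # same blocks but the gap opens before the exon end: incompatible
        shifted = blocks_frame(
            [("f1", "chr1", "+", 170, 195, 0, 2), ("f1", "chr1", "+", 300, 330, 1, 2)]
        )
        q = count_features(shifted, toy_annotation, toy_introns)
        assert q.transcript_counts["t1"] == 0

    def test_fragment_counts_once_per_feature(self, toy_annotation, toy_introns):
        # both mates of one fragment inside the same intron
        blocks = blocks_frame(
            [("f0", "chr1", "+", 210, 240, 0, 2), ("f0", "chr1", "+", 260, 290, 1, 2)]
        )
        q = count_features(blocks, toy_annotation, toy_introns)
        assert q.intron_counts["t1.i1"] == 1

    def test_strandedness(self, toy_annotation, toy_introns):
        blocks = blocks_frame([("f0", "chr1", "-", 320, 370, 0, 1)])
        q = count_features(blocks, toy_annotation, toy_introns, stranded=True)
        assert q.transcript_counts["t1"] == 0
        q = count_features(blocks, toy_annotation, toy_introns, stranded=False)
        assert q.transcript_counts["t1"] == 1

    def test_unknown_chromosome_skipped_with_warning(
        self, toy_annotation, toy_introns, caplog
    ):
        blocks = blocks_frame(
            [
                ("f0", "chrUn", "+", 320, 370, 0, 1),
                ("f1", "chr1", "+", 320, 370, 0, 1),
            ]
        )
        with caplog.at_level("WARNING"):
            q = count_features(blocks, toy_annotation, toy_introns)
        assert "chrUn" in caplog.text
        assert q.transcript_counts["t1"] == 1

    def test_zero_library_size_is_an_error(self, toy_annotation, toy_introns):
        with pytest.raises(ValueError, match="library"):
            count_features(blocks_frame([]), toy_annotation, toy_introns)


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,library,expected",
        [(10, 1000, 1_000_000, 10.0), (0, 1000, 1_000_000, 0.0),
         (50, 500, 2_000_000, 50.0)],
    )
    def test_arithmetic(self, toy_annotation, toy_introns, count, length, library, expected):
        q = SampleQuant(
            "s", "control", 1, library,
            transcript_counts={"t1": count}, intron_counts={},
        )
        # t1 exonic length is 300; rescale count to emulate `length`
        q.transcript_counts["t1"] = count
        rpkm = count * 1e9 / (length * library)
        assert rpkm == pytest.approx(expected)
        compute_rpkm(q, toy_annotation, toy_introns)
        assert q.transcript_rpkm["t1"] == pytest.approx(
            count * 1e9 / (300 * library)
        )

    def test_zero_length_feature_is_an_error(self, toy_annotation):
        from intronret.annotation_model import IntronRecord

        bad = IntronRecord("z", "t1", "g1", "chr1", "+", 10, 10, 1, 1)
        q = SampleQuant("s", "control", 1, 1000, {"t1": 0}, {"z": 0})
        with pytest.raises(ValueError, match="length"):
            compute_rpkm(q, toy_annotation, [bad])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        count=st.integers(min_value=0, max_value=10_000),
        library=st.integers(min_value=1, max_value=10_000_000),
        factor=st.integers(min_value=2, max_value=100),
    )
    def test_scale_invariance(self, count, library, factor):
        """Scaling every count and the library size leaves RPKM unchanged."""
        annotation = make_toy_annotation()
        introns = extract_introns(annotation.transcripts["t1"])
        q1 = SampleQuant("a", "control", 1, library,
                         {"t1": count}, {i.intron_id: count for i in introns})
        q2 = SampleQuant("b", "control", 1, library * factor,
                         {"t1": count * factor},
                         {i.intron_id: count * factor for i in introns})
        compute_rpkm(q1, annotation, introns)
        compute_rpkm(q2, annotation, introns)
        assert q1.transcript_rpkm["t1"] == pytest.approx(q2.transcript_rpkm["t1"])
        for iid in q1.intron_rpkm:
            assert q1.intron_rpkm[iid] == pytest.approx(q2.intron_rpkm[iid])


def make_quant(annotation, introns, condition, replicate, t_rpkm, i_rpkm):
    q = SampleQuant(f"{condition}_r{replicate}", condition, replicate, 1_000_000,
                    {"t1": 0}, {i.intron_id: 0 for i in introns})
    q.transcript_rpkm = {"t1": t_rpkm}
    q.intron_rpkm = {i.intron_id: i_rpkm for i in introns}
    return q


class TestAnalysisFilters:
    @pytest.mark.parametrize("rpkm,kept", [(12.0, True), (9.0, False), (10.0, False)])
    def test_transcript_threshold_is_strict(self, toy_annotation, toy_introns, rpkm, kept):
        quants = [
            make_quant(toy_annotation, toy_introns, "control", r, rpkm, rpkm)
            for r in (1, 2)
        ]
        passed_t, _ = apply_analysis_filters(quants, toy_introns)
        assert ("t1" in passed_t) is kept

    def test_intron_fraction_any_replicate(self, toy_annotation, toy_introns):
        # 12.5% in one replicate is enough; 8% everywhere is not
        q1 = make_quant(toy_annotation, toy_introns, "control", 1, 12.0, 1.5)
        q2 = make_quant(toy_annotation, toy_introns, "control", 2, 12.0, 0.5)
        _, passed = apply_analysis_filters([q1, q2], toy_introns)
        assert passed == {i.intron_id for i in toy_introns}
        q1 = make_quant(toy_annotation, toy_introns, "control", 1, 12.0, 0.96)
        q2 = make_quant(toy_annotation, toy_introns, "control", 2, 12.0, 0.96)
        _, passed = apply_analysis_filters([q1, q2], toy_introns)
        assert passed == set()

    def test_scope_control_ignores_knockdown_evidence(self, toy_annotation, toy_introns):
        ctrl = make_quant(toy_annotation, toy_introns, "control", 1, 12.0, 0.5)
        kd = make_quant(toy_annotation, toy_introns, "kd", 1, 12.0, 6.0)
        _, any_scope = apply_analysis_filters([ctrl, kd], toy_introns)
        _, ctrl_scope = apply_analysis_filters(
            [ctrl, kd], toy_introns, intron_filter_scope="control"
        )
        assert any_scope and not ctrl_scope

    def test_no_control_samples_is_an_error(self, toy_annotation, toy_introns):
        kd = make_quant(toy_annotation, toy_introns, "kd", 1, 12.0, 6.0)
        with pytest.raises(ValueError, match="control"):
            apply_analysis_filters([kd], toy_introns)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        rpkm=st.floats(min_value=0.0, max_value=100.0),
        bump=st.floats(min_value=0.0, max_value=50.0),
    )
    def test_raising_the_threshold_never_adds_transcripts(self, rpkm, bump):
        annotation = make_toy_annotation()
        introns = extract_introns(annotation.transcripts["t1"])
        quants = [make_quant(annotation, introns, "control", 1, rpkm, rpkm)]
        lo, _ = apply_analysis_filters(quants, introns, min_transcript_rpkm=10.0)
        hi, _ = apply_analysis_filters(quants, introns, min_transcript_rpkm=10.0 + bump)
        assert hi <= lo


class TestRetentionMath:
    def test_retention_index_limits(self):
        assert retention_index(2.0, 10.0) == pytest.approx(0.2)
        assert retention_index(10.0, 10.0) == pytest.approx(1.0)
        assert retention_index(0.0, 10.0) == 0.0
        with pytest.raises(ValueError):
            retention_index(1.0, 0.0)

    def test_fold_change(self):
        assert fold_retention_change(0.3, 0.3, eps=0.01) == pytest.approx(1.0)
        assert fold_retention_change(0.3, 0.3, eps=5.0) == pytest.approx(1.0)
        assert fold_retention_change(0.4, 0.1, eps=0.0) == pytest.approx(4.0)

    def test_affected_window(self):
        assert flag_affected([3.5, 1.1])
        assert not flag_affected([1.5, 1.8])
        assert not flag_affected([12.0, 1.0])  # above the window
        assert flag_affected([2.0, 1.0]) and flag_affected([10.0, 1.0])


class TestRetentionTable:
    def test_indices_folds_and_affected_flags(self, toy_annotation, toy_introns):
        ctrl = [make_quant(toy_annotation, toy_introns, "control", r, 20.0, 2.0)
                for r in (1, 2)]
        kd = [make_quant(toy_annotation, toy_introns, "knockdown", r, 20.0, 8.0)
              for r in (1, 2)]
        table = retention_table(ctrl + kd, toy_annotation, toy_introns)
        assert len(table) == 2
        row = table.iloc[0]
        assert row["index_control"] == pytest.approx(0.1)
        assert row["index_knockdown"] == pytest.approx(0.4)
        assert row["fold_knockdown"] == pytest.approx(0.41 / 0.11)
        assert bool(row["affected"])


class TestFragmentIO:
    def test_tsv_round_trip(self, tmp_path, toy_annotation, toy_introns):
        blocks = blocks_frame(
            [
                ("f0", "chr1", "+", 170, 200, 0, 2),
                ("f0", "chr1", "+", 300, 330, 1, 2),
                ("f1", "chr1", "-", 210, 260, 0, 1),
            ]
        )
        path = tmp_path / "frags.tsv"
        write_fragments_tsv(blocks, str(path))
        loaded = load_fragments_tsv(str(path))
        a = blocks.sort_values(["fragment_id", "block_index"]).reset_index(drop=True)
        b = loaded.sort_values(["fragment_id", "block_index"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_dtype=False)

    def test_sam_mate_merging_and_multimapper_exclusion(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\n"
            "@SQ\tSN:chr1\tLN:1200\n"
            # proper pair, overlapping mates -> one fragment, merged block
            "p1\t99\tchr1\t101\t60\t50M\t=\t131\t80\t*\t*\n"
            "p1\t147\tchr1\t131\t60\t50M\t=\t101\t-80\t*\t*\n"
            # multimapper via NH tag: excluded
            "m1\t0\tchr1\t301\t60\t50M\t*\t0\t0\t*\t*\tNH:i:4\n"
            # low mapping quality: excluded
            "m2\t0\tchr1\t301\t0\t50M\t*\t0\t0\t*\t*\n"
        )
        blocks = load_fragments_sam(str(sam))
        assert set(blocks["fragment_id"]) == {"p1"}
        assert len(blocks) == 1  # overlapping mates merged into one block
        assert (blocks.iloc[0]["start"], blocks.iloc[0]["end"]) == (100, 180)
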