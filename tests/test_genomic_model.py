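"""Domain types, GTF/MAF I/O, interval index, and transcript merging."""

import numpy as np
import pytest

from lncorth.genomic_model import (
    AlignmentBlock,
    AnnotationSet,
    Interval,
    Transcript,
    merge_transcripts,
    read_gtf,
    read_maf,
    reverse_complement,
    write_gtf,
    write_maf,
)
from helpers import make_transcript, random_annotation


class TestTypes:
    def test_interval_rejects_bad_coordinates(self):
        with pytest.raises(ValueError):
            Interval("chr1", 10, 10)
        with pytest.raises(ValueError):
            Interval("chr1", -1, 5)

    def test_transcript_sorts_exons_and_derives_chain(self):
        t = make_transcript("t1", "g1", [(300, 400), (0, 100)])
        assert [(e.start, e.end) for e in t.exons] == [(0, 100), (300, 400)]
        assert t.intron_chain == ((100, 300),)
        assert t.length == 200

    def test_transcript_rejects_overlapping_exons(self):
        with pytest.raises(ValueError):
            make_transcript("t1", "g1", [(0, 100), (50, 150)])

    def test_spliced_sequence_minus_strand_is_reverse_complement(self):
        genome = {"chr1": "AACCGGTTAACC"}
        plus = make_transcript("t", "g", [(0, 4), (8, 12)])
        minus = make_transcript("t2", "g", [(0, 4), (8, 12)], strand="-")
        assert plus.spliced_sequence(genome) == "AACCAACC"
        assert minus.spliced_sequence(genome) == reverse_complement("AACCAACC")

    def test_alignment_block_invariants(self):
        with pytest.raises(ValueError):
            AlignmentBlock(
                Interval("a", 0, 4), Interval("b", 0, 4), "ACGT", "ACG"
            )
        with pytest.raises(ValueError):  # ungapped length mismatch
            AlignmentBlock(
                Interval("a", 0, 5), Interval("b", 0, 4), "ACG-T", "ACGT-"
            )
        with pytest.raises(ValueError):  # all-gap column
            AlignmentBlock(
                Interval("a", 0, 3), Interval("b", 0, 3), "AC-G", "AC-G"
            )


class TestGtf:
    def test_coordinate_convention(self, tmp_path):
        path = tmp_path / "one.gtf"
        path.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        annotation = read_gtf(path)
        exon = annotation["t"].exons[0]
        assert (exon.start, exon.end) == (0, 100)
        assert len(exon) == 100

    def test_two_exon_lines_one_transcript_even_out_of_order(self, tmp_path):
        path = tmp_path / "two.gtf"
        path.write_text(
            'chr1\tx\texon\t501\t600\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        annotation = read_gtf(path)
        t = annotation["t"]
        assert t.n_exons == 2
        assert t.intron_chain == ((100, 500),)

    def test_agrees_with_reference_gtf_reader(self, tmp_path):
        gffutils = pytest.importorskip("gffutils")
        rng = np.random.default_rng(5)
        annotation = random_annotation(rng, 20)
        path = tmp_path / "random.gtf"
        write_gtf(annotation, path)
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        for t in annotation:
            exons = sorted(
                (
                    f
                    for f in db.features_of_type("exon")
                    if f.attributes["transcript_id"][0] == t.transcript_id
                ),
                key=lambda f: f.start,
            )
            assert [(f.start - 1, f.end) for f in exons] == [
                (e.start, e.end) for e in t.exons
            ]

    def test_errors_name_the_line(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text("chr1\tx\texon\t1\t100\t.\t+\t.\n")
        with pytest.raises(ValueError, match="line 1"):
            read_gtf(path)
        path.write_text('chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g";\n')
        with pytest.raises(ValueError, match="transcript_id"):
            read_gtf(path)

    def test_round_trip_random_annotations(self, tmp_path):
        rng = np.random.default_rng(11)
        annotation = random_annotation(rng, 100)
        path = tmp_path / "rt.gtf"
        write_gtf(annotation, path)
        back = read_gtf(path)
        assert len(back) == len(annotation)
        for t in annotation:
            b = back[t.transcript_id]
            assert b.gene_id == t.gene_id
            assert b.exons == t.exons

    def test_empty_set_round_trips(self, tmp_path):
        path = tmp_path / "empty.gtf"
        write_gtf(AnnotationSet(), path)
        assert len(read_gtf(path)) == 0


class TestMaf:
    def test_gap_free_identical_block(self, tmp_path):
        path = tmp_path / "a.maf"
        path.write_text(
            "##maf version=1\n"
            "a\n"
            "s src 0 10 + 100 ACGTACGTAC\n"
            "s tgt 5 10 + 100 ACGTACGTAC\n"
        )
        (block,) = read_maf(path)
        assert len(block.src) == 10 and len(block.tgt) == 10
        assert block.tgt.start == 5

    def test_target_gap_shortens_target_interval(self, tmp_path):
        path = tmp_path / "b.maf"
        path.write_text(
            "##maf version=1\na\n"
            "s src 0 10 + 100 ACGTACGTAC\n"
            "s tgt 0 9 + 100 ACGTAC-TAC\n"
        )
        (block,) = read_maf(path)
        assert len(block.src) == 10
        assert len(block.tgt) == 9

    def test_minus_strand_target_normalised_to_forward(self, tmp_path):
        # target row text is the reverse complement of the forward-strand
        # slice [88, 98) of a 100 bp sequence (MAF start 2, size 10, '-')
        fwd = "AACCGGTTAA"
        path = tmp_path / "c.maf"
        path.write_text(
            "##maf version=1\na\n"
            f"s src 0 10 + 100 ACGTACGTAC\n"
            f"s tgt 2 10 - 100 {reverse_complement(fwd)}\n"
        )
        (block,) = read_maf(path)
        assert (block.tgt.start, block.tgt.end, block.tgt.strand) == (88, 98, "-")
        assert block.tgt_text == reverse_complement(fwd)

    def test_rejects_non_pairwise_blocks(self, tmp_path):
        path = tmp_path / "d.maf"
        path.write_text(
            "##maf version=1\na\n"
            "s a 0 4 + 10 ACGT\n"
            "s b 0 4 + 10 ACGT\n"
            "s c 0 4 + 10 ACGT\n"
        )
        with pytest.raises(ValueError, match="pairwise"):
            read_maf(path)

    def test_write_read_round_trip(self, tmp_path):
        blocks = [
            AlignmentBlock(
                Interval("s", 10, 20), Interval("t", 50, 59, "-"),
                "ACGTACGTAC", "ACGTAC-TAC",
            )
        ]
        path = tmp_path / "rt.maf"
        write_maf(blocks, path)
        assert read_maf(path) == blocks


class TestIntervalIndex:
    def test_overlap_queries_match_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        annotation = random_annotation(rng, 500, seq_ids=("chr1",))
        transcripts = list(annotation)
        for _ in range(1000):
            start = int(rng.integers(0, 110_000))
            end = start + int(rng.integers(1, 5000))
            got = {t.transcript_id for t in annotation.overlapping("chr1", start, end)}
            expected = {
                t.transcript_id
                for t in transcripts
                if t.start < end and start < t.end
            }
            assert got == expected


class TestMerge:
    def test_same_transcript_in_three_samples_collapses(self):
        sets = [
            AnnotationSet([make_transcript("t1", "g1", [(0, 100), (200, 300)])])
            for _ in range(3)
        ]
        merged = merge_transcripts(sets)
        assert len(merged) == 1
        assert merged["t1"].samples == {"sample_0", "sample_1", "sample_2"}

    def test_terminal_ends_take_union_span(self):
        a = AnnotationSet([make_transcript("tA", "g", [(50, 100), (200, 300)])])
        b = AnnotationSet([make_transcript("tB", "g", [(0, 100), (200, 320)])])
        merged = merge_transcripts([a, b])
        assert len(merged) == 1
        t = next(iter(merged))
        assert (t.start, t.end) == (0, 320)
        assert t.intron_chain == ((100, 200),)

    def test_one_bp_intron_difference_keeps_both(self):
        a = AnnotationSet([make_transcript("tA", "g", [(0, 100), (200, 300)])])
        b = AnnotationSet([make_transcript("tB", "g", [(0, 101), (200, 300)])])
        assert len(merge_transcripts([a, b])) == 2

    def test_single_exon_merges_only_on_exact_identity(self):
        a = AnnotationSet([make_transcript("tA", "g", [(0, 100)])])
        b = AnnotationSet([make_transcript("tB", "g", [(0, 101)])])
        c = AnnotationSet([make_transcript("tC", "g", [(0, 100)])])
        assert len(merge_transcripts([a, b, c])) == 2

    def test_merge_is_idempotent_and_order_independent(self):
        rng = np.random.default_rng(9)
        a = random_annotation(rng, 30)
        b = random_annotation(np.random.default_rng(9), 30)  # same content
        ab = merge_transcripts([a, b])
        ba = merge_transcripts([b, a])
        again = merge_transcripts([ab])
        assert {t.transcript_id for t in ab} == {t.transcript_id for t in ba}
        for t in ab:
            assert ba[t.transcript_id].exons == t.exons
            assert again[t.transcript_id].exons == t.exons

    def test_mixed_genomes_rejected(self):
        a = AnnotationSet([make_transcript("tA", "g", [(0, 100), (200, 300)])])
        b = AnnotationSet(
            [make_transcript("tB", "g", [(0, 100), (200, 300)], seq="weird")]
        )
        with pytest.raises(ValueError, match="mixed"):
            merge_transcripts([a, b], genome_seq_ids={"chr1", "chr2"})
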