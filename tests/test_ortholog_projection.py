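"""Exon/gene projection through alignment blocks and ortholog calling."""

import numpy as np
import pytest

from lncorth.genomic_model import AlignmentBlock, AnnotationSet, Interval
from lncorth.ortholog_projection import (
    build_target_annotation,
    project_exon,
    project_gene,
    spliced_alignment,
)
from helpers import make_transcript


def block(src_start, tgt_start, src_text, tgt_text, tgt_strand="+", src_seq="chrS", tgt_seq="chrT"):
    src_len = len(src_text) - src_text.count("-")
    tgt_len = len(tgt_text) - tgt_text.count("-")
    return AlignmentBlock(
        Interval(src_seq, src_start, src_start + src_len),
        Interval(tgt_seq, tgt_start, tgt_start + tgt_len, tgt_strand),
        src_text,
        tgt_text,
    )


def brute_force_exon_identity(exon, blocks):
    """Column-by-column oracle independent of the projection walker."""
    aligned = matches = 0
    for b in blocks:
        src_pos = b.src.start
        for s, t in zip(b.src_text, b.tgt_text):
            if s == "-":
                continue
            if exon.start <= src_pos < exon.end:
                aligned += 1
                if t != "-" and s.upper() == t.upper() and s.upper() != "N":
                    matches += 1
            src_pos += 1
    return aligned, matches


class TestProjectExon:
    def test_identical_gap_free_block(self):
        b = block(100, 500, "ACGTACGTAC", "ACGTACGTAC")
        p = project_exon(Interval("chrS", 100, 110), [b])
        assert p.identity == 1.0 and p.coverage == 1.0
        assert (p.tgt_interval.start, p.tgt_interval.end) == (500, 510)

    def test_exon_outside_blocks_is_absent(self):
        b = block(100, 500, "ACGT", "ACGT")
        p = project_exon(Interval("chrS", 1000, 1100), [b])
        assert p.tgt_interval is None and p.coverage == 0.0

    def test_hand_counted_mismatches_and_target_gaps(self):
        # 20 source positions: 3 mismatches, 2 target-gap columns
        src_text = "AAAAAAAAAAAAAAAAAAAA"
        tgt_text = "AAACCCAAAAAAAAAA-A-A"  # mismatch at cols 3,4,5; gaps at 16,18
        b = block(0, 0, src_text, tgt_text)
        p = project_exon(Interval("chrS", 0, 20), [b])
        assert p.aligned_columns == 20
        assert p.matches == 15
        assert p.identity == pytest.approx(15 / 20)

    def test_source_gap_columns_are_not_source_positions(self):
        b = block(0, 0, "AC-GT", "ACAGT")
        p = project_exon(Interval("chrS", 0, 4), [b])
        assert p.aligned_columns == 4 and p.matches == 4
        assert len(p.tgt_interval) == 5  # target spans the inserted base

    def test_n_bases_count_as_mismatches(self):
        b = block(0, 0, "ANNA", "ANNA")
        p = project_exon(Interval("chrS", 0, 4), [b])
        assert p.matches == 2

    def test_overlapping_source_blocks_rejected(self):
        b1 = block(0, 0, "ACGTACGT", "ACGTACGT")
        b2 = block(4, 100, "ACGTACGT", "ACGTACGT")
        with pytest.raises(ValueError, match="overlapping"):
            project_exon(Interval("chrS", 0, 12), [b1, b2])

    def test_minus_strand_block_maps_to_forward_target_coordinates(self):
        b = block(0, 50, "ACGTACGTAC", "ACGTACGTAC", tgt_strand="-")
        p = project_exon(Interval("chrS", 2, 8), [b])
        # alignment column i maps to forward coordinate tgt.end-1-i
        assert (p.tgt_interval.start, p.tgt_interval.end) == (52, 58)
        assert p.tgt_interval.strand == "-"

    def test_matches_brute_force_on_random_blocks(self):
        rng = np.random.default_rng(21)
        bases = list("ACGTN")
        for _ in range(100):
            n_col = int(rng.integers(30, 120))
            src_chars, tgt_chars = [], []
            for _ in range(n_col):
                r = rng.random()
                if r < 0.08:
                    src_chars.append("-")
                    tgt_chars.append(bases[rng.integers(4)])
                elif r < 0.16:
                    src_chars.append(bases[rng.integers(4)])
                    tgt_chars.append("-")
                else:
                    src_chars.append(bases[rng.integers(5)])
                    tgt_chars.append(bases[rng.integers(5)])
            src_text, tgt_text = "".join(src_chars), "".join(tgt_chars)
            if not (len(src_text) - src_text.count("-")) or not (
                len(tgt_text) - tgt_text.count("-")
            ):
                continue
            b = block(int(rng.integers(0, 1000)), int(rng.integers(0, 1000)),
                      src_text, tgt_text)
            exon = Interval(
                "chrS", b.src.start, b.src.start + int(rng.integers(1, len(b.src) + 1))
            )
            p = project_exon(exon, [b])
            aligned, matches = brute_force_exon_identity(exon, [b])
            assert (p.aligned_columns, p.matches) == (aligned, matches)


class TestProjectGene:
    def make_gene(self, identity_fraction, n=100):
        n_mismatch = round(n * (1 - identity_fraction))
        src_text = "A" * n
        tgt_text = "C" * n_mismatch + "A" * (n - n_mismatch)
        b = block(0, 0, src_text, tgt_text)
        t = make_transcript("t", "g", [(0, n // 2), (n // 2, n)], seq="chrS")
        return [t], [b]

    def test_identity_at_threshold_is_called(self):
        ts, bs = self.make_gene(0.60)
        assert project_gene(ts, bs).ortholog_call is True

    def test_identity_just_below_threshold_is_not_called(self):
        ts, bs = self.make_gene(0.59)
        gp = project_gene(ts, bs)
        assert gp.ortholog_call is False and gp.reason == "low_identity"

    def test_low_coverage_blocks_call(self):
        b = block(0, 0, "A" * 30, "A" * 30)
        t = make_transcript("t", "g", [(0, 50), (60, 100)], seq="chrS")
        gp = project_gene([t], [b])
        assert gp.gene_identity == 1.0
        assert gp.ortholog_call is False and gp.reason == "low_coverage"

    def test_split_projection_refused(self):
        b1 = block(0, 0, "A" * 40, "A" * 40, tgt_seq="chrT")
        b2 = block(60, 0, "A" * 40, "A" * 40, tgt_seq="chrT2")
        t = make_transcript("t", "g", [(0, 40), (60, 100)], seq="chrS")
        gp = project_gene([t], [b1, b2])
        assert gp.ortholog_call is False and gp.reason == "split_projection"

    def test_raising_threshold_never_adds_calls(self, default_world):
        from lncorth.genomic_model import read_maf

        blocks = read_maf(default_world.paths["alignment.maf"])
        lnc = [l for l in default_world.loci if l.locus_class.startswith("lnc_")]
        previous = None
        for thr in (0.3, 0.5, 0.6, 0.8, 0.95):
            called = {
                l.gene_id
                for l in lnc
                if project_gene([l.transcript], blocks, identity_threshold=thr).ortholog_call
            }
            if previous is not None:
                assert called <= previous
            previous = called

    def test_planted_identities_recovered_with_perfect_separation(self, default_world):
        """Sensitivity and specificity are both 1.0 when planted identities
        sit far from the 0.60 threshold (0.85 and 0.40)."""
        from lncorth.genomic_model import read_maf

        blocks = read_maf(default_world.paths["alignment.maf"])
        truth = default_world.truth
        for locus in default_world.loci:
            if not locus.locus_class.startswith("lnc_"):
                continue
            gp = project_gene([locus.transcript], blocks)
            planted = truth.loc[locus.gene_id, "planted_identity"]
            should_call = locus.in_target and planted >= 0.60
            assert gp.ortholog_call == should_call, locus.gene_id

    def test_reciprocal_projection_contains_original_exons(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        b = block(1000, 3000, seq, seq)
        inverted = AlignmentBlock(b.tgt, b.src, b.tgt_text, b.src_text)
        exon = Interval("chrS", 1050, 1150)
        fwd = project_exon(exon, [b])
        back = project_exon(
            Interval("chrT", fwd.tgt_interval.start, fwd.tgt_interval.end), [inverted]
        )
        assert back.tgt_interval.start <= exon.start
        assert back.tgt_interval.end >= exon.end


class TestBuildTargetAnnotation:
    def test_full_projection_keeps_exon_count(self):
        src_text = "A" * 300
        b = block(0, 0, src_text, src_text)
        t = make_transcript("t", "g", [(0, 100), (120, 200), (240, 300)], seq="chrS")
        source = AnnotationSet([t])
        gp = project_gene([t], [b])
        target, summary, flags = build_target_annotation(source, {"g": gp})
        assert summary == {
            "n_genes": 1,
            "n_transcripts": 1,
            "n_ge_min_bp": 1,
            "max_spliced_bp": 240,
        }
        assert target["t"].n_exons == 3 and flags["t"] == []

    def test_unprojected_middle_exon_gives_partial_two_exon_model(self):
        b1 = block(0, 0, "A" * 100, "A" * 100)
        b2 = block(240, 240, "A" * 60, "A" * 60)
        t = make_transcript("t", "g", [(0, 100), (120, 200), (240, 300)], seq="chrS")
        source = AnnotationSet([t])
        gp = project_gene([t], [b1, b2])
        target, _summary, flags = build_target_annotation(source, {"g": gp})
        assert target["t"].n_exons == 2
        assert "partial" in flags["t"]

    def test_summary_is_self_consistent_on_synthetic_world(self, default_world):
        from lncorth.genomic_model import read_maf

        blocks = read_maf(default_world.paths["alignment.maf"])
        source = AnnotationSet(
            [l.transcript for l in default_world.loci if l.locus_class.startswith("lnc_")]
        )
        projections = {
            gid: project_gene(source.gene_transcripts(gid), blocks)
            for gid in source.gene_ids
        }
        target, summary, _ = build_target_annotation(source, projections)
        lengths = [t.length for t in target]
        assert summary["n_transcripts"] == len(lengths)
        assert summary["n_ge_min_bp"] == sum(1 for L in lengths if L >= 200)
        assert summary["max_spliced_bp"] == (max(lengths) if lengths else 0)
        assert summary["n_genes"] == len({t.gene_id for t in target})


class TestSplicedAlignment:
    def test_concatenates_exons_and_keeps_target_gaps(self):
        b = block(0, 0, "ACGTAC-GTACGT", "ACCTACAGT-CGT")
        t = make_transcript("t", "g", [(0, 4), (8, 12)], seq="chrS")
        src_aln, tgt_aln = spliced_alignment(t, [b])
        # source positions 0-3 then 8-11 (source gap column skipped)
        assert src_aln == "ACGTACGT"
        assert tgt_aln == "ACCT-CGT"

    def test_minus_strand_reads_in_transcript_sense(self):
        b = block(0, 0, "ACGTACGT", "ACGAACGT")
        plus = make_transcript("t", "g", [(0, 8)], seq="chrS")
        minus = make_transcript("t2", "g2", [(0, 8)], seq="chrS", strand="-")
        sp, tp = spliced_alignment(plus, [b])
        sm, tm = spliced_alignment(minus, [b])
        from lncorth.genomic_model import reverse_complement

        assert sm == reverse_complement(sp)
        assert tm == reverse_complement(tp)
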