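"""Project lncRNA exons through pairwise alignment blocks into a target genome.

Identity accounting, fixed once for the whole package: walking alignment
columns over a source exon, a column where the target holds a gap counts as
an aligned non-match; a column where the source holds a gap is not a source
position and is skipped; N on either side is a non-match.  Identity is
matches / aligned columns; coverage is the fraction of exon bp that lie
inside alignment blocks.  Gene identity is the match-weighted mean over exon
projections, thresholded (default 0.60) together with coverage (default
0.5) for the ortholog call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genomic_model import AlignmentBlock, AnnotationSet, Interval, Transcript


@dataclass
class ExonProjection:
    src_exon: Interval
    tgt_interval: Interval | None
    aligned_columns: int
    matches: int
    coverage: float

    @property
    def identity(self) -> float | None:
        if self.aligned_columns == 0:
            return None
        return self.matches / self.aligned_columns


@dataclass
class GeneProjection:
    gene_id: str
    exon_projections: list[ExonProjection]
    gene_identity: float | None
    gene_coverage: float
    ortholog_call: bool
    reason: str
    tgt_transcripts: list[Transcript] = field(default_factory=list)


def _check_blocks(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    blocks = sorted(blocks, key=lambda b: (b.src.seq_id, b.src.start))
    prev: AlignmentBlock | None = None
    for b in blocks:
        if (
            prev is not None
            and prev.src.seq_id == b.src.seq_id
            and b.src.start < prev.src.end
        ):
            raise ValueError(
                f"overlapping source blocks at {b.src.seq_id}:{b.src.start}; "
                "projection would be ambiguous"
            )
        prev = b
    return blocks


def _walk_block(block: AlignmentBlock, exon: Interval):
    """Yield (src_pos, tgt_pos_or_None, src_char, tgt_char) for exon columns.

    src_pos runs in forward coordinates (source rows are forward-strand);
    tgt positions are mapped to forward coordinates regardless of the target
    row's alignment orientation.
    """
    src_pos = block.src.start
    tgt_off = 0  # non-gap characters consumed in the target row
    minus = block.tgt.strand == "-"
    for s_ch, t_ch in zip(block.src_text, block.tgt_text):
        t_here = None
        if t_ch != "-":
            t_here = (
                block.tgt.end - 1 - tgt_off if minus else block.tgt.start + tgt_off
            )
            tgt_off += 1
        if s_ch != "-":
            if exon.start <= src_pos < exon.end:
                yield src_pos, t_here, s_ch, t_ch
            src_pos += 1


def project_exon(exon: Interval, blocks: list[AlignmentBlock]) -> ExonProjection:
    """Project one exon through sorted, source-disjoint alignment blocks.

    Returns aligned-column/match counts, the projected target interval
    (min/max target positions hit), and coverage.  An exon entirely outside
    all blocks yields an absent projection with coverage 0.
    """
    blocks = _check_blocks(
        [b for b in blocks if b.src.seq_id == exon.seq_id and b.src.overlaps(exon)]
    )
    aligned = 0
    matches = 0
    tgt_min = None
    tgt_max = None
    tgt_seq = None
    tgt_strand = None
    for block in blocks:
        for _src_pos, tgt_pos, s_ch, t_ch in _walk_block(block, exon):
            aligned += 1
            su, tu = s_ch.upper(), t_ch.upper()
            if tu != "-" and su == tu and su != "N":
                matches += 1
            if tgt_pos is not None:
                if tgt_seq is None:
                    tgt_seq = block.tgt.seq_id
                    tgt_strand = block.tgt.strand
                elif tgt_seq != block.tgt.seq_id or tgt_strand != block.tgt.strand:
                    tgt_seq = "__mixed__"
                tgt_min = tgt_pos if tgt_min is None else min(tgt_min, tgt_pos)
                tgt_max = tgt_pos if tgt_max is None else max(tgt_max, tgt_pos)
    coverage = aligned / len(exon)
    tgt_iv = None
    if tgt_min is not None and tgt_seq != "__mixed__":
        # projected feature strand: exon strand composed with block orientation
        strand = exon.strand if tgt_strand == "+" else ("-" if exon.strand == "+" else "+")
        tgt_iv = Interval(tgt_seq, tgt_min, tgt_max + 1, strand)
    return ExonProjection(
        src_exon=exon,
        tgt_interval=tgt_iv,
        aligned_columns=aligned,
        matches=matches,
        coverage=coverage,
    )


def project_transcript_exons(
    transcript: Transcript, blocks: list[AlignmentBlock]
) -> list[ExonProjection]:
    return [project_exon(e, blocks) for e in transcript.exons]


def project_gene(
    gene_transcripts: list[Transcript],
    blocks: list[AlignmentBlock],
    identity_threshold: float = 0.60,
    coverage_threshold: float = 0.5,
) -> GeneProjection:
    """Aggregate exon projections of a gene into an ortholog call.

    gene_identity is the aligned-column-weighted mean over projected exons;
    the call requires identity >= identity_threshold (boundary inclusive:
    "at least 60% identity") AND coverage >= coverage_threshold, and all
    projected exons landing on one target sequence and strand (otherwise the
    call is refused with reason ``split_projection``).
    """
    gene_id = gene_transcripts[0].gene_id
    projections: list[ExonProjection] = []
    for t in gene_transcripts:
        projections.extend(project_transcript_exons(t, blocks))
    total_cols = sum(p.aligned_columns for p in projections)
    total_matches = sum(p.matches for p in projections)
    total_bp = sum(len(p.src_exon) for p in projections)
    identity = total_matches / total_cols if total_cols else None
    coverage = total_cols / total_bp if total_bp else 0.0

    targets = {
        (p.tgt_interval.seq_id, p.tgt_interval.strand)
        for p in projections
        if p.tgt_interval is not None
    }
    meets = (
        identity is not None
        and identity >= identity_threshold
        and coverage >= coverage_threshold
    )
    if not targets:
        call, reason = False, "no_projection"
    elif len(targets) > 1:
        call, reason = False, "split_projection"
    elif meets:
        call, reason = True, "ok"
    elif identity is not None and identity < identity_threshold:
        call, reason = False, "low_identity"
    else:
        call, reason = False, "low_coverage"
    return GeneProjection(
        gene_id=gene_id,
        exon_projections=projections,
        gene_identity=identity,
        gene_coverage=coverage,
        ortholog_call=bool(call),
        reason=reason,
    )


def build_target_annotation(
    source_annotation: AnnotationSet,
    projections: dict[str, GeneProjection],
    min_transcript_bp: int = 200,
) -> tuple[AnnotationSet, dict[str, object], dict[str, list[str]]]:
    """Assemble projected exons into target-genome transcript models.

    For every source transcript of a projected gene, projected exon
    intervals (sorted by target coordinate) become a target transcript with
    the same ids; unprojected exons are dropped and the transcript flagged
    ``partial``; models shorter than ``min_transcript_bp`` are retained but
    flagged ``short``.  Returns (target annotation, summary, flags-by-transcript).

    Summary keys: n_genes, n_transcripts, n_ge_min_bp, max_spliced_bp.
    """
    target = AnnotationSet()
    flags: dict[str, list[str]] = {}
    genes_with_models: set[str] = set()
    for gene_id, gp in sorted(projections.items()):
        proj_by_interval = {
            (p.src_exon.start, p.src_exon.end): p for p in gp.exon_projections
        }
        for t in source_annotation.gene_transcripts(gene_id):
            tgt_exons = []
            partial = False
            for e in t.exons:
                p = proj_by_interval.get((e.start, e.end))
                if p is None or p.tgt_interval is None:
                    partial = True
                    continue
                tgt_exons.append(p.tgt_interval)
            if not tgt_exons:
                flags[t.transcript_id] = ["unprojected"]
                continue
            tflags = []
            if partial:
                tflags.append("partial")
            # merge projected exons that abut or overlap on the target
            tgt_exons.sort(key=lambda iv: iv.start)
            merged: list[Interval] = []
            for iv in tgt_exons:
                if merged and iv.start < merged[-1].end:
                    last = merged[-1]
                    merged[-1] = Interval(
                        last.seq_id, last.start, max(last.end, iv.end), last.strand
                    )
                    tflags.append("merged_exons")
                else:
                    merged.append(iv)
            model = Transcript(
                transcript_id=t.transcript_id,
                gene_id=gene_id,
                exons=merged,
                biotype=t.biotype,
            )
            if model.length < min_transcript_bp:
                tflags.append("short")
            flags[t.transcript_id] = tflags
            target.add(model)
            genes_with_models.add(gene_id)
            gp.tgt_transcripts.append(model)
    lengths = [t.length for t in target]
    summary = {
        "n_genes": len(genes_with_models),
        "n_transcripts": len(target),
        "n_ge_min_bp": sum(1 for L in lengths if L >= min_transcript_bp),
        "max_spliced_bp": max(lengths) if lengths else 0,
    }
    return target, summary, flags


def spliced_alignment(
    transcript: Transcript, blocks: list[AlignmentBlock]
) -> tuple[str, str]:
    """Gapped pairwise alignment of a transcript's spliced source sequence
    against its projected target sequence, concatenated across exons in
    transcript (5'→3') order.

    Used by the coding-conservation screen.  Columns where the source has a
    gap are omitted (they are not transcript positions); target-gap columns
    are kept as '-'.
    """
    src_chars: list[str] = []
    tgt_chars: list[str] = []
    for exon in transcript.exons:
        use = _check_blocks(
            [
                b
                for b in blocks
                if b.src.seq_id == exon.seq_id and b.src.overlaps(exon)
            ]
        )
        for block in use:
            for _sp, _tp, s_ch, t_ch in _walk_block(block, exon):
                src_chars.append(s_ch.upper())
                tgt_chars.append(t_ch.upper() if t_ch != "-" else "-")
    src = "".join(src_chars)
    tgt = "".join(tgt_chars)
    if transcript.strand == "-":
        from .genomic_model import reverse_complement

        # reverse-complement both rows so the alignment reads 5'->3' in
        # transcript sense; gap characters pass through unchanged
        src = reverse_complement(src)
        tgt = reverse_complement(tgt)
    return src, tgt
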