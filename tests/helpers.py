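"""Shared builders for test fixtures."""

from lncorth.genomic_model import AnnotationSet, Interval, Transcript


def make_transcript(tid, gene, exons, seq="chr1", strand="+", biotype="unknown"):
    return Transcript(
        transcript_id=tid,
        gene_id=gene,
        exons=[Interval(seq, s, e, strand) for s, e in exons],
        biotype=biotype,
    )


def random_annotation(rng, n, seq_ids=("chr1", "chr2")):
    annotation = AnnotationSet()
    for i in range(n):
        seq = seq_ids[rng.integers(len(seq_ids))]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        cursor = int(rng.integers(0, 100_000))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(50, 400))
            exons.append((cursor, cursor + length))
            cursor += length + int(rng.integers(30, 500))
        annotation.add(
            make_transcript(f"t{i}", f"g{i // 2}", exons, seq=seq, strand=strand)
        )
    return annotation
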