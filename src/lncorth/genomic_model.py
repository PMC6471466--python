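"""Domain types and I/O for genomes, gene models and pairwise alignment blocks.

All internal coordinates are 0-based half-open on the forward strand.  GTF I/O
converts at the boundary (GTF is 1-based inclusive); MAF minus-strand rows are
normalised to forward-strand intervals on read.  Transcript merging across
samples collapses records with identical intron chains, the core rule of
reference-guided assembly mergers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from Bio import AlignIO
from intervaltree import IntervalTree

__all__ = [
    "Interval",
    "Transcript",
    "AnnotationSet",
    "AlignmentBlock",
    "read_gtf",
    "write_gtf",
    "read_maf",
    "merge_transcripts",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Interval:
    """A stranded genomic interval, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Transcript:
    """A stranded multi-exon gene model on one sequence.

    Exons are kept disjoint and sorted by start regardless of input order.
    ``biotype`` is one of {"coding", "lncRNA_candidate", "unknown"}.
    """

    transcript_id: str
    gene_id: str
    exons: list[Interval]
    biotype: str = "unknown"
    samples: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        exons = sorted(self.exons, key=lambda e: e.start)
        seq_ids = {e.seq_id for e in exons}
        strands = {e.strand for e in exons}
        if len(seq_ids) != 1 or len(strands) != 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons on mixed sequences/strands"
            )
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        self.exons = exons

    @property
    def seq_id(self) -> str:
        return self.exons[0].seq_id

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> Interval:
        return Interval(self.seq_id, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        """Spliced (exonic) length in bp."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    def spliced_sequence(self, genome) -> str:
        """Extract the spliced transcript sequence (5'→3') from a genome.

        ``genome`` is any mapping of seq_id to string-sliceable sequence
        (e.g. a ``pyfaidx.Fasta`` or a plain dict of strings).
        """
        parts = [str(genome[self.seq_id][e.start : e.end]) for e in self.exons]
        seq = "".join(parts).upper()
        return reverse_complement(seq) if self.strand == "-" else seq


class AnnotationSet:
    """A collection of transcripts with gene and interval indices.

    Overlap queries run against per-sequence interval trees over transcript
    spans and return exactly the transcripts an exhaustive scan would.
    """

    def __init__(self, transcripts: list[Transcript] | None = None):
        self._transcripts: dict[str, Transcript] = {}
        self._genes: dict[str, list[str]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for t in transcripts or []:
            self.add(t)

    def add(self, t: Transcript) -> None:
        if t.transcript_id in self._transcripts:
            raise ValueError(f"duplicate transcript_id {t.transcript_id}")
        self._transcripts[t.transcript_id] = t
        self._genes.setdefault(t.gene_id, []).append(t.transcript_id)
        self._trees.setdefault(t.seq_id, IntervalTree()).addi(
            t.start, t.end, t.transcript_id
        )

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self):
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __getitem__(self, transcript_id: str) -> Transcript:
        return self._transcripts[transcript_id]

    @property
    def transcripts(self) -> dict[str, Transcript]:
        return dict(self._transcripts)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self._genes)

    def gene_transcripts(self, gene_id: str) -> list[Transcript]:
        return [self._transcripts[tid] for tid in self._genes[gene_id]]

    def gene_span(self, gene_id: str) -> Interval:
        """Union span of a gene: min start to max end over its transcripts."""
        ts = self.gene_transcripts(gene_id)
        return Interval(
            ts[0].seq_id,
            min(t.start for t in ts),
            max(t.end for t in ts),
            ts[0].strand,
        )

    def gene_spans(self) -> dict[str, Interval]:
        return {g: self.gene_span(g) for g in self._genes}

    def overlapping(self, seq_id: str, start: int, end: int) -> list[Transcript]:
        """Transcripts whose genomic span overlaps [start, end) on seq_id."""
        tree = self._trees.get(seq_id)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        return [self._transcripts[tid] for tid in hits]

    def exon_overlapping(
        self, seq_id: str, start: int, end: int, strand: str | None = None
    ) -> list[Transcript]:
        """Transcripts with at least one exon overlapping [start, end)."""
        out = []
        for t in self.overlapping(seq_id, start, end):
            if strand is not None and t.strand != strand:
                continue
            if any(e.start < end and start < e.end for e in t.exons):
                out.append(t)
        return out


@dataclass(frozen=True)
class AlignmentBlock:
    """One colinear gapped pairwise alignment segment (a MAF block).

    ``src``/``tgt`` are forward-strand intervals; ``src_text``/``tgt_text``
    are the equal-length gapped rows as aligned (minus-strand rows keep the
    reverse-complemented orientation in which they were aligned).
    """

    src: Interval
    tgt: Interval
    src_text: str
    tgt_text: str

    def __post_init__(self) -> None:
        if len(self.src_text) != len(self.tgt_text):
            raise ValueError("alignment rows have unequal gapped length")
        for text, iv, name in (
            (self.src_text, self.src, "source"),
            (self.tgt_text, self.tgt, "target"),
        ):
            ungapped = len(text) - text.count("-")
            if ungapped != len(iv):
                raise ValueError(
                    f"{name} row ungapped length {ungapped} != interval "
                    f"length {len(iv)}"
                )
        if any(a == "-" and b == "-" for a, b in zip(self.src_text, self.tgt_text)):
            raise ValueError("column gapped in both rows")


# ---------------------------------------------------------------------------
# GTF I/O

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path) -> AnnotationSet:
    """Read an Ensembl-dialect GTF into an :class:`AnnotationSet`.

    Only ``exon`` features are used; each must carry ``gene_id`` and
    ``transcript_id`` attributes.  1-based inclusive coordinates become
    0-based half-open.  Raises ``ValueError`` naming the offending line on
    malformed input.
    """
    exons: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: expected 9 "
                    f"tab-separated fields, got {len(fields)}"
                )
            seq_id, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: non-integer coordinate"
                ) from exc
            attributes = _parse_attributes(attrs)
            if "transcript_id" not in attributes:
                raise ValueError(
                    f"{path}: line {lineno}: exon feature without transcript_id"
                )
            if "gene_id" not in attributes:
                raise ValueError(
                    f"{path}: line {lineno}: exon feature without gene_id"
                )
            tid = attributes["transcript_id"]
            if tid not in exons:
                order.append(tid)
                exons[tid] = []
                meta[tid] = (
                    attributes["gene_id"],
                    attributes.get("biotype", "unknown"),
                )
            exons[tid].append(Interval(seq_id, start_i - 1, end_i, strand))
    annotation = AnnotationSet()
    for tid in order:
        gene_id, biotype = meta[tid]
        annotation.add(
            Transcript(
                transcript_id=tid, gene_id=gene_id, exons=exons[tid], biotype=biotype
            )
        )
    return annotation


def write_gtf(annotation: AnnotationSet, path, source: str = "lncorth") -> None:
    """Write exon features for every transcript; round-trips through read_gtf."""
    with open(path, "w") as fh:
        for t in annotation:
            for e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'biotype "{t.biotype}";'
                )
                fh.write(
                    "\t".join(
                        [
                            e.seq_id,
                            source,
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            e.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# MAF I/O


def read_maf(path) -> list[AlignmentBlock]:
    """Read a pairwise MAF file into alignment blocks, in file order.

    Exactly two rows per block (source first).  MAF strand semantics
    (minus-strand starts counted from the reverse-complemented sequence) are
    normalised to forward-strand 0-based half-open intervals; the gapped row
    text is kept in alignment orientation.
    """
    blocks: list[AlignmentBlock] = []
    for aln in AlignIO.parse(str(path), "maf"):
        if len(aln) != 2:
            raise ValueError(
                f"{path}: MAF block with {len(aln)} rows; only pairwise "
                "(2-row) blocks are supported"
            )
        rows = []
        for rec in aln:
            ann = rec.annotations
            start, size = int(ann["start"]), int(ann["size"])
            strand = "+" if ann["strand"] in (1, "+") else "-"
            src_size = int(ann["srcSize"])
            if strand == "+":
                fstart, fend = start, start + size
            else:
                fstart, fend = src_size - start - size, src_size - start
            rows.append(
                (Interval(rec.id, fstart, fend, strand), str(rec.seq).upper())
            )
        (src_iv, src_text), (tgt_iv, tgt_text) = rows
        blocks.append(AlignmentBlock(src_iv, tgt_iv, src_text, tgt_text))
    return blocks


def write_maf(blocks: list[AlignmentBlock], path) -> None:
    """Write pairwise blocks as MAF (inverse of :func:`read_maf`)."""

    def s_line(iv: Interval, text: str, src_size: int) -> str:
        size = len(iv)
        start = iv.start if iv.strand == "+" else src_size - iv.end
        return f"s {iv.seq_id} {start} {size} {iv.strand} {src_size} {text}\n"

    # srcSize only matters for minus-strand coordinate recovery; use the
    # largest end seen per sequence so round-trips are exact.
    sizes: dict[str, int] = {}
    for b in blocks:
        for iv in (b.src, b.tgt):
            sizes[iv.seq_id] = max(sizes.get(iv.seq_id, 0), iv.end)
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for b in blocks:
            fh.write("a\n")
            fh.write(s_line(b.src, b.src_text, sizes[b.src.seq_id]))
            fh.write(s_line(b.tgt, b.tgt_text, sizes[b.tgt.seq_id]))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Transcript merging


def merge_transcripts(
    per_sample_sets: list[AnnotationSet],
    genome_seq_ids: set[str] | None = None,
) -> AnnotationSet:
    """Merge per-sample transcript sets into one non-redundant set.

    Multi-exon transcripts with identical intron chains (same sequence and
    strand) collapse to a single record whose terminal exons take the union
    span; single-exon transcripts collapse only on exact interval identity.
    Sample provenance is retained on the merged record.  Merging is
    idempotent and order-independent.

    When ``genome_seq_ids`` is given, transcripts on unknown sequences raise
    (guards against mixing sets assembled on different genomes).
    """
    if genome_seq_ids is not None:
        for annotation in per_sample_sets:
            for t in annotation:
                if t.seq_id not in genome_seq_ids:
                    raise ValueError(
                        f"transcript {t.transcript_id} on {t.seq_id}: not a "
                        "sequence of the stated genome (mixed genomes?)"
                    )
    groups: dict[tuple, list[Transcript]] = {}
    for idx, annotation in enumerate(per_sample_sets):
        for t in annotation:
            if t.n_exons == 1:
                key = ("single", t.seq_id, t.strand, t.start, t.end)
            else:
                key = ("multi", t.seq_id, t.strand, t.intron_chain)
            groups.setdefault(key, []).append(
                replace(t, samples=t.samples or frozenset({f"sample_{idx}"}))
            )
    merged = AnnotationSet()
    for key in sorted(groups, key=str):
        members = groups[key]
        rep = min(members, key=lambda t: t.transcript_id)
        exons = list(rep.exons)
        if rep.n_exons > 1:
            first_start = min(t.exons[0].start for t in members)
            last_end = max(t.exons[-1].end for t in members)
            exons[0] = replace(exons[0], start=first_start)
            exons[-1] = replace(exons[-1], end=last_end)
        samples = frozenset().union(*(t.samples for t in members))
        merged.add(
            Transcript(
                transcript_id=rep.transcript_id,
                gene_id=rep.gene_id,
                exons=exons,
                biotype=rep.biotype,
                samples=samples,
            )
        )
    return merged


# ---------------------------------------------------------------------------
# FASTA helpers (writing only; reading goes through pyfaidx or a dict)


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
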