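"""Genomic-context classification of lncRNA candidates.

Each candidate is placed relative to the protein-coding annotation using
gene spans (min start to max end over a gene's transcripts):

* ``genic`` — candidate span entirely inside at least one coding-gene span;
* ``intergenic`` — zero overlap with every coding-gene span;
* ``spanning`` — partial overlap (extends past a gene into intergenic space).

Genic/spanning candidates get a sense/antisense orientation relative to the
overlapped (nearest, on ties) gene.  Intergenic candidates get a subtype
from the nearest gene within a window: divergent (head-to-head), convergent
(tail-to-tail), same_strand, or isolated when no gene is near.  The three
classes are exhaustive and mutually exclusive, so tallies always partition
the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

from .genomic_model import AnnotationSet, Interval, Transcript


@dataclass(frozen=True)
class ContextCall:
    transcript_id: str
    context: str  # genic | intergenic | spanning
    orientation: str  # sense | antisense | NA
    subtype: str  # divergent | convergent | same_strand | isolated | NA
    nearest_coding_gene_id: str | None
    distance_bp: int


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two intervals on one sequence; 0 if they touch/overlap."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def _intergenic_subtype(cand: Interval, gene: Interval) -> str:
    """Relative orientation of an intergenic candidate and its nearest gene.

    Head = 5' end (start on '+', end on '-').  Divergent: the facing ends are
    both heads (transcription runs apart); convergent: both tails.
    """
    if cand.strand == gene.strand:
        return "same_strand"
    if cand.end <= gene.start:  # candidate left of gene
        cand_facing_head = cand.strand == "-"  # head at right end
        gene_facing_head = gene.strand == "+"  # head at left end
    else:  # candidate right of gene
        cand_facing_head = cand.strand == "+"
        gene_facing_head = gene.strand == "-"
    return "divergent" if (cand_facing_head and gene_facing_head) else "convergent"


def classify_context(
    candidate: Transcript,
    coding: AnnotationSet,
    window_bp: int = 10_000,
    gene_spans: dict[str, Interval] | None = None,
) -> ContextCall:
    """Classify one candidate against coding gene spans (see module docs).

    The nearest gene is the one at the smallest span distance, ties broken by
    lexicographic gene_id, so output is deterministic.  An empty coding
    annotation yields intergenic/isolated.
    """
    spans = gene_spans if gene_spans is not None else coding.gene_spans()
    c = candidate.span
    contained_by: list[str] = []
    overlapped: list[str] = []
    nearest: tuple[int, str] | None = None
    for gid in sorted(spans):
        g = spans[gid]
        if g.seq_id != c.seq_id:
            continue
        d = _gap(c.start, c.end, g.start, g.end)
        if nearest is None or (d, gid) < nearest:
            nearest = (d, gid)
        if d == 0:
            overlapped.append(gid)
            if g.start <= c.start and c.end <= g.end:
                contained_by.append(gid)

    if not overlapped:
        if nearest is None or nearest[0] > window_bp:
            gid = nearest[1] if nearest else None
            dist = nearest[0] if nearest else 0
            return ContextCall(
                candidate.transcript_id, "intergenic", "NA", "isolated", gid, dist
            )
        dist, gid = nearest
        subtype = _intergenic_subtype(c, spans[gid])
        return ContextCall(
            candidate.transcript_id, "intergenic", "NA", subtype, gid, dist
        )

    context = "genic" if contained_by else "spanning"
    ref_gid = min(contained_by) if contained_by else min(overlapped)
    orientation = "sense" if spans[ref_gid].strand == c.strand else "antisense"
    return ContextCall(
        candidate.transcript_id, context, orientation, "NA", ref_gid, 0
    )


def classify_all(
    candidates: AnnotationSet | list[Transcript],
    coding: AnnotationSet,
    window_bp: int = 10_000,
) -> tuple[list[ContextCall], dict[str, int]]:
    """Classify every candidate; returns calls plus a class tally.

    The tally covers exactly {genic, intergenic, spanning} and sums to the
    number of candidates.
    """
    spans = coding.gene_spans()
    calls = [
        classify_context(t, coding, window_bp, gene_spans=spans)
        for t in candidates
    ]
    tally = Counter(call.context for call in calls)
    return calls, {
        "genic": tally.get("genic", 0),
        "intergenic": tally.get("intergenic", 0),
        "spanning": tally.get("spanning", 0),
    }
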