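"""Set algebra over expression evidence, and the final conserved lncRNA call.

Candidates for functional relevance combine two disjoint rules:

* rule 1 — differentially expressed both between retina and native RPE and
  between native and cultured RPE (union of the culture time points);
* rule 2 — expressed at the same level in native RPE and retina (expressed
  in both, not DE between them) but responsive to culturing.

Candidates whose projected target-genome models overlap protein-coding
exons (UTRs included, either strand by default) are then purged; what
remains are the conserved "true" lncRNAs, summarised as a percentage of the
studied repertoire.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genomic_model import AnnotationSet


@dataclass
class CandidateSelection:
    candidates: list[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)
    rule1: set[str] = field(default_factory=set)
    rule2: set[str] = field(default_factory=set)


def select_candidates(
    de_retina_vs_rpe: set[str],
    de_4wk: set[str],
    de_8wk: set[str],
    expressed_native: set[str],
    expressed_retina: set[str],
) -> CandidateSelection:
    """Combine DE and expression evidence into the candidate set.

    rule 1: DE retina-vs-RPE AND DE native-vs-cultured (4wk ∪ 8wk).
    rule 2: expressed in both native RPE and retina, NOT DE retina-vs-RPE,
    AND DE native-vs-cultured.  The rules are disjoint by construction, so
    |candidates| = |rule1| + |rule2|.  Provenance records which rule(s)
    admitted each gene.
    """
    de_cultured = de_4wk | de_8wk
    rule1 = de_retina_vs_rpe & de_cultured
    stable = (expressed_native & expressed_retina) - de_retina_vs_rpe
    rule2 = stable & de_cultured
    provenance: dict[str, list[str]] = {}
    for g in rule1:
        provenance.setdefault(g, []).append("de_retina_and_culture")
    for g in rule2:
        provenance.setdefault(g, []).append("stable_but_culture_responsive")
    return CandidateSelection(
        candidates=sorted(rule1 | rule2),
        provenance=provenance,
        rule1=rule1,
        rule2=rule2,
    )


def purge_target_coding_overlap(
    candidate_gene_ids: list[str],
    projected_models: AnnotationSet,
    target_coding: AnnotationSet,
    sense_only: bool = False,
) -> tuple[list[str], list[str], list[str]]:
    """Split candidates into true lncRNAs vs protein-coding-overlapping loci.

    A candidate is overlapping when any exon of any of its projected
    target-genome transcripts overlaps any exon (UTR exons included) of a
    target protein-coding transcript — on either strand by default, since
    same-locus UTR transcripts are suspect regardless of orientation.
    Candidates without a projected model are set aside as ``unprojected``.
    Returns (true_lncRNAs, overlapping, unprojected); the three lists
    partition the input.
    """
    true_lnc: list[str] = []
    overlapping: list[str] = []
    unprojected: list[str] = []
    projected_gene_ids = {t.gene_id for t in projected_models}
    for gid in candidate_gene_ids:
        if gid not in projected_gene_ids:
            unprojected.append(gid)
            continue
        hit = False
        for t in projected_models.gene_transcripts(gid):
            for e in t.exons:
                strand = t.strand if sense_only else None
                hits = target_coding.exon_overlapping(
                    e.seq_id, e.start, e.end, strand=strand
                )
                if any(h.biotype == "coding" for h in hits):
                    hit = True
                    break
            if hit:
                break
        (overlapping if hit else true_lnc).append(gid)
    return true_lnc, overlapping, unprojected


def conservation_fraction(conserved_count: int, studied_count: int) -> float:
    """Conserved loci as a percentage of the studied repertoire."""
    if studied_count <= 0:
        raise ValueError("studied_count must be positive")
    if conserved_count > studied_count:
        raise ValueError("conserved_count cannot exceed studied_count")
    return 100.0 * conserved_count / studied_count
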