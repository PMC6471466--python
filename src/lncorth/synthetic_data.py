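"""Seeded two-species toy world with planted ground truth.

The generator emulates the study design the pipeline was built for: a
source-genome tissue transcriptome (native RPE plus 4- and 8-week cultures)
whose lncRNA repertoire is projected into a target genome where a retina /
RPE expression contrast exists.  It plants, per locus class:

* protein-coding genes present in both genomes, with long biased-codon ORFs
  and third-position-skewed cross-species substitutions;
* conserved lncRNAs (identity well above the 60% ortholog threshold) split
  into quiet, culture-responsive-and-retina-DE (rule 1), stable-but-
  culture-responsive (rule 2), and target-coding-overlap trap loci;
* coding-derived decoy "lncRNAs" whose substitutions concentrate at third
  codon positions (detectable by the coding-conservation screen);
* low-identity decoys (below the threshold) and source-only species-specific
  loci; plus single-exon and sub-200-bp junk for the structural filter.

Substitution placement is uniform for neutral loci and third-position-
concentrated for coding/decoy loci.  Counts are drawn per gene from a
negative binomial with variance mu + alpha*mu^2 and planted fold changes.
Everything is deterministic given the seed, and every planted label is
recoverable from the emitted FASTA/GTF/MAF/TSV files by independent recount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .candidate_filter import longest_orf
from .genomic_model import (
    AnnotationSet,
    Interval,
    Transcript,
    AlignmentBlock,
    write_fasta,
    write_gtf,
    write_maf,
)

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOPS
]
# biased codon usage for planted ORFs: prefer C/G-ending codons
_CODON_W = np.array([3.0 if c[2] in "CG" else 1.0 for c in SENSE_CODONS])
_CODON_P = _CODON_W / _CODON_W.sum()

CONDITIONS = ("native", "cult4w", "cult8w", "retina")

# locus classes and their planted behaviour
CLASS_CODING = "coding"
CLASS_RULE1 = "lnc_conserved_responsive"
CLASS_RULE2 = "lnc_conserved_stable_responsive"
CLASS_OVERLAP = "lnc_conserved_target_overlap"
CLASS_QUIET = "lnc_conserved_quiet"
CLASS_DECOY = "lnc_coding_decoy"
CLASS_LOWID = "lnc_low_identity"
CLASS_SPECIFIC = "lnc_species_specific"
CLASS_SINGLE = "junk_single_exon"
CLASS_SHORT = "junk_short"


@dataclass
class WorldSpec:
    """Parameters of the synthetic two-species world (defaults = study design)."""

    seed: int = 0
    genome_length: int | None = None  # optional cap per genome; None = as needed
    n_coding_genes: int = 12
    n_conserved_responsive: int = 6
    n_conserved_stable: int = 4
    n_conserved_overlap: int = 5
    n_conserved_quiet: int = 10
    n_coding_decoys: int = 5
    n_low_identity: int = 8
    n_species_specific: int = 7
    n_single_exon_junk: int = 4
    n_short_junk: int = 4
    conserved_identity: float = 0.85
    low_identity: float = 0.40
    coding_identity: float = 0.90
    exon_count_range: tuple[int, int] = (2, 4)
    exon_len_range: tuple[int, int] = (120, 300)
    intron_len_range: tuple[int, int] = (100, 400)
    spacer_range: tuple[int, int] = (500, 1500)
    replicates: int = 4
    dispersion: float = 0.05
    base_mean_range: tuple[float, float] = (100.0, 500.0)
    lfc_retina: float = 3.0  # planted log2 FC, retina over native, DE loci
    lfc_culture: float = -3.0  # planted log2 FC, cultured over native, responsive loci
    n_samples: int = 3  # per-sample assembled GTFs for the merge stage

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_identity <= 1.0 and 0.0 <= self.conserved_identity <= 1.0):
            raise ValueError("identities must lie in [0, 1]")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per condition")


@dataclass
class Locus:
    gene_id: str
    locus_class: str
    transcript: Transcript  # source-genome model
    planted_identity: float | None
    lfc_retina: float
    lfc_culture: float
    in_target: bool
    expected_candidate: bool
    expected_true_lncRNA: bool


@dataclass
class SyntheticWorld:
    spec: WorldSpec
    outdir: Path
    src_genome: dict[str, str]
    tgt_genome: dict[str, str]
    loci: list[Locus]
    truth: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _orf_sequence(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(SENSE_CODONS, size=n_codons, p=_CODON_P)
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    return "ATG" + "".join(codons) + stop


def _mutate(
    rng: np.random.Generator, seq: str, positions: np.ndarray
) -> str:
    out = list(seq)
    for pos in positions:
        old = out[pos]
        choices = [b for b in BASES if b != old]
        out[pos] = choices[rng.integers(3)]
    return "".join(out)


def _transcript_sense_positions(exons: list[Interval], offset: int, strand: str) -> list[int]:
    """Locus-local positions of exonic bases in transcript 5'->3' order."""
    pos = []
    for e in exons:
        pos.extend(range(e.start - offset, e.end - offset))
    return pos[::-1] if strand == "-" else pos


class _GenomeBuilder:
    def __init__(self, name: str):
        self.name = name
        self.parts: list[str] = []
        self.length = 0

    def append(self, seq: str) -> int:
        start = self.length
        self.parts.append(seq)
        self.length += len(seq)
        return start

    def sequence(self) -> str:
        return "".join(self.parts)


def _class_plan(spec: WorldSpec) -> list[tuple[str, str]]:
    plan = []

    def add(cls: str, prefix: str, n: int) -> None:
        for i in range(n):
            plan.append((cls, f"{prefix}_{i:03d}"))

    add(CLASS_CODING, "CODING", spec.n_coding_genes)
    add(CLASS_RULE1, "LNC_R1", spec.n_conserved_responsive)
    add(CLASS_RULE2, "LNC_R2", spec.n_conserved_stable)
    add(CLASS_OVERLAP, "LNC_OVL", spec.n_conserved_overlap)
    add(CLASS_QUIET, "LNC_QUIET", spec.n_conserved_quiet)
    add(CLASS_DECOY, "LNC_DECOY", spec.n_coding_decoys)
    add(CLASS_LOWID, "LNC_LOWID", spec.n_low_identity)
    add(CLASS_SPECIFIC, "LNC_SPEC", spec.n_species_specific)
    add(CLASS_SINGLE, "JUNK_SE", spec.n_single_exon_junk)
    add(CLASS_SHORT, "JUNK_SHORT", spec.n_short_junk)
    return plan


def _locus_structure(
    rng: np.random.Generator, spec: WorldSpec, cls: str
) -> tuple[list[tuple[int, int]], int, str]:
    """Exon (start, end) offsets within the locus, locus length, strand."""
    strand = "+" if rng.random() < 0.5 else "-"
    if cls == CLASS_SINGLE:
        L = int(rng.integers(300, 600))
        return [(0, L)], L, strand
    if cls == CLASS_SHORT:
        e1 = int(rng.integers(40, 80))
        e2 = int(rng.integers(40, 199 - e1))
        intron = int(rng.integers(*spec.intron_len_range))
        return [(0, e1), (e1 + intron, e1 + intron + e2)], e1 + intron + e2, strand
    n_exons = int(rng.integers(spec.exon_count_range[0], spec.exon_count_range[1] + 1))
    exons = []
    cursor = 0
    for i in range(n_exons):
        if i > 0:
            cursor += int(rng.integers(*spec.intron_len_range))
        elen = int(rng.integers(*spec.exon_len_range))
        exons.append((cursor, cursor + elen))
        cursor += elen
    return exons, cursor, strand


def _fill_locus_sequence(
    rng: np.random.Generator,
    cls: str,
    exon_offsets: list[tuple[int, int]],
    locus_len: int,
    strand: str,
) -> str:
    """Random locus sequence; coding loci carry a planted ORF in the spliced
    transcript sense.  Decoy loci stay ORF-free: they model degraded coding
    loci whose sequence looks noncoding but whose substitution pattern keeps
    the coding periodicity."""
    seq = list(_rand_seq(rng, locus_len))
    if cls == CLASS_CODING:
        exonic = sum(e - s for s, e in exon_offsets)
        n_codons = max(40, exonic // 3 - 4)
        orf = _orf_sequence(rng, n_codons - 2)[: exonic - (exonic % 3)]
        spliced = list(orf.ljust(exonic, "A"))
        positions = _transcript_sense_positions(
            [Interval("x", s, e) for s, e in exon_offsets], 0, strand
        )
        # place spliced bases back, complementing for minus-strand loci
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for base, pos in zip(spliced, positions):
            seq[pos] = comp[base] if strand == "-" else base
    elif cls.startswith("lnc_"):
        _break_orfs(seq, exon_offsets, strand)
    return "".join(seq)


def _break_orfs(
    seq: list[str], exon_offsets: list[tuple[int, int]], strand: str, max_aa: int = 30
) -> None:
    """Disrupt chance ORFs in a planted lncRNA locus (in place).

    Planted noncoding loci should not carry coding-length ORFs, so any ORF
    longer than ``max_aa`` in the spliced transcript sense gets a stop codon
    dropped into its middle until none remain.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    positions = _transcript_sense_positions(
        [Interval("x", s, e) for s, e in exon_offsets], 0, strand
    )
    while True:
        spliced = "".join(
            comp[seq[p]] if strand == "-" else seq[p] for p in positions
        )
        _frame, start, _end, aa = longest_orf(spliced)
        if aa <= max_aa:
            return
        mid = start + 3 * (aa // 2)
        for offset, base in enumerate("TAA"):
            p = positions[mid + offset]
            seq[p] = comp[base] if strand == "-" else base


def _substitution_positions(
    rng: np.random.Generator,
    cls: str,
    identity: float,
    exon_offsets: list[tuple[int, int]],
    locus_len: int,
    strand: str,
) -> np.ndarray:
    """Choose locus-local positions to substitute so the realised whole-locus
    identity equals the planted one; coding/decoy loci concentrate exonic
    substitutions at third codon positions of the transcript frame."""
    n_sub = int(round((1.0 - identity) * locus_len))
    exonic_positions = _transcript_sense_positions(
        [Interval("x", s, e) for s, e in exon_offsets], 0, strand
    )
    if cls in (CLASS_CODING, CLASS_DECOY):
        pos3 = np.array(exonic_positions[2::3])
        exonic_set = set(exonic_positions)
        intronic = np.array(
            [p for p in range(locus_len) if p not in exonic_set], dtype=int
        )
        n_exonic_sub = int(round((1.0 - identity) * len(exonic_positions)))
        n_exonic_sub = min(n_exonic_sub, len(pos3))
        n_intronic_sub = min(max(n_sub - n_exonic_sub, 0), len(intronic))
        chosen = [rng.choice(pos3, size=n_exonic_sub, replace=False)]
        if n_intronic_sub:
            chosen.append(rng.choice(intronic, size=n_intronic_sub, replace=False))
        return np.concatenate(chosen).astype(int)
    return rng.choice(locus_len, size=min(n_sub, locus_len), replace=False).astype(int)


def generate_world(spec: WorldSpec, outdir) -> SyntheticWorld:
    """Build the two-species world and write all files under ``outdir``.

    Emits: src_genome.fa / tgt_genome.fa, src_coding.gtf / tgt_coding.gtf,
    per-sample assembled-transcript GTFs (sample_0.gtf, ...), alignment.maf,
    counts.tsv + gene_lengths.tsv + conditions.tsv, and truth.tsv.
    """
    rng = np.random.default_rng(spec.seed)
    outdir = Path(outdir)
    plan = _class_plan(spec)

    src = _GenomeBuilder("chrS")
    tgt = _GenomeBuilder("chrT")
    loci: list[Locus] = []
    blocks: list[AlignmentBlock] = []
    n_responsive = 0
    tgt_extra_coding: list[Transcript] = []  # overlap-trap annotations
    tgt_coding_models: list[Transcript] = []

    # pre-compute total length for feasibility when a cap is given
    if spec.genome_length is not None:
        worst = sum(
            spec.spacer_range[1]
            + spec.exon_count_range[1] * spec.exon_len_range[1]
            + (spec.exon_count_range[1] - 1) * spec.intron_len_range[1]
            for _ in plan
        )
        if worst > spec.genome_length:
            raise ValueError(
                f"infeasible spec: {len(plan)} loci may need up to {worst} bp "
                f"but genome_length is {spec.genome_length}"
            )

    for cls, gene_id in plan:
        src.append(_rand_seq(rng, int(rng.integers(*spec.spacer_range))))
        tgt.append(_rand_seq(rng, int(rng.integers(*spec.spacer_range))))

        exon_offsets, locus_len, strand = _locus_structure(rng, spec, cls)
        locus_seq = _fill_locus_sequence(rng, cls, exon_offsets, locus_len, strand)
        src_start = src.append(locus_seq)
        exons = [
            Interval("chrS", src_start + s, src_start + e, strand)
            for s, e in exon_offsets
        ]
        transcript = Transcript(
            transcript_id=f"{gene_id}.1",
            gene_id=gene_id,
            exons=exons,
            biotype="coding" if cls == CLASS_CODING else "unknown",
        )

        in_target = cls in (
            CLASS_CODING,
            CLASS_RULE1,
            CLASS_RULE2,
            CLASS_OVERLAP,
            CLASS_QUIET,
            CLASS_DECOY,
            CLASS_LOWID,
        )
        identity: float | None = None
        if in_target:
            identity = {
                CLASS_CODING: spec.coding_identity,
                CLASS_LOWID: spec.low_identity,
            }.get(cls, spec.conserved_identity)
            subs = _substitution_positions(
                rng, cls, identity, exon_offsets, locus_len, strand
            )
            tgt_seq = _mutate(rng, locus_seq, subs)
            tgt_start = tgt.append(tgt_seq)
            blocks.append(
                AlignmentBlock(
                    src=Interval("chrS", src_start, src_start + locus_len),
                    tgt=Interval("chrT", tgt_start, tgt_start + locus_len),
                    src_text=locus_seq,
                    tgt_text=tgt_seq,
                )
            )
            if cls == CLASS_CODING:
                tgt_coding_models.append(
                    Transcript(
                        transcript_id=f"{gene_id}.t1",
                        gene_id=f"{gene_id}_tgt",
                        exons=[
                            Interval("chrT", tgt_start + s, tgt_start + e, strand)
                            for s, e in exon_offsets
                        ],
                        biotype="coding",
                    )
                )
            if cls == CLASS_OVERLAP:
                # annotate a coding gene over the projected region so the
                # final purge sees a UTR-style exon overlap
                tgt_extra_coding.append(
                    Transcript(
                        transcript_id=f"{gene_id}.trap",
                        gene_id=f"{gene_id}_trapgene",
                        exons=[
                            Interval(
                                "chrT",
                                max(0, tgt_start - 50),
                                tgt_start + locus_len + 50,
                                "+",
                            )
                        ],
                        biotype="coding",
                    )
                )

        responsive = cls in (
            CLASS_RULE1,
            CLASS_RULE2,
            CLASS_OVERLAP,
            CLASS_DECOY,
        ) or (cls == CLASS_LOWID and int(gene_id[-3:]) % 2 == 0) or (
            cls == CLASS_SPECIFIC and int(gene_id[-3:]) % 2 == 0
        )
        retina_de = responsive and cls != CLASS_RULE2
        # alternate the direction of planted changes so non-responsive genes
        # stay the majority reference for median-of-ratios normalisation
        if responsive:
            sign = 1.0 if n_responsive % 2 == 0 else -1.0
            n_responsive += 1
        else:
            sign = 1.0
        loci.append(
            Locus(
                gene_id=gene_id,
                locus_class=cls,
                transcript=transcript,
                planted_identity=identity,
                lfc_retina=sign * spec.lfc_retina if retina_de else 0.0,
                lfc_culture=sign * spec.lfc_culture if responsive else 0.0,
                in_target=in_target,
                expected_candidate=responsive,
                expected_true_lncRNA=cls in (CLASS_RULE1, CLASS_RULE2),
            )
        )

    src.append(_rand_seq(rng, int(rng.integers(*spec.spacer_range))))
    tgt.append(_rand_seq(rng, int(rng.integers(*spec.spacer_range))))

    if spec.genome_length is not None and (
        src.length > spec.genome_length or tgt.length > spec.genome_length
    ):
        raise ValueError("infeasible spec: planted loci exceed genome_length")

    src_genome = {"chrS": src.sequence()}
    tgt_genome = {"chrT": tgt.sequence()}

    # ---- per-sample assembled transcript sets (terminal-end jitter) -------
    sample_sets: list[AnnotationSet] = []
    for k in range(spec.n_samples):
        annotation = AnnotationSet()
        for locus in loci:
            t = locus.transcript
            exons = list(t.exons)
            if t.n_exons > 1 and k > 0:
                jitter = int(rng.integers(0, 40))
                first = exons[0]
                new_start = min(first.start + jitter, first.end - 20)
                exons[0] = Interval(first.seq_id, new_start, first.end, first.strand)
            annotation.add(
                Transcript(
                    transcript_id=t.transcript_id,
                    gene_id=t.gene_id,
                    exons=exons,
                    biotype=t.biotype,
                    samples=frozenset({f"sample_{k}"}),
                )
            )
        sample_sets.append(annotation)

    # ---- expression counts ------------------------------------------------
    counted = [l for l in loci if l.locus_class.startswith("lnc_")]
    gene_ids = [l.gene_id for l in counted]
    base = rng.uniform(*spec.base_mean_range, size=len(counted))
    samples = [f"{cond}_{r}" for cond in CONDITIONS for r in range(spec.replicates)]
    conditions = {s: s.rsplit("_", 1)[0] for s in samples}
    mat = np.zeros((len(counted), len(samples)), dtype=int)
    for i, locus in enumerate(counted):
        for j, s in enumerate(samples):
            cond = conditions[s]
            mu = base[i]
            if cond == "retina":
                mu *= 2.0 ** locus.lfc_retina
            elif cond in ("cult4w", "cult8w"):
                mu *= 2.0 ** locus.lfc_culture
            mat[i, j] = _nb_draw(rng, mu, spec.dispersion)
    counts = pd.DataFrame(mat, index=gene_ids, columns=samples)
    lengths = pd.Series(
        {l.gene_id: l.transcript.length for l in counted}, name="length_bp"
    )

    truth = pd.DataFrame(
        {
            "gene_id": [l.gene_id for l in loci],
            "class": [l.locus_class for l in loci],
            "planted_identity": [
                l.planted_identity if l.planted_identity is not None else np.nan
                for l in loci
            ],
            "planted_lfc_retina": [l.lfc_retina for l in loci],
            "planted_lfc_culture": [l.lfc_culture for l in loci],
            "in_target": [l.in_target for l in loci],
            "expected_candidate": [l.expected_candidate for l in loci],
            "expected_true_lncRNA": [l.expected_true_lncRNA for l in loci],
        }
    ).set_index("gene_id")

    # ---- write ------------------------------------------------------------
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _p(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    write_fasta(src_genome, _p("src_genome.fa"))
    write_fasta(tgt_genome, _p("tgt_genome.fa"))
    src_coding = AnnotationSet(
        [l.transcript for l in loci if l.locus_class == CLASS_CODING]
    )
    write_gtf(src_coding, _p("src_coding.gtf"))
    write_gtf(
        AnnotationSet(tgt_coding_models + tgt_extra_coding), _p("tgt_coding.gtf")
    )
    for k, annotation in enumerate(sample_sets):
        write_gtf(annotation, _p(f"sample_{k}.gtf"))
    write_maf(blocks, _p("alignment.maf"))
    counts.to_csv(_p("counts.tsv"), sep="\t")
    lengths.to_frame().to_csv(_p("gene_lengths.tsv"), sep="\t")
    pd.Series(conditions, name="condition").rename_axis("sample").to_frame().to_csv(
        _p("conditions.tsv"), sep="\t"
    )
    truth.to_csv(_p("truth.tsv"), sep="\t")

    return SyntheticWorld(
        spec=spec,
        outdir=outdir,
        src_genome=src_genome,
        tgt_genome=tgt_genome,
        loci=loci,
        truth=truth,
        paths=paths,
    )


def _nb_draw(rng: np.random.Generator, mu: float, alpha: float) -> int:
    """NB draw parameterised by mean and dispersion (var = mu + alpha mu^2)."""
    if mu <= 0:
        return 0
    if alpha <= 0:
        return int(rng.poisson(mu))
    r = 1.0 / alpha
    p = r / (r + mu)
    return int(rng.negative_binomial(r, p))


def generate_training_sequences(
    n_per_class: int = 50, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Labelled training data for the coding-potential model.

    Coding class: transcripts with a planted ORF of >= 100 codons under
    biased codon usage, flanked by short UTRs.  Noncoding class: same-length
    sequences resampled from a first-order Markov chain fitted to the coding
    sequence — dinucleotide composition is preserved in expectation while
    ORF structure is destroyed.
    """
    if n_per_class < 20:
        raise ValueError("need n_per_class >= 20")
    rng = np.random.default_rng(seed)
    coding: list[str] = []
    noncoding: list[str] = []
    for _ in range(n_per_class):
        n_codons = int(rng.integers(100, 220))
        seq = (
            _rand_seq(rng, int(rng.integers(20, 120)))
            + _orf_sequence(rng, n_codons)
            + _rand_seq(rng, int(rng.integers(20, 200)))
        )
        coding.append(seq)
        noncoding.append(_markov_shuffle(rng, seq))
    return coding, noncoding


def _markov_shuffle(rng: np.random.Generator, seq: str) -> str:
    """Resample a sequence from a first-order Markov chain fitted to it."""
    idx = {b: i for i, b in enumerate(BASES)}
    trans = np.ones((4, 4))
    for a, b in zip(seq, seq[1:]):
        trans[idx[a], idx[b]] += 1
    trans /= trans.sum(axis=1, keepdims=True)
    out = [seq[rng.integers(len(seq))]]
    for _ in range(len(seq) - 1):
        out.append(BASES[rng.choice(4, p=trans[idx[out[-1]]])])
    return "".join(out)


def context_fixture(
    n_genic: int = 157,
    n_intergenic: int = 542,
    n_spanning: int = 149,
    seed: int = 0,
) -> tuple[AnnotationSet, AnnotationSet]:
    """Candidate/coding annotation pair with a planted genic/intergenic/
    spanning partition, mirroring a three-way repertoire split."""
    rng = np.random.default_rng(seed)
    coding = AnnotationSet()
    n_genes = 10
    gene_span = 10_000
    pitch = 50_000
    for g in range(n_genes):
        start = 20_000 + g * pitch
        coding.add(
            Transcript(
                transcript_id=f"PC_{g}.1",
                gene_id=f"PC_{g}",
                exons=[
                    Interval("chr1", start, start + 4000, "+"),
                    Interval("chr1", start + 6000, start + gene_span, "+"),
                ],
                biotype="coding",
            )
        )
    candidates = AnnotationSet()
    counter = 0

    def two_exon(start: int, width: int, strand: str) -> list[Interval]:
        third = max(width // 3, 50)
        return [
            Interval("chr1", start, start + third, strand),
            Interval("chr1", start + 2 * third, start + width, strand),
        ]

    def add(exons: list[Interval]) -> None:
        nonlocal counter
        candidates.add(
            Transcript(
                transcript_id=f"CAND_{counter}.1",
                gene_id=f"CAND_{counter}",
                exons=exons,
            )
        )
        counter += 1

    for i in range(n_genic):
        g = i % n_genes
        start = 20_000 + g * pitch + 500 + int(rng.integers(0, 2000))
        add(two_exon(start, 1500, "+" if rng.random() < 0.5 else "-"))
    for i in range(n_spanning):
        g = i % n_genes
        # overlap the gene's 3' end and extend beyond
        start = 20_000 + g * pitch + gene_span - 500 - int(rng.integers(0, 400))
        add(two_exon(start, 3000, "+" if rng.random() < 0.5 else "-"))
    for i in range(n_intergenic):
        g = i % n_genes
        start = 20_000 + g * pitch + gene_span + 15_000 + int(rng.integers(0, 10_000))
        add(two_exon(start, 1200, "+" if rng.random() < 0.5 else "-"))
    return candidates, coding
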