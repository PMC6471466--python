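"""End-to-end orchestration: merge → filter → classify → project → purge
coding-like → expression → conserved selection, from a single flat config.

Every numeric constant of the analysis lives on :class:`PipelineConfig`
(structural 200 bp / multi-exon filters, the 0.60 ortholog identity and 0.5
coverage thresholds, fold change > 2 with FDR < 0.01, the mean-20-reads
expressed call, the 0.01 coding-conservation alpha).  ``run_pipeline``
writes one report per stage plus a machine-readable run manifest whose
per-stage counts are mutually consistent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .candidate_filter import (
    CodingPotentialModel,
    FilterConfig,
    filter_coding_potential,
    filter_structural,
    train_coding_model,
)
from .coding_conservation import purge_coding_like
from .conserved_selector import (
    conservation_fraction,
    purge_target_coding_overlap,
    select_candidates,
)
from .context_classifier import classify_all
from .expression_analysis import (
    CountMatrix,
    apply_deg_thresholds,
    call_expressed,
    compute_tpm,
    de_table,
    nb_de_test,
)
from .genomic_model import AnnotationSet, read_gtf, read_maf, merge_transcripts, write_gtf
from .ortholog_projection import (
    build_target_annotation,
    project_gene,
    spliced_alignment,
)
from .synthetic_data import generate_training_sequences


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run (flat YAML on disk)."""

    src_genome: str = ""
    src_coding_gtf: str = ""
    tgt_coding_gtf: str = ""
    sample_gtfs: list[str] = field(default_factory=list)
    maf: str = ""
    counts_tsv: str = ""
    conditions_tsv: str = ""
    lengths_tsv: str = ""
    coding_model: str = ""  # optional pre-trained model file
    # condition names for the four-way design
    cond_native: str = "native"
    cond_cult4: str = "cult4w"
    cond_cult8: str = "cult8w"
    cond_retina: str = "retina"
    # thresholds
    min_length_bp: int = 200
    min_exons: int = 2
    coding_score_threshold: float = 0.5
    identity_threshold: float = 0.60
    coverage_threshold: float = 0.5
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.01
    min_mean_reads: float = 20.0
    coding_alpha: float = 0.01
    window_bp: int = 10_000
    studied_denominator: int | None = None
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (self.min_length_bp >= 1, "min_length_bp >= 1"),
            (self.min_exons >= 1, "min_exons >= 1"),
            (0 <= self.coding_score_threshold <= 1, "coding_score_threshold in [0,1]"),
            (0 <= self.identity_threshold <= 1, "identity_threshold in [0,1]"),
            (0 <= self.coverage_threshold <= 1, "coverage_threshold in [0,1]"),
            (self.fc_threshold > 0, "fc_threshold > 0"),
            (0 < self.fdr_threshold < 1, "fdr_threshold in (0,1)"),
            (self.min_mean_reads >= 0, "min_mean_reads >= 0"),
            (0 < self.coding_alpha < 1, "coding_alpha in (0,1)"),
        ]
        for ok, what in checks:
            if not ok:
                raise ValueError(f"invalid config: requires {what}")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _read_genome(path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def _stage(manifest: dict, name: str, n_in: int, n_out: int, **extra) -> None:
    manifest["stages"].append({"stage": name, "n_in": n_in, "n_out": n_out, **extra})


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full chain; returns the manifest (also written to outdir).

    Reports written: merged.gtf, candidates.gtf, context.tsv,
    projection.tsv, projected.gtf, coding_conservation.tsv, de_<contrast>.tsv,
    conservation_report.tsv, summary.json, manifest.json.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "config": dataclasses.asdict(config),
        "stages": [],
    }

    # stage 1: merge per-sample assemblies -------------------------------
    genome = _read_genome(config.src_genome)
    sample_sets = [read_gtf(p) for p in config.sample_gtfs]
    merged = merge_transcripts(sample_sets, genome_seq_ids=set(genome))
    _stage(manifest, "merge", sum(len(s) for s in sample_sets), len(merged))
    write_gtf(merged, outdir / "merged.gtf")

    # stage 2: structural filter -----------------------------------------
    fcfg = FilterConfig(
        min_length_bp=config.min_length_bp,
        min_exons=config.min_exons,
        coding_score_threshold=config.coding_score_threshold,
    )
    structural, removed_structural = filter_structural(merged, fcfg)
    _stage(manifest, "structural_filter", len(merged), len(structural))

    # stage 3: coding-potential screen -----------------------------------
    src_coding = read_gtf(config.src_coding_gtf)
    if config.coding_model:
        model = CodingPotentialModel.load(config.coding_model)
    else:
        coding_seqs, noncoding_seqs = generate_training_sequences(
            n_per_class=60, seed=config.seed
        )
        model = train_coding_model(coding_seqs, noncoding_seqs, seed=config.seed)
    candidates, removed_coding = filter_coding_potential(
        structural, genome, model, fcfg, coding_annotation=src_coding
    )
    _stage(manifest, "coding_filter", len(structural), len(candidates))
    write_gtf(candidates, outdir / "candidates.gtf")
    removal_rows = [
        {"transcript_id": tid, "reason": reason, "score": ""}
        for tid, reason in removed_structural
    ] + [
        {"transcript_id": tid, "reason": reason, "score": score}
        for tid, reason, score in removed_coding
    ]
    pd.DataFrame(removal_rows).to_csv(outdir / "removed.tsv", sep="\t", index=False)

    # stage 4: genomic-context classification ----------------------------
    calls, tally = classify_all(candidates, src_coding, window_bp=config.window_bp)
    _stage(manifest, "classify", len(candidates), len(calls), tally=tally)
    pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "class": c.context,
                "orientation": c.orientation,
                "subtype": c.subtype,
                "nearest_gene": c.nearest_coding_gene_id or "",
                "distance_bp": c.distance_bp,
            }
            for c in calls
        ]
    ).to_csv(outdir / "context.tsv", sep="\t", index=False)

    # stage 5: ortholog projection ---------------------------------------
    blocks = read_maf(config.maf)
    projections = {}
    for gid in candidates.gene_ids:
        projections[gid] = project_gene(
            candidates.gene_transcripts(gid),
            blocks,
            identity_threshold=config.identity_threshold,
            coverage_threshold=config.coverage_threshold,
        )
    ortholog_genes = sorted(g for g, p in projections.items() if p.ortholog_call)
    _stage(manifest, "project", len(projections), len(ortholog_genes))
    projected, proj_summary, _flags = build_target_annotation(
        candidates, projections, min_transcript_bp=config.min_length_bp
    )
    write_gtf(projected, outdir / "projected.gtf")
    pd.DataFrame(
        [
            {
                "gene_id": g,
                "identity": "" if p.gene_identity is None else round(p.gene_identity, 4),
                "coverage": round(p.gene_coverage, 4),
                "ortholog_call": p.ortholog_call,
                "reason": p.reason,
            }
            for g, p in sorted(projections.items())
        ]
    ).to_csv(outdir / "projection.tsv", sep="\t", index=False)

    # stage 6: coding-conservation purge ---------------------------------
    alignments: dict[str, tuple[str, str] | None] = {}
    for gid in ortholog_genes:
        for t in candidates.gene_transcripts(gid):
            src_aln, tgt_aln = spliced_alignment(t, blocks)
            alignments[t.transcript_id] = (src_aln, tgt_aln) if src_aln else None
    retained_tids, removed_tids, cc_results = purge_coding_like(
        alignments, alpha=config.coding_alpha
    )
    coding_like_genes = {candidates[tid].gene_id for tid in removed_tids}
    conserved_genes = [g for g in ortholog_genes if g not in coding_like_genes]
    _stage(manifest, "coding_conservation", len(ortholog_genes), len(conserved_genes))
    pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "frame": r.best_frame,
                "n_sub": r.n_sub_total,
                "n_sub_pos3": r.n_sub_pos3,
                "p": r.p_value,
                "p_corrected": r.p_corrected,
                "flagged_coding": r.flagged_coding,
                "reason": r.reason,
            }
            for r in cc_results.values()
        ]
    ).to_csv(outdir / "coding_conservation.tsv", sep="\t", index=False)

    # stage 7: expression and DE -----------------------------------------
    cond_map = pd.read_csv(config.conditions_tsv, sep="\t", index_col=0)[
        "condition"
    ].to_dict()
    cm = CountMatrix.read_tsv(
        config.counts_tsv, cond_map, lengths_path=config.lengths_tsv or None
    )
    if cm.lengths is not None:
        compute_tpm(cm.counts, cm.lengths).to_csv(outdir / "tpm.tsv", sep="\t")
    native = cm.samples_for(config.cond_native)
    retina = cm.samples_for(config.cond_retina)
    expressed_native = set(
        cm.counts.index[call_expressed(cm.counts, native, config.min_mean_reads)]
    )
    expressed_retina = set(
        cm.counts.index[call_expressed(cm.counts, retina, config.min_mean_reads)]
    )
    de_sets: dict[str, set[str]] = {}
    for contrast, group_b in (
        ("retina_vs_native", retina),
        ("cult4w_vs_native", cm.samples_for(config.cond_cult4)),
        ("cult8w_vs_native", cm.samples_for(config.cond_cult8)),
    ):
        results = apply_deg_thresholds(
            nb_de_test(cm.counts, native, group_b),
            fc_threshold=config.fc_threshold,
            fdr_threshold=config.fdr_threshold,
        )
        de_table(results).to_csv(outdir / f"de_{contrast}.tsv", sep="\t")
        de_sets[contrast] = {r.feature_id for r in results if r.is_deg}
    _stage(
        manifest,
        "expression",
        len(cm.counts),
        sum(len(s) for s in de_sets.values()),
        de_counts={k: len(v) for k, v in de_sets.items()},
    )

    # stage 8: conserved selection ---------------------------------------
    selection = select_candidates(
        de_sets["retina_vs_native"],
        de_sets["cult4w_vs_native"],
        de_sets["cult8w_vs_native"],
        expressed_native,
        expressed_retina,
    )
    tgt_coding = read_gtf(config.tgt_coding_gtf)
    conserved_candidates = [
        g for g in selection.candidates if g in set(conserved_genes)
    ]
    true_lnc, overlapping, unprojected = purge_target_coding_overlap(
        conserved_candidates, projected, tgt_coding
    )
    studied = config.studied_denominator or len(cm.counts)
    pct = conservation_fraction(len(true_lnc), studied)
    _stage(manifest, "select", len(selection.candidates), len(true_lnc))

    report = pd.DataFrame(
        [
            {
                "gene_id": g,
                "ortholog_call": projections[g].ortholog_call if g in projections else False,
                "candidate": g in set(selection.candidates),
                "rule": ";".join(selection.provenance.get(g, [])),
                "coding_like": g in coding_like_genes,
                "overlaps_target_coding": g in set(overlapping),
                "conserved_true_lncRNA": g in set(true_lnc),
            }
            for g in sorted(set(cm.counts.index) | set(projections))
        ]
    )
    report.to_csv(outdir / "conservation_report.tsv", sep="\t", index=False)

    summary = summarize(
        tally=tally,
        n_candidates_total=len(candidates),
        expressed_native=len(expressed_native),
        n_features=len(cm.counts),
        de_sets=de_sets,
        n_selected=len(selection.candidates),
        n_true=len(true_lnc),
        conservation_pct=pct,
    )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest["summary"] = summary
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def summarize(
    tally: dict[str, int],
    n_candidates_total: int,
    expressed_native: int,
    n_features: int,
    de_sets: dict[str, set[str]],
    n_selected: int,
    n_true: int,
    conservation_pct: float,
) -> dict:
    """Human-facing run summary: class tallies, expressed fraction (nearest
    whole percent), per-contrast DE counts with unique/common breakdown,
    candidate and true-lncRNA counts, and the conservation percentage."""
    de4 = de_sets.get("cult4w_vs_native", set())
    de8 = de_sets.get("cult8w_vs_native", set())
    expressed_pct = round(100.0 * expressed_native / n_features) if n_features else 0
    return {
        "context_tally": dict(tally),
        "context_total": sum(tally.values()),
        "n_lncRNA_candidates": n_candidates_total,
        "n_expressed_native": expressed_native,
        "expressed_pct": expressed_pct,
        "de_counts": {k: len(v) for k, v in de_sets.items()},
        "de_culture_unique_4wk": len(de4 - de8),
        "de_culture_unique_8wk": len(de8 - de4),
        "de_culture_common": len(de4 & de8),
        "n_candidates_selected": n_selected,
        "n_true_lncRNAs": n_true,
        "conservation_pct": conservation_pct,
    }
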