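"""Reduce merged transcripts to lncRNA candidates.

Two stages: structural filters (multi-exon, spliced length >= 200 bp — the
usual lncRNA definition) and a coding-potential screen.  The screen is a
logistic score over four classical sequence features (longest-ORF length,
ORF coverage, hexamer usage log-odds, GC fraction), trained on labelled
coding/noncoding sequences; it stands in for dedicated lncRNA classifiers
such as FEELnc and is deliberately swappable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.linear_model import LogisticRegression

from .genomic_model import AnnotationSet, Transcript

STOP_CODONS = {"TAA", "TAG", "TGA"}
_HEXAMERS = ["".join(p) for p in product("ACGT", repeat=6)]
_HEX_INDEX = {h: i for i, h in enumerate(_HEXAMERS)}


@dataclass
class FilterConfig:
    """Thresholds for candidate filtering."""

    min_length_bp: int = 200
    min_exons: int = 2
    coding_score_threshold: float = 0.5
    min_orf_aa: int = 30

    def __post_init__(self) -> None:
        if self.min_length_bp < 1 or self.min_exons < 1:
            raise ValueError("min_length_bp and min_exons must be >= 1")
        if not 0.0 <= self.coding_score_threshold <= 1.0:
            raise ValueError("coding_score_threshold must lie in [0, 1]")


def longest_orf(spliced_sequence: str) -> tuple[int, int, int, int]:
    """Longest ATG..stop ORF over the three forward frames.

    Returns ``(frame, start, end, aa_length)`` with ``start``/``end`` as
    0-based half-open nucleotide coordinates of the ORF including start and
    stop codons; ties go to the 5'-most start, then the lowest frame index.
    No ORF -> ``(0, 0, 0, 0)``.  An open reading through the 3' end without
    a stop codon does not count.
    """
    seq = spliced_sequence.upper()
    best = (0, 0, 0, 0)
    for frame in range(3):
        start = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                aa = (pos - start) // 3  # stop codon not counted as residue
                cand = (frame, start, pos + 3, aa)
                if aa > best[3] or (
                    aa == best[3]
                    and aa > 0
                    and (start, frame) < (best[1], best[0])
                ):
                    best = cand
                start = None
    return best


def _hexamer_counts(seq: str) -> np.ndarray:
    counts = np.zeros(len(_HEXAMERS))
    seq = seq.upper()
    for i in range(len(seq) - 5):
        idx = _HEX_INDEX.get(seq[i : i + 6])
        if idx is not None:
            counts[idx] += 1
    return counts


@dataclass
class CodingPotentialModel:
    """Logistic coding-potential score over four sequence features.

    Features: longest-ORF length (aa, log1p), ORF coverage fraction, mean
    per-hexamer log-odds (coding vs noncoding training frequencies), and GC
    fraction.  ``score`` maps any sequence to [0, 1]; higher means more
    coding-like.  The model serialises to flat key-value text and reloads
    bit-exactly.
    """

    weights: np.ndarray  # (4,)
    intercept: float
    feature_means: np.ndarray  # (4,)
    feature_scales: np.ndarray  # (4,)
    hexamer_log_odds: np.ndarray  # (4096,)
    training_accuracy: float = field(default=float("nan"))

    def features(self, sequence: str) -> np.ndarray:
        seq = sequence.upper()
        n = max(len(seq), 1)
        _frame, _s, _e, aa = longest_orf(seq)
        orf_nt = aa * 3 + 3 if aa > 0 else 0
        hex_counts = _hexamer_counts(seq)
        total = hex_counts.sum()
        hex_score = (
            float(hex_counts @ self.hexamer_log_odds / total) if total else 0.0
        )
        gc = (seq.count("G") + seq.count("C")) / n
        return np.array([math.log1p(aa), orf_nt / n, hex_score, gc])

    def score(self, sequence: str) -> float:
        x = (self.features(sequence) - self.feature_means) / self.feature_scales
        z = float(x @ self.weights + self.intercept)
        return 1.0 / (1.0 + math.exp(-z))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"intercept\t{self.intercept.hex()}\n")
            fh.write(f"training_accuracy\t{repr(self.training_accuracy)}\n")
            for name, arr in (
                ("weight", self.weights),
                ("mean", self.feature_means),
                ("scale", self.feature_scales),
            ):
                for i, v in enumerate(arr):
                    fh.write(f"{name}_{i}\t{float(v).hex()}\n")
            for h, v in zip(_HEXAMERS, self.hexamer_log_odds):
                if v != 0.0:
                    fh.write(f"hex_{h}\t{float(v).hex()}\n")

    @classmethod
    def load(cls, path) -> "CodingPotentialModel":
        kv: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                k, v = line.rstrip("\n").split("\t")
                kv[k] = v
        hexes = np.zeros(len(_HEXAMERS))
        for k, v in kv.items():
            if k.startswith("hex_"):
                hexes[_HEX_INDEX[k[4:]]] = float.fromhex(v)
        pick = lambda name: np.array(
            [float.fromhex(kv[f"{name}_{i}"]) for i in range(4)]
        )
        return cls(
            weights=pick("weight"),
            intercept=float.fromhex(kv["intercept"]),
            feature_means=pick("mean"),
            feature_scales=pick("scale"),
            hexamer_log_odds=hexes,
            training_accuracy=float(kv["training_accuracy"]),
        )


def train_coding_model(
    coding_seqs: list[str], noncoding_seqs: list[str], seed: int = 0
) -> CodingPotentialModel:
    """Fit the logistic coding-potential model on labelled sequences.

    Requires >= 20 sequences per class.  Deterministic given the seed (the
    seed fixes the training-order shuffle; the lbfgs fit itself is
    deterministic).
    """
    if len(coding_seqs) < 20 or len(noncoding_seqs) < 20:
        raise ValueError(
            "need >= 20 training sequences per class; provide more labelled "
            f"data (got {len(coding_seqs)} coding, {len(noncoding_seqs)} noncoding)"
        )
    # hexamer log-odds from training counts, additive pseudocount 1
    c_counts = np.ones(len(_HEXAMERS))
    n_counts = np.ones(len(_HEXAMERS))
    for s in coding_seqs:
        c_counts += _hexamer_counts(s)
    for s in noncoding_seqs:
        n_counts += _hexamer_counts(s)
    log_odds = np.log(c_counts / c_counts.sum()) - np.log(n_counts / n_counts.sum())

    shell = CodingPotentialModel(
        weights=np.zeros(4),
        intercept=0.0,
        feature_means=np.zeros(4),
        feature_scales=np.ones(4),
        hexamer_log_odds=log_odds,
    )
    X = np.array([shell.features(s) for s in coding_seqs + noncoding_seqs])
    y = np.array([1] * len(coding_seqs) + [0] * len(noncoding_seqs))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    X, y = X[order], y[order]

    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0
    Xs = (X - means) / scales
    clf = LogisticRegression(C=1.0, max_iter=1000)
    clf.fit(Xs, y)
    acc = float((clf.predict(Xs) == y).mean())
    return CodingPotentialModel(
        weights=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        feature_means=means,
        feature_scales=scales,
        hexamer_log_odds=log_odds,
        training_accuracy=acc,
    )


def filter_structural(
    transcripts: AnnotationSet, config: FilterConfig | None = None
) -> tuple[AnnotationSet, list[tuple[str, str]]]:
    """Keep multi-exon transcripts of sufficient spliced length.

    Returns ``(kept, removed)`` where ``removed`` is a list of
    ``(transcript_id, reason)`` pairs; reasons are ``single_exon`` (checked
    first) or ``too_short``.  Kept and removed partition the input.
    """
    config = config or FilterConfig()
    kept = AnnotationSet()
    removed: list[tuple[str, str]] = []
    for t in transcripts:
        if t.n_exons < config.min_exons:
            removed.append((t.transcript_id, "single_exon"))
        elif t.length < config.min_length_bp:
            removed.append((t.transcript_id, "too_short"))
        else:
            kept.add(t)
    return kept, removed


def filter_coding_potential(
    transcripts: AnnotationSet,
    genome,
    model: CodingPotentialModel,
    config: FilterConfig | None = None,
    coding_annotation: AnnotationSet | None = None,
) -> tuple[AnnotationSet, list[tuple[str, str, float]]]:
    """Drop transcripts that look protein-coding.

    A transcript is removed when (a) any exon overlaps an annotated
    protein-coding exon on the same strand (``annotation_overlap``), or
    (b) its coding-potential score reaches the threshold (``coding_score``).
    Antisense overlap alone does not remove (handled later as genic
    antisense context).  Returns ``(lncRNA_candidates, removed)`` with
    removed entries ``(transcript_id, reason, score)``.
    """
    config = config or FilterConfig()
    kept = AnnotationSet()
    removed: list[tuple[str, str, float]] = []
    for t in transcripts:
        if t.seq_id not in genome:
            raise ValueError(
                f"transcript {t.transcript_id}: sequence {t.seq_id} missing "
                "from genome"
            )
        overlap = False
        if coding_annotation is not None:
            for e in t.exons:
                hits = coding_annotation.exon_overlapping(
                    e.seq_id, e.start, e.end, strand=t.strand
                )
                if any(h.biotype == "coding" for h in hits):
                    overlap = True
                    break
        if overlap:
            removed.append((t.transcript_id, "annotation_overlap", float("nan")))
            continue
        score = model.score(t.spliced_sequence(genome))
        if score >= config.coding_score_threshold:
            removed.append((t.transcript_id, "coding_score", score))
        else:
            kept.add(t)
    return kept, removed
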