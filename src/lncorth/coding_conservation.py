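"""Screen for cryptic coding loci by their cross-species substitution pattern.

Protein-coding sequence evolving under purifying selection tolerates
substitutions preferentially at third codon positions (mostly synonymous),
while genuinely noncoding sequence accumulates them uniformly.  For a
pairwise alignment of a transcript and its ortholog we therefore test, in
each of the three forward reading frames, whether substitutions concentrate
at third positions beyond what a uniform null allows: a one-sided exact
binomial test on the number of substitution columns falling at position 3,
with the null success probability equal to the fraction of counted columns
assigned to position 3 (≈ 1/3).  The smallest of the three frame p-values,
Bonferroni-corrected by 3, flags the locus as coding-like.

Gap and N columns are excluded from both numerator and denominator, which
makes the statistic symmetric in which species is called source.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binom

MIN_UNGAPPED_COLUMNS = 90


@dataclass
class CodingConservationResult:
    transcript_id: str
    best_frame: int
    n_sub_total: int
    n_sub_pos3: int
    statistic: float  # third-position substitution excess (observed - expected fraction)
    p_value: float  # best-frame one-sided exact binomial p (uncorrected)
    p_corrected: float  # Bonferroni x3, capped at 1
    flagged_coding: bool
    reason: str = "ok"


def _frame_test(
    src: str, tgt: str, frame: int
) -> tuple[int, int, float, float]:
    """Counts and binomial p for one frame.

    Columns are indexed along counted (ungapped, non-N) positions; column k
    sits at codon position ((k - frame) mod 3) + 1.
    """
    n_counted = 0
    n_pos3 = 0
    n_sub = 0
    n_sub_pos3 = 0
    k = 0
    for a, b in zip(src, tgt):
        if a in "-N" or b in "-N":
            continue
        pos3 = (k - frame) % 3 == 2
        n_counted += 1
        if pos3:
            n_pos3 += 1
        if a != b:
            n_sub += 1
            if pos3:
                n_sub_pos3 += 1
        k += 1
    if n_sub == 0 or n_counted == 0:
        return n_sub, n_sub_pos3, 0.0, 1.0
    p_null = n_pos3 / n_counted
    # one-sided upper tail: P(X >= n_sub_pos3 | n_sub, p_null)
    p = float(binom.sf(n_sub_pos3 - 1, n_sub, p_null))
    stat = n_sub_pos3 / n_sub - p_null
    return n_sub, n_sub_pos3, stat, p


def codon_position_test(
    transcript_id: str,
    src_aligned: str,
    tgt_aligned: str,
    alpha: float = 0.01,
) -> CodingConservationResult:
    """Third-position substitution-excess test on a gapped pairwise alignment.

    Requires >= 90 ungapped columns; shorter alignments return an unflagged
    result with reason ``too_short``.  Identical sequences give p = 1.
    """
    if len(src_aligned) != len(tgt_aligned):
        raise ValueError("aligned rows have unequal length")
    src = src_aligned.upper()
    tgt = tgt_aligned.upper()
    n_ungapped = sum(
        1 for a, b in zip(src, tgt) if a not in "-N" and b not in "-N"
    )
    if n_ungapped < MIN_UNGAPPED_COLUMNS:
        return CodingConservationResult(
            transcript_id, 0, 0, 0, 0.0, 1.0, 1.0, False, reason="too_short"
        )
    best = None
    for frame in range(3):
        n_sub, n_sub3, stat, p = _frame_test(src, tgt, frame)
        if best is None or p < best[3]:
            best = (frame, n_sub, n_sub3, p, stat)
    frame, n_sub, n_sub3, p, stat = best[0], best[1], best[2], best[3], best[4]
    p_corr = min(1.0, 3.0 * p)
    return CodingConservationResult(
        transcript_id=transcript_id,
        best_frame=frame,
        n_sub_total=n_sub,
        n_sub_pos3=n_sub3,
        statistic=stat,
        p_value=p,
        p_corrected=p_corr,
        flagged_coding=p_corr < alpha,
    )


def purge_coding_like(
    alignments: dict[str, tuple[str, str] | None],
    alpha: float = 0.01,
) -> tuple[list[str], list[str], dict[str, CodingConservationResult]]:
    """Partition transcripts into retained and removed by the coding screen.

    ``alignments`` maps transcript_id to its (source, target) spliced
    pairwise alignment, or None when the transcript has no projection.
    Untestable transcripts are retained with reason ``untestable``.
    Returns (retained_ids, removed_ids, results).
    """
    retained: list[str] = []
    removed: list[str] = []
    results: dict[str, CodingConservationResult] = {}
    for tid in sorted(alignments):
        aln = alignments[tid]
        if aln is None:
            results[tid] = CodingConservationResult(
                tid, 0, 0, 0, 0.0, 1.0, 1.0, False, reason="untestable"
            )
            retained.append(tid)
            continue
        res = codon_position_test(tid, aln[0], aln[1], alpha=alpha)
        results[tid] = res
        (removed if res.flagged_coding else retained).append(tid)
    return retained, removed, results
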