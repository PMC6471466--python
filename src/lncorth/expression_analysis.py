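"""Expression summaries and a simple negative-binomial differential test.

TPM normalisation, a mean-raw-count expressed call, and a per-feature NB
Wald test with median-of-ratios size factors, method-of-moments dispersion
and Benjamini-Hochberg FDR — a transparent stand-in for full DE machinery
(no dispersion shrinkage, no outlier filtering) applying the selection
thresholds: fold change strictly above 2 and FDR strictly below 0.01.

The Wald p-value uses a Student-t reference with nA+nB-2 degrees of
freedom rather than a normal one: with the handful of replicates typical of
these designs the plug-in variance makes the normal reference
anti-conservative, and the t reference restores near-nominal type-I error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Integer read counts, features x samples, with a condition per sample."""

    counts: pd.DataFrame  # features x samples
    conditions: dict[str, str]  # sample -> condition
    lengths: pd.Series | None = None  # feature lengths in bp (for TPM)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without a condition: {sorted(missing)}")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any() or (self.lengths <= 0).any():
                raise ValueError("every feature needs a positive length")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    @classmethod
    def read_tsv(cls, counts_path, conditions: dict[str, str], lengths_path=None):
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        lengths = None
        if lengths_path is not None:
            lengths = pd.read_csv(
                lengths_path, sep="\t", index_col=0
            ).iloc[:, 0]
        return cls(counts=counts, conditions=conditions, lengths=lengths)


@dataclass
class DEResult:
    feature_id: str
    base_mean: float
    log2_fc: float  # condition B over A
    p_value: float
    fdr: float
    is_deg: bool = False


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: reads per kb, scaled so each column sums to 1e6.

    All-zero samples stay all-zero (no NaN).
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive length in bp")
    rpk = counts.div(lengths / 1000.0, axis=0)
    denom = rpk.sum(axis=0)
    tpm = rpk.div(denom.replace(0, np.nan), axis=1) * 1e6
    return tpm.fillna(0.0)


def call_expressed(
    counts: pd.DataFrame, samples: list[str], min_mean_reads: float = 20
) -> pd.Series:
    """Expressed iff the mean raw count over the selected samples reaches the
    threshold (boundary inclusive)."""
    if not samples:
        raise ValueError("need at least one sample")
    return counts[samples].mean(axis=1) >= min_mean_reads


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over features with all-positive counts."""
    log_counts = np.log(counts.where(counts > 0))
    log_geo = log_counts.mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        return pd.Series(1.0, index=counts.columns)
    ratios = log_counts.loc[usable].sub(log_geo[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    return sf.fillna(1.0)


def nb_de_test(
    counts: pd.DataFrame, group_a: list[str], group_b: list[str]
) -> list[DEResult]:
    """Per-feature NB Wald test of condition B over condition A.

    Normalises by median-of-ratios size factors; estimates a per-feature
    method-of-moments NB dispersion (variance mu + alpha*mu^2, alpha floored
    at 1e-8); tests the log2 ratio of group means (pseudocount 0.5) with a
    delta-method standard error and a two-sided t(nA+nB-2) p-value.
    Swapping the groups negates log2_fc and preserves p.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    sub = counts[list(group_a) + list(group_b)]
    sf = size_factors(sub)
    norm = sub.div(sf, axis=1)
    A = norm[list(group_a)].values
    B = norm[list(group_b)].values
    nA, nB = A.shape[1], B.shape[1]
    mu_a = A.mean(axis=1)
    mu_b = B.mean(axis=1)
    base_mean = norm.mean(axis=1).values

    # pooled method-of-moments dispersion: var = mu + alpha mu^2
    var_a = A.var(axis=1, ddof=1)
    var_b = B.var(axis=1, ddof=1)
    mu_pool = (nA * mu_a + nB * mu_b) / (nA + nB)
    var_pool = ((nA - 1) * var_a + (nB - 1) * var_b) / (nA + nB - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_pool - mu_pool) / np.square(mu_pool)
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    lfc = np.log2(mu_b + PSEUDOCOUNT) - np.log2(mu_a + PSEUDOCOUNT)
    nb_var_a = mu_a + alpha * np.square(mu_a)
    nb_var_b = mu_b + alpha * np.square(mu_b)
    ln2sq = math.log(2) ** 2
    se2 = (
        nb_var_a / (nA * np.square(mu_a + PSEUDOCOUNT))
        + nb_var_b / (nB * np.square(mu_b + PSEUDOCOUNT))
    ) / ln2sq
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, lfc / se, 0.0)
    df = nA + nB - 2
    p = 2.0 * stats.t.sf(np.abs(wald), df)
    p = np.minimum(p, 1.0)
    # features with no counts at all carry no evidence
    p = np.where((mu_a == 0) & (mu_b == 0), 1.0, p)

    return [
        DEResult(
            feature_id=f,
            base_mean=float(bm),
            log2_fc=float(l),
            p_value=float(pv),
            fdr=float("nan"),
        )
        for f, bm, l, pv in zip(sub.index, base_mean, lfc, p)
    ]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjustment; adjusted >= raw, capped at 1, monotone."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_deg_thresholds(
    results: list[DEResult],
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.01,
) -> list[DEResult]:
    """Attach BH FDR and the DEG flag: |fold change| strictly > fc_threshold
    and FDR strictly < fdr_threshold (two-sided)."""
    if not results:
        return results
    fdr = benjamini_hochberg([r.p_value for r in results])
    log2_cut = math.log2(fc_threshold)
    for r, q in zip(results, fdr):
        r.fdr = float(q)
        r.is_deg = abs(r.log2_fc) > log2_cut and r.fdr < fdr_threshold
    return results


def de_table(results: list[DEResult]) -> pd.DataFrame:
    """Results as a DataFrame with conventional column names."""
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "Base Mean": [r.base_mean for r in results],
            "Fold Change": [r.log2_fc for r in results],  # log2 scale
            "pvalue": [r.p_value for r in results],
            "padj": [r.fdr for r in results],
            "is_deg": [r.is_deg for r in results],
        }
    ).set_index("feature_id")
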