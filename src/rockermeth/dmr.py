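"""Intra-segment testing, filtering and DMR classification (pipeline step 3).

Each non-neutral Viterbi segment is tested for tumor/normal difference with
a two-sided Wilcoxon-Mann-Whitney test on the CpG-wise averaged beta values
(one average per site per group).  P-values are Benjamini-Hochberg adjusted
over all tested segments of the run; segments with FDR >= alpha or fewer
than ``min_sites`` sites are discarded.  Surviving segments are classified
as

    hyper       gain of methylation, any length,
    hypo        loss of methylation, length <= hypo_block_len (10 kb),
    hypo_block  loss of methylation, length  > hypo_block_len,

where hypo-blocks are the operative proxy for partially methylated domains.
"""

from __future__ import annotations

from typing import Iterable, List, Optional

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .config import RunConfig, DEFAULT_CONFIG
from .io import BetaMatrix, SEGMENT_COLUMNS

#: Largest group size at which the exact WMW null distribution is used
#: (ties force the normal approximation with tie/continuity correction).
EXACT_WMW_MAX_N = 25


def segment_wmw_test(
    tumor_site_means: np.ndarray, normal_site_means: np.ndarray
) -> float:
    """Two-sided rank-sum p-value comparing per-site group mean betas.

    Exact distribution when both vectors have <= 25 entries and no ties
    across the pooled values; otherwise the normal approximation with tie
    and continuity correction.  Returns NaN when either vector is empty
    after removing missing values.
    """
    a = np.asarray(tumor_site_means, dtype=float)
    b = np.asarray(normal_site_means, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        return float("nan")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact"
        if (a.size <= EXACT_WMW_MAX_N and b.size <= EXACT_WMW_MAX_N and not has_ties)
        else "asymptotic"
    )
    return float(
        mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def adjust_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up; NaNs pass through untouched."""
    p = np.asarray(list(pvalues), dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def split_by_max_distance(
    segment: pd.Series, sites: pd.DataFrame, max_distance: Optional[float]
) -> List[pd.Series]:
    """Cut one segment at every inter-site gap larger than ``max_distance``.

    ``segment`` is a row of the segment table (with i0/i1 site indices into
    ``sites``).  Returns the list of sub-segments (the original when no gap
    exceeds the threshold or splitting is disabled); sub-segments cover
    exactly the original site range.
    """
    if max_distance is None:
        return [segment]
    i0, i1 = int(segment["i0"]), int(segment["i1"])
    pos = sites["pos"].to_numpy()[i0 : i1 + 1]
    gaps = np.diff(pos)
    cut_after = np.nonzero(gaps > max_distance)[0]
    if cut_after.size == 0:
        return [segment]
    bounds = np.concatenate([[0], cut_after + 1, [len(pos)]])
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        sub = segment.copy()
        sub["i0"], sub["i1"] = i0 + int(a), i0 + int(b) - 1
        sub["start"], sub["end"] = int(pos[a]), int(pos[b - 1])
        sub["n_sites"] = int(b - a)
        out.append(sub)
    return out


def classify_dmr(state_code: int, length_bp: float, config: RunConfig) -> str:
    """Direction + length -> DMR class label (hyper / hypo / hypo_block)."""
    if state_code == 3:
        return "hyper"
    if state_code == 1:
        return "hypo_block" if length_bp > config.hypo_block_len else "hypo"
    raise ValueError("neutral segments are never DMR candidates")


def segment_statistics(
    segments: pd.DataFrame,
    tumor: BetaMatrix,
    normal: BetaMatrix,
    auc: np.ndarray,
    config: RunConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Attach statistics (WMW p, FDR, mean AUC, mean beta diff) to segments.

    Only non-neutral segments enter the test and the BH family; neutral
    segments keep NaN statistics but remain in the table (they are needed
    as denominators for genome-fraction summaries).  When ``max_distance``
    is configured, non-neutral segments are split at large gaps first and
    the sub-segments are tested individually.
    """
    t_means = np.nanmean(tumor.values, axis=1)
    n_means = np.nanmean(normal.values, axis=1)

    rows: List[pd.Series] = []
    for _, seg in segments.iterrows():
        if seg["state_code"] == 2:
            rows.append(seg)
        else:
            rows.extend(split_by_max_distance(seg, tumor.sites, config.max_distance))
    table = pd.DataFrame(rows).reset_index(drop=True)

    pvals = np.full(len(table), np.nan)
    mean_auc = np.full(len(table), np.nan)
    beta_diff = np.full(len(table), np.nan)
    for i, seg in table.iterrows():
        i0, i1 = int(seg["i0"]), int(seg["i1"])
        sl = slice(i0, i1 + 1)
        mean_auc[i] = float(np.nanmean(auc[sl]))
        beta_diff[i] = float(np.nanmean(t_means[sl]) - np.nanmean(n_means[sl]))
        if seg["state_code"] != 2:
            pvals[i] = segment_wmw_test(t_means[sl], n_means[sl])
    table["mean_auc"] = mean_auc
    table["mean_beta_diff"] = beta_diff
    table["p_value"] = pvals
    table["fdr"] = adjust_fdr(pvals)
    table["length_bp"] = table["end"].astype(int) - table["start"].astype(int) + 1
    return table


def filter_segments(
    tested: pd.DataFrame, config: RunConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Select and classify DMRs from the tested segment table.

    Keeps non-neutral segments with ``FDR < fdr_alpha`` and
    ``n_sites >= min_sites`` (both boundaries literal: FDR exactly at alpha
    is discarded, ``min_sites`` sites are kept).  Returns the canonical DMR
    table sorted by (chrom, start) with states relabelled through
    :func:`classify_dmr`.
    """
    cand = tested[tested["state_code"] != 2].copy()
    keep = (
        np.isfinite(cand["fdr"].to_numpy())
        & (cand["fdr"].to_numpy() < config.fdr_alpha)
        & (cand["n_sites"].to_numpy() >= config.min_sites)
    )
    cand = cand[keep].copy()
    if len(cand):
        cand["state"] = [
            classify_dmr(int(sc), float(lb), config)
            for sc, lb in zip(cand["state_code"], cand["length_bp"])
        ]
    out_cols = list(SEGMENT_COLUMNS) + ["i0", "i1", "state_code"]
    if len(cand) == 0:
        return pd.DataFrame(columns=out_cols)
    return cand[out_cols].reset_index(drop=True)


def dmr_burden(dmrs: pd.DataFrame, segments: pd.DataFrame) -> dict:
    """Fraction of the segmented genome covered by gain / loss DMRs.

    The denominator is the total genomic span of *all* segments (including
    neutral); numerators sum DMR lengths by direction (hypo and hypo_block
    both count as loss).
    """
    if len(segments) == 0:
        raise ValueError("empty segmentation: burden undefined")
    span = float(
        (segments["end"].astype(int) - segments["start"].astype(int) + 1).sum()
    )
    out = {"gain": 0.0, "loss": 0.0}
    if len(dmrs):
        lengths = dmrs["length_bp"].astype(float)
        gain = lengths[dmrs["state"] == "hyper"].sum()
        loss = lengths[dmrs["state"].isin(["hypo", "hypo_block"])].sum()
        out = {"gain": float(gain) / span, "loss": float(loss) / span}
    return out
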