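"""Per-sample / per-cell DMR scoring (pipeline step 4).

For a DMR *z* and sample *i*, the sample score is a robust Z-score of the
sample's median beta inside the DMR against the normal-reference
distribution of the same quantity:

    score_iz = (b_iz - median_j(b_jz)) / mad_j(b_jz),

where b_iz is the median beta (percent) of the sample's CpG sites inside
the DMR, j runs over normal samples, and the denominator is floored at one
percentage point to avoid exploding scores in ultra-stable regions.  A DMR
counts as *supported* in a sample when the score strictly exceeds +3
(gain) or falls strictly below -3 (loss); the per-sample fraction of
supporting events (PSFSE) averages this support over all catalog DMRs of
one class.  The per-cell variant (PCFSE) additionally drops cells with too
much missing data inside any DMR class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .config import RunConfig, DEFAULT_CONFIG
from .io import BetaMatrix

#: DMR classes for which support fractions are reported.
SCORE_CLASSES = ("hyper", "hypo", "hypo_block")

#: Loss-direction classes (supported at score < -threshold).
LOSS_CLASSES = frozenset({"hypo", "hypo_block"})


@dataclass
class SampleScoreMatrix:
    """Sample scores plus per-(DMR, sample) missingness bookkeeping."""

    scores: pd.DataFrame          # dmr_id x sample
    missing_frac: pd.DataFrame    # dmr_id x sample, fraction of DMR sites missing
    dmr_states: pd.Series         # dmr_id -> class label
    reference: pd.DataFrame       # dmr_id -> (median, dispersion) of normals


def _dispersion(x: np.ndarray, estimator: str) -> float:
    if estimator == "scaled_mad":
        return float(median_abs_deviation(x, scale="normal"))
    if estimator == "raw_mad":
        return float(median_abs_deviation(x, scale=1.0))
    if estimator == "max_abs_dev":
        return float(np.max(np.abs(x - np.median(x))))
    raise ValueError(f"unknown dispersion estimator {estimator!r}")


def rocker_sample_score(
    sample_median: float,
    normal_medians: np.ndarray,
    estimator: str = "scaled_mad",
    mad_floor: float = 1.0,
) -> float:
    """Score one (DMR, sample) pair from already-computed medians (percent).

    The reference dispersion across normal samples is floored at
    ``mad_floor`` (one percentage point by default).
    """
    ref = np.asarray(normal_medians, dtype=float)
    ref = ref[np.isfinite(ref)]
    if not np.isfinite(sample_median) or ref.size == 0:
        return float("nan")
    center = float(np.median(ref))
    disp = max(_dispersion(ref, estimator), mad_floor)
    return (float(sample_median) - center) / disp


def score_matrix(
    dmrs: pd.DataFrame,
    query: BetaMatrix,
    normal: BetaMatrix,
    config: RunConfig = DEFAULT_CONFIG,
) -> SampleScoreMatrix:
    """Sample scores for every (catalog DMR, query sample) pair.

    ``dmrs`` is a canonical DMR table (1-based inclusive chrom/start/end
    plus state); query and normal matrices need not share the catalog's
    full site set — each DMR uses whatever assayed sites fall inside its
    bounds.  Samples with no non-missing site in a DMR get a NaN score.
    """
    q_sites = query.sites
    n_sites = normal.sites
    dmr_ids = [f"{r.chrom}:{int(r.start)}-{int(r.end)}" for r in dmrs.itertuples()]
    scores = np.full((len(dmrs), query.n_samples), np.nan)
    miss = np.ones((len(dmrs), query.n_samples))
    ref_rows = []

    q_by_chrom = {c: g for c, g in q_sites.groupby("chrom", sort=False)}
    n_by_chrom = {c: g for c, g in n_sites.groupby("chrom", sort=False)}
    for r, dmr in enumerate(dmrs.itertuples()):
        lo, hi = int(dmr.start), int(dmr.end)
        qg = q_by_chrom.get(dmr.chrom)
        ng = n_by_chrom.get(dmr.chrom)
        q_idx = (
            qg.index[(qg["pos"] >= lo) & (qg["pos"] <= hi)].to_numpy()
            if qg is not None
            else np.array([], dtype=int)
        )
        n_idx = (
            ng.index[(ng["pos"] >= lo) & (ng["pos"] <= hi)].to_numpy()
            if ng is not None
            else np.array([], dtype=int)
        )
        if n_idx.size:
            with np.errstate(all="ignore"):
                normal_medians = np.nanmedian(normal.values[n_idx], axis=0)
        else:
            normal_medians = np.array([np.nan])
        ref = normal_medians[np.isfinite(normal_medians)]
        center = float(np.median(ref)) if ref.size else np.nan
        disp = (
            max(_dispersion(ref, config.mad_estimator), 1.0) if ref.size else np.nan
        )
        ref_rows.append({"median": center, "dispersion": disp})
        if q_idx.size == 0 or not np.isfinite(center):
            continue
        vals = query.values[q_idx]
        miss[r] = np.mean(~np.isfinite(vals), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            q_medians = np.nanmedian(vals, axis=0)
        scores[r] = (q_medians - center) / disp

    samples = [str(s) for s in query.samples]
    return SampleScoreMatrix(
        scores=pd.DataFrame(scores, index=dmr_ids, columns=samples),
        missing_frac=pd.DataFrame(miss, index=dmr_ids, columns=samples),
        dmr_states=pd.Series(list(dmrs["state"]), index=dmr_ids),
        reference=pd.DataFrame(ref_rows, index=dmr_ids),
    )


def psfse(
    scores: pd.Series,
    dmr_states: pd.Series,
    direction: str,
    threshold: float = 3.0,
    drop_missing_from_denominator: bool = False,
) -> float:
    """Fraction of one class's DMRs supported in one sample.

    Gain support: score > threshold; loss support (hypo and hypo_block):
    score < -threshold.  The inequality is strict (a score of exactly +/-3
    does not count).  Missing scores never count as support; by default
    they stay in the denominator.
    """
    if direction not in SCORE_CLASSES:
        raise ValueError(f"direction must be one of {SCORE_CLASSES}, got {direction!r}")
    mask = dmr_states == direction
    n_dir = int(mask.sum())
    if n_dir == 0:
        return float("nan")
    s = scores[mask].to_numpy(dtype=float)
    finite = np.isfinite(s)
    if direction in LOSS_CLASSES:
        support = finite & (s < -threshold)
    else:
        support = finite & (s > threshold)
    denom = int(finite.sum()) if drop_missing_from_denominator else n_dir
    if denom == 0:
        return float("nan")
    return float(support.sum()) / denom


def psfse_table(
    matrix: SampleScoreMatrix,
    threshold: float = 3.0,
    drop_missing_from_denominator: bool = False,
) -> pd.DataFrame:
    """PSFSE per sample (rows) and DMR class (columns)."""
    out = {}
    for direction in SCORE_CLASSES:
        if not (matrix.dmr_states == direction).any():
            continue
        out[direction] = [
            psfse(
                matrix.scores[c],
                matrix.dmr_states,
                direction,
                threshold,
                drop_missing_from_denominator,
            )
            for c in matrix.scores.columns
        ]
    return pd.DataFrame(out, index=matrix.scores.columns)


def pcfse(
    matrix: SampleScoreMatrix,
    missing_cap: float = 0.5,
    threshold: float = 3.0,
) -> pd.DataFrame:
    """Per-cell support fractions with a missing-data gate.

    A cell is kept only when, within *every* DMR class present in the
    catalog, the fraction of missing beta values across that class's DMRs
    is below ``missing_cap``.  Missing scores are dropped from the PSFSE
    denominator (sparse single-cell assays would otherwise bound the
    fraction artificially).
    """
    classes = [c for c in SCORE_CLASSES if (matrix.dmr_states == c).any()]
    keep = []
    for cell in matrix.scores.columns:
        ok = True
        for cls in classes:
            m = matrix.missing_frac.loc[matrix.dmr_states == cls, cell]
            if float(m.mean()) >= missing_cap:
                ok = False
                break
        if ok:
            keep.append(cell)
    if not keep:
        import logging

        logging.getLogger("rockermeth").warning(
            "all cells exceed the %.0f%% missingness cap", 100 * missing_cap
        )
        return pd.DataFrame(columns=classes)
    sub = SampleScoreMatrix(
        scores=matrix.scores[keep],
        missing_frac=matrix.missing_frac[keep],
        dmr_states=matrix.dmr_states,
        reference=matrix.reference,
    )
    return psfse_table(sub, threshold, drop_missing_from_denominator=True)
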