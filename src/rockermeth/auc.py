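"""Per-site ROC-AUC of tumor versus normal beta values (pipeline step 1).

The area under the ROC curve for a single CpG site equals the normalised
Mann-Whitney U statistic

    AUC = (#{(t, n): t > n} + 0.5 * #{t = n}) / (n_t * n_n),

computed here from midranks of the pooled values (exact under ties,
O(n log n)).  AUC -> 1 means tumor betas exceed normal betas
(hyper-methylation); AUC -> 0 means the opposite (hypo-methylation); 0.5 is
the null.  Sites with extreme AUC are *differentially methylated sites*
(DMSs).
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .config import RunConfig, DEFAULT_CONFIG
from .io import AUCTrack, BetaMatrix

logger = logging.getLogger("rockermeth")

#: AUC cutoffs for DMS calling, by stringency mode (hypo below, hyper above).
DMS_CUTOFFS = {"lenient": (0.2, 0.8), "stringent": (0.1, 0.9)}


def compute_site_auc(tumor_betas: Sequence[float], normal_betas: Sequence[float]) -> float:
    """ROC AUC for one site; NaN when either group has < 2 non-missing values.

    Ties contribute 1/2 (midrank convention), so the result matches the
    trapezoidal ROC area exactly.
    """
    t = np.asarray(tumor_betas, dtype=float)
    n = np.asarray(normal_betas, dtype=float)
    t = t[np.isfinite(t)]
    n = n[np.isfinite(n)]
    if t.size < 2 or n.size < 2:
        return float("nan")
    pooled = np.concatenate([t, n])
    ranks = rankdata(pooled)
    u = ranks[: t.size].sum() - t.size * (t.size + 1) / 2.0
    return float(u / (t.size * n.size))


def compute_auc_track(
    tumor: BetaMatrix,
    normal: BetaMatrix,
    config: RunConfig = DEFAULT_CONFIG,
) -> AUCTrack:
    """Vectorised per-site AUC over matched tumor/normal beta matrices.

    Both matrices must carry identical site lists.  Sites with fewer than
    two non-missing values in either group get AUC = NaN and are dropped
    from the returned track (with a logged count); the track's
    ``sigma_tot`` is the sample standard deviation (ddof=1) of all retained
    AUC values, pooled across chromosomes.
    """
    if len(tumor.sites) != len(normal.sites) or not (
        tumor.site_key().values == normal.site_key().values
    ).all():
        tk, nk = tumor.site_key(), normal.site_key()
        m = min(len(tk), len(nk))
        diff = np.nonzero((tk.values[:m] != nk.values[:m]).any(axis=1))[0]
        where = (
            f"row {diff[0]}: {tuple(tk.iloc[diff[0]])} vs {tuple(nk.iloc[diff[0]])}"
            if diff.size
            else f"lengths {len(tk)} vs {len(nk)}"
        )
        raise ValueError(f"tumor/normal site lists differ ({where})")
    if normal.n_samples < config.min_normals:
        logger.warning(
            "control group has %d samples (< %d); per-site AUC will be coarse",
            normal.n_samples,
            config.min_normals,
        )

    pooled = np.concatenate([tumor.values, normal.values], axis=1)
    nt_col = tumor.n_samples
    # midranks among non-missing values of each row
    ranks = rankdata(pooled, axis=1, nan_policy="omit")
    t_part = ranks[:, :nt_col]
    n_t = np.isfinite(tumor.values).sum(axis=1)
    n_n = np.isfinite(normal.values).sum(axis=1)
    r_sum = np.nansum(t_part, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        auc = (r_sum - n_t * (n_t + 1) / 2.0) / (n_t * n_n)
    auc = np.where((n_t >= 2) & (n_n >= 2), auc, np.nan)

    keep = np.isfinite(auc)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d sites with <2 non-missing values in a group", n_dropped)
    track = AUCTrack(
        sites=tumor.sites.loc[keep].reset_index(drop=True),
        auc=auc[keep],
        n_tumor=n_t[keep],
        n_normal=n_n[keep],
    )
    track.sigma_tot = float(np.std(track.auc, ddof=1)) if len(track) > 1 else float("nan")
    return track


def call_dms(track: AUCTrack, mode: str = "lenient") -> np.ndarray:
    """Label each site ``hypo`` / ``neutral`` / ``hyper`` by AUC cutoffs.

    Lenient: hypo iff AUC < 0.2, hyper iff AUC > 0.8; stringent: < 0.1 and
    > 0.9.  Boundary values are neutral (strict inequalities).
    """
    if mode not in DMS_CUTOFFS:
        raise ValueError(f"mode must be one of {sorted(DMS_CUTOFFS)}, got {mode!r}")
    lo, hi = DMS_CUTOFFS[mode]
    labels = np.full(len(track), "neutral", dtype=object)
    labels[track.auc < lo] = "hypo"
    labels[track.auc > hi] = "hyper"
    return labels
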