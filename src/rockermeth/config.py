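"""Run-level configuration for the DMR-calling pipeline.

All tunables of the four pipeline stages live in one dataclass so that the
CLI, the library entry points and the test-suite share a single source of
defaults.  Beta values are handled internally in *percentage* units
([0, 100]) because the sample-score dispersion floor (one percentage point)
and the catalog effect-size filter (five percentage points) are defined on
that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional


@dataclass(frozen=True)
class RunConfig:
    """Parameters of the segmentation / filtering / scoring pipeline.

    Attributes
    ----------
    p:
        Homogeneous state-jump probability of the HMM, ``0 < p < 1``.
        Larger values allow shorter segments (higher resolution).
    F:
        Variance-split factor, ``0 < F < 1``.  The neutral state receives
        standard deviation ``F * sigma_tot``; the two differential states
        receive ``(1 - F) * sigma_tot``.
    mu:
        Symmetric offset of the differential state means from the AUC null
        value 0.5, ``0 < mu < 0.5``; state means are ``0.5 - mu``, ``0.5``
        and ``0.5 + mu``.
    d_norm:
        Distance-normalisation constant (bp).  Inter-site distances are
        divided by ``d_norm`` before entering the transition probabilities;
        larger values make state jumps between nearby sites less likely.
    min_sites:
        Minimum number of CpG sites for a segment to be reported as a DMR.
    fdr_alpha:
        Benjamini-Hochberg significance cutoff; segments with
        ``FDR >= fdr_alpha`` are discarded.
    max_distance:
        Optional gap threshold (bp).  When set, segments are split wherever
        two consecutive CpG sites are farther apart than this value (useful
        for sparse array designs).  ``None`` disables splitting.
    hypo_block_len:
        Length threshold (bp) separating short hypo-methylated DMRs from
        large hypo-blocks (the operative proxy for partially methylated
        domains).
    score_threshold:
        Per-sample support threshold on the sample Z-score; a DMR counts as
        supported in a sample when the score strictly exceeds this value
        (gain) or falls strictly below its negative (loss).
    min_normals:
        Control-group size below which a warning is emitted (the per-site
        AUC becomes coarse and noisy with few reference samples).
    mad_estimator:
        Dispersion estimator for the sample-score reference:
        ``"scaled_mad"`` (median absolute deviation x 1.4826,
        normal-consistent), ``"raw_mad"`` (plain MAD) or ``"max_abs_dev"``
        (maximum absolute deviation from the median).
    """

    p: float = 0.05
    F: float = 0.4
    mu: float = 0.25
    d_norm: float = 1e5
    min_sites: int = 6
    fdr_alpha: float = 0.05
    max_distance: Optional[float] = None
    hypo_block_len: float = 10_000.0
    score_threshold: float = 3.0
    min_normals: int = 10
    mad_estimator: str = "scaled_mad"

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must be in (0, 1), got {self.p}")
        if not 0.0 < self.F < 1.0:
            raise ValueError(f"F must be in (0, 1), got {self.F}")
        if not 0.0 < self.mu < 0.5:
            raise ValueError(f"mu must be in (0, 0.5), got {self.mu}")
        if self.d_norm <= 0:
            raise ValueError(f"d_norm must be positive, got {self.d_norm}")
        if self.min_sites < 1:
            raise ValueError(f"min_sites must be >= 1, got {self.min_sites}")
        if not 0.0 < self.fdr_alpha <= 1.0:
            raise ValueError(f"fdr_alpha must be in (0, 1], got {self.fdr_alpha}")
        if self.max_distance is not None and self.max_distance <= 0:
            raise ValueError("max_distance must be positive or None")
        if self.hypo_block_len <= 0:
            raise ValueError("hypo_block_len must be positive")
        if self.mad_estimator not in ("scaled_mad", "raw_mad", "max_abs_dev"):
            raise ValueError(f"unknown mad_estimator {self.mad_estimator!r}")

    def with_(self, **kwargs) -> "RunConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


DEFAULT_CONFIG = RunConfig()
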