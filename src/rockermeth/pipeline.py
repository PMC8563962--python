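"""End-to-end tumor/normal DMR calling: AUC -> HMM -> test -> filter."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from . import auc as auc_mod
from . import dmr as dmr_mod
from . import hmm as hmm_mod
from .config import RunConfig, DEFAULT_CONFIG
from .io import AUCTrack, BetaMatrix


@dataclass
class SegmentationResult:
    """Everything one run produces: the AUC track, the full segment table
    (including neutral segments) and the filtered, classified DMR table."""

    track: AUCTrack
    params: hmm_mod.HMMParams
    segments: pd.DataFrame
    dmrs: pd.DataFrame

    def burden(self) -> dict:
        return dmr_mod.dmr_burden(self.dmrs, self.segments)


def call_dmrs(
    tumor: BetaMatrix,
    normal: BetaMatrix,
    config: RunConfig = DEFAULT_CONFIG,
    track: Optional[AUCTrack] = None,
) -> SegmentationResult:
    """Run the full pipeline on matched tumor/normal beta matrices.

    A precomputed AUC track may be supplied (e.g. loaded from disk); it
    must then be coordinate-compatible with the matrices, which are still
    required for the intra-segment tests and effect sizes.
    """
    if track is None:
        track = auc_mod.compute_auc_track(tumor, normal, config)
    params = hmm_mod.set_params(config, track.sigma_tot)
    states = hmm_mod.viterbi_decode(track, params)
    segments = hmm_mod.states_to_segments(states, track.sites)

    # align beta matrices to the retained track sites for testing
    key = pd.MultiIndex.from_frame(tumor.site_key())
    track_key = pd.MultiIndex.from_frame(track.sites[["chrom", "pos"]])
    locs = key.get_indexer(track_key)
    if (locs < 0).any():
        raise ValueError("AUC track contains sites absent from the beta matrices")
    tumor_sub = BetaMatrix(
        sites=tumor.sites.iloc[locs], samples=tumor.samples, values=tumor.values[locs]
    )
    normal_sub = BetaMatrix(
        sites=normal.sites.iloc[locs], samples=normal.samples, values=normal.values[locs]
    )
    tested = dmr_mod.segment_statistics(segments, tumor_sub, normal_sub, track.auc, config)
    dmrs = dmr_mod.filter_segments(tested, config)
    return SegmentationResult(track=track, params=params, segments=tested, dmrs=dmrs)
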