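"""Site-wise and segment-wise benchmark metrics against simulated truth.

Segment-wise: a predicted DMR is a true positive when it overlaps some
truth DMR of the same direction by *more than* ``overlap_fraction``
(default 30%) of the predicted DMR's length (the denominator is
configurable); recall is the fraction of truth DMRs matched by at least
one true-positive prediction.  Site-wise: a direction-aware confusion
matrix over all simulated sites; specificity is the fraction of
truth-negative sites not claimed by any predicted DMR.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .simulate import SyntheticTruth

#: DMR class label -> direction used for matching.
DIRECTION_OF = {
    "hyper": "gain",
    "hypo": "loss",
    "hypo_block": "loss",
    "gain": "gain",
    "loss": "loss",
}


@dataclass
class EvalReport:
    """Precision/recall/F1 at segment and site resolution, plus specificity."""

    segment_precision: float
    segment_recall: float
    segment_f1: float
    site_precision: float
    site_recall: float
    site_f1: float
    specificity: float
    n_predicted: int
    n_truth: int
    overlap_fraction: float

    def to_dict(self) -> Dict[str, float]:
        return asdict(self)


def _f1(precision: float, recall: float) -> float:
    if not (np.isfinite(precision) and np.isfinite(recall)) or precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _direction(state: str) -> str:
    try:
        return DIRECTION_OF[str(state)]
    except KeyError:
        raise ValueError(f"prediction state {state!r} has no direction") from None


def evaluate_predictions(
    predicted: pd.DataFrame,
    truth: SyntheticTruth,
    overlap_fraction: float = 0.30,
    overlap_denominator: str = "predicted",
) -> EvalReport:
    """Score a predicted DMR table (1-based inclusive) against truth.

    ``overlap_denominator`` chooses the length against which the >30%
    overlap is measured: ``"predicted"`` (default), ``"truth"`` or
    ``"either"`` (the rule passes for either denominator).
    """
    if overlap_denominator not in ("predicted", "truth", "either"):
        raise ValueError(f"bad overlap_denominator {overlap_denominator!r}")
    if len(predicted) and "state" not in predicted.columns:
        raise ValueError("predicted table must carry a 'state' column")

    pred = predicted.reset_index(drop=True)
    pred_dir = [_direction(s) for s in pred["state"]] if len(pred) else []
    truth_dmrs = truth.dmrs.reset_index(drop=True)
    truth_dir = [_direction(s) for s in truth_dmrs["direction"]]

    # ---- segment-wise ----
    tp_flags = np.zeros(len(pred), dtype=bool)
    truth_matched = np.zeros(len(truth_dmrs), dtype=bool)
    for i, p in pred.iterrows():
        p_len = int(p["end"]) - int(p["start"]) + 1
        for j, t in truth_dmrs.iterrows():
            if t["chrom"] != p["chrom"] or truth_dir[j] != pred_dir[i]:
                continue
            ov = min(int(p["end"]), int(t["end"])) - max(int(p["start"]), int(t["start"])) + 1
            if ov <= 0:
                continue
            t_len = int(t["end"]) - int(t["start"]) + 1
            if overlap_denominator == "predicted":
                hit = ov > overlap_fraction * p_len
            elif overlap_denominator == "truth":
                hit = ov > overlap_fraction * t_len
            else:
                hit = ov > overlap_fraction * min(p_len, t_len)
            if hit:
                tp_flags[i] = True
                truth_matched[j] = True
    n_tp = int(tp_flags.sum())
    seg_precision = n_tp / len(pred) if len(pred) else float("nan")
    seg_recall = float(truth_matched.mean()) if len(truth_dmrs) else float("nan")

    # ---- site-wise ----
    pos = truth.sites["pos"].to_numpy()
    chroms = truth.sites["chrom"].to_numpy()
    pred_site = np.full(len(pos), "none", dtype=object)
    for i, p in pred.iterrows():
        inside = (
            (chroms == p["chrom"])
            & (pos >= int(p["start"]))
            & (pos <= int(p["end"]))
        )
        pred_site[inside] = pred_dir[i]
    truth_site = np.array(
        [DIRECTION_OF.get(str(v), "none") for v in truth.site_labels], dtype=object
    )
    tp = int(((truth_site != "none") & (pred_site == truth_site)).sum())
    fn = int(((truth_site != "none") & (pred_site != truth_site)).sum())
    fp = int(((pred_site != "none") & (pred_site != truth_site)).sum())
    neg = truth_site == "none"
    tn = int((neg & (pred_site == "none")).sum())
    site_precision = tp / (tp + fp) if (tp + fp) else float("nan")
    site_recall = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / int(neg.sum()) if neg.any() else float("nan")

    return EvalReport(
        segment_precision=seg_precision,
        segment_recall=seg_recall,
        segment_f1=_f1(seg_precision, seg_recall),
        site_precision=site_precision,
        site_recall=site_recall,
        site_f1=_f1(site_precision, site_recall),
        specificity=specificity,
        n_predicted=int(len(pred)),
        n_truth=int(len(truth_dmrs)),
        overlap_fraction=overlap_fraction,
    )
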