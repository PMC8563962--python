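"""Data containers and delimited-text readers/writers.

The universal input is a *beta matrix*: CpG sites (rows, with genomic
coordinates) by samples (columns) holding methylation fractions.  Values are
stored internally as percentages in [0, 100]; fraction-scale input ([0, 1])
is converted on read.  Coordinates are 1-based inclusive internally; all BED
output is 0-based half-open.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger("rockermeth")

SITE_COLUMNS = ("chrom", "pos")

#: Canonical DMR/segment table columns (1-based inclusive coordinates).
SEGMENT_COLUMNS = (
    "chrom",
    "start",
    "end",
    "state",
    "n_sites",
    "mean_auc",
    "p_value",
    "fdr",
    "mean_beta_diff",
    "length_bp",
)


@dataclass
class BetaMatrix:
    """Methylation beta values (percent) for sites x samples.

    Parameters
    ----------
    sites:
        DataFrame with columns ``chrom`` (str), ``pos`` (int, 1-based) and
        optionally ``site_id``; rows sorted by (chrom, pos), positions
        strictly increasing within a chromosome.
    samples:
        Sample identifiers, one per value column.
    values:
        Array of shape ``(n_sites, n_samples)`` in percentage units; NaN
        marks missing values.
    """

    sites: pd.DataFrame
    samples: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (sites x samples)")
        if self.values.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        for col in SITE_COLUMNS:
            if col not in self.sites.columns:
                raise ValueError(f"sites frame lacks required column {col!r}")
        if (self.sites["pos"] < 1).any():
            raise ValueError("positions must be >= 1 (1-based coordinates)")
        dup = self.sites.duplicated(subset=["chrom", "pos"])
        if dup.any():
            first = self.sites.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate site {first['chrom']}:{first['pos']}"
            )
        # enforce (chrom, pos) sort without reordering silently: sites must
        # arrive sorted per chromosome; chromosomes keep first-seen order.
        pos = self.sites["pos"].to_numpy()
        chrom = self.sites["chrom"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        if np.any(same & (np.diff(pos) <= 0)):
            raise ValueError("sites must be strictly increasing in pos within a chromosome")
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0) | (self.values > 100)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value {self.values[i, j]} outside [0, 100] at "
                f"{self.sites['chrom'].iat[i]}:{self.sites['pos'].iat[i]}, "
                f"sample {self.samples[j]}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_key(self) -> pd.DataFrame:
        return self.sites[["chrom", "pos"]]

    def to_frame(self) -> pd.DataFrame:
        """Sites + values as one flat DataFrame (percent units)."""
        out = self.sites.copy()
        for j, s in enumerate(self.samples):
            out[str(s)] = self.values[:, j]
        return out


@dataclass
class AUCTrack:
    """Genome-ordered per-site ROC-AUC values, the HMM observation sequence."""

    sites: pd.DataFrame
    auc: np.ndarray
    n_tumor: np.ndarray
    n_normal: np.ndarray
    sigma_tot: float = float("nan")

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.auc = np.asarray(self.auc, dtype=float)
        if len(self.auc) != len(self.sites):
            raise ValueError("auc length must match number of sites")
        finite = self.auc[np.isfinite(self.auc)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("AUC values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.auc)


def read_beta_matrix(
    path: Union[str, Path],
    units_hint: Optional[str] = None,
    sep: str = "\t",
) -> BetaMatrix:
    """Read a delimited beta matrix (chrom, pos, [site_id], samples...).

    Values may be on the fraction ([0, 1]) or percentage ([0, 100]) scale;
    when ``units_hint`` is ``None`` the scale is auto-detected (a maximum
    non-missing value <= 1.0 means fractions).  Non-numeric cells become
    missing (NaN) with a logged count; duplicate coordinates raise.
    """
    if units_hint not in (None, "fraction", "percent"):
        raise ValueError("units_hint must be None, 'fraction' or 'percent'")
    df = pd.read_csv(path, sep=sep, dtype={"chrom": str})
    if "chrom" not in df.columns or "pos" not in df.columns:
        raise ValueError(f"{path}: expected 'chrom' and 'pos' columns")
    meta_cols = ["chrom", "pos"] + (["site_id"] if "site_id" in df.columns else [])
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")
    raw = df[sample_cols]
    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    n_coerced = int(np.isnan(values).sum() - raw.isna().to_numpy().sum())
    if n_coerced > 0:
        logger.warning("%s: %d non-numeric cells treated as missing", path, n_coerced)
    sites = df[meta_cols].copy()
    sites["pos"] = sites["pos"].astype(int)
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    values = values[order]

    finite = values[np.isfinite(values)]
    if units_hint == "fraction" or (
        units_hint is None and finite.size and np.nanmax(finite) <= 1.0
    ):
        values = values * 100.0
    return BetaMatrix(sites=sites, samples=[str(c) for c in sample_cols], values=values)


def write_beta_matrix(bm: BetaMatrix, path: Union[str, Path], sep: str = "\t") -> None:
    """Write a beta matrix as TSV in percentage units (round-trip safe)."""
    bm.to_frame().to_csv(path, sep=sep, index=False)


def read_auc_track(path: Union[str, Path], sep: str = "\t") -> AUCTrack:
    """Read a precomputed AUC track TSV (chrom, pos, auc[, n_tumor, n_normal])."""
    df = pd.read_csv(path, sep=sep, dtype={"chrom": str})
    for col in ("chrom", "pos", "auc"):
        if col not in df.columns:
            raise ValueError(f"{path}: expected column {col!r}")
    n_t = df["n_tumor"].to_numpy() if "n_tumor" in df.columns else np.zeros(len(df))
    n_n = df["n_normal"].to_numpy() if "n_normal" in df.columns else np.zeros(len(df))
    auc = df["auc"].to_numpy(dtype=float)
    track = AUCTrack(
        sites=df[["chrom", "pos"]].assign(pos=df["pos"].astype(int)),
        auc=auc,
        n_tumor=n_t,
        n_normal=n_n,
    )
    track.sigma_tot = float(np.nanstd(auc, ddof=1))
    return track


def write_auc_track(track: AUCTrack, path: Union[str, Path], sep: str = "\t") -> None:
    out = track.sites[["chrom", "pos"]].copy()
    out["auc"] = track.auc
    out["n_tumor"] = track.n_tumor
    out["n_normal"] = track.n_normal
    out.to_csv(path, sep=sep, index=False)


def _bed_score(fdr: float) -> int:
    """-10*log10(FDR), capped at 1000 (Phred-like BED score)."""
    if not np.isfinite(fdr) or fdr <= 0:
        return 1000
    return int(min(1000, round(-10.0 * np.log10(fdr))))


def write_dmr_bed(dmrs: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a DMR table as BED6+ (0-based half-open).

    Columns: chrom, start, end, name (state + index), score
    (-10*log10(FDR), capped at 1000), strand ".", then n_sites, mean_auc,
    mean_beta_diff, p_value, fdr.
    """
    rows = []
    for i, (_, d) in enumerate(dmrs.iterrows(), start=1):
        rows.append(
            {
                "chrom": d["chrom"],
                "start": int(d["start"]) - 1,
                "end": int(d["end"]),
                "name": f"{d['state']}_{i}",
                "score": _bed_score(d.get("fdr", np.nan)),
                "strand": ".",
                "n_sites": int(d.get("n_sites", 0)),
                "mean_auc": d.get("mean_auc", np.nan),
                "mean_beta_diff": d.get("mean_beta_diff", np.nan),
                "p_value": d.get("p_value", np.nan),
                "fdr": d.get("fdr", np.nan),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "n_sites", "mean_auc", "mean_beta_diff", "p_value", "fdr",
        ],
    )
    out.to_csv(path, sep="\t", index=False, header=True)


def read_dmr_bed(path: Union[str, Path]) -> pd.DataFrame:
    """Read a BED-like DMR file back into the canonical 1-based table.

    Accepts the BED6+ written by :func:`write_dmr_bed` or any headered
    BED-like file with at least chrom/start/end/name; the state is the name
    column stripped of a trailing ``_<index>``.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("chrom"):
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    else:
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
        base = ["chrom", "start", "end", "name", "score", "strand"]
        df.columns = base[: df.shape[1]] + [
            f"col{j}" for j in range(max(0, df.shape[1] - len(base)))
        ]
    if "name" not in df.columns:
        raise ValueError(f"{path}: BED name column (DMR state/direction) is required")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int) + 1,
            "end": df["end"].astype(int),
            "state": df["name"].astype(str).str.replace(r"_\d+$", "", regex=True),
        }
    )
    for col in ("n_sites", "mean_auc", "mean_beta_diff", "p_value", "fdr"):
        if col in df.columns:
            out[col] = df[col]
    out["length_bp"] = out["end"] - out["start"] + 1
    return out


def write_run_metadata(path: Union[str, Path], **fields) -> None:
    """Dump run parameters/counts/seed as JSON."""
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, default=str)
        fh.write("\n")
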