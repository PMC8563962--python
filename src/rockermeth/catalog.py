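"""Multi-dataset DMR catalog: interval partition, refinement, sharedness.

Per-dataset DMR sets are first partitioned into *atoms* — the maximal
intervals on which dataset membership is constant (the boundary-set
arithmetic of a multi-intersection).  Atoms are then refined per supporting
dataset: enough probes (>= 6), a significant two-sided WMW test on
per-sample median betas after Benjamini-Hochberg correction (FDR < 0.05),
an absolute mean beta difference > 5 percentage points, and at least 3
CpG sites with concordant extreme AUC (< 0.25 for losses, > 0.75 for
gains).  Entries supported by several datasets must show a dominant
(strict-majority) direction; ties are discarded.  The 10 kb hypo /
hypo-block distinction is re-applied on the refined coordinates.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .config import RunConfig, DEFAULT_CONFIG
from .dmr import adjust_fdr, segment_wmw_test
from .io import AUCTrack, BetaMatrix

#: Direction of each DMR class label.
_DIRECTION = {"hyper": "gain", "hypo": "loss", "hypo_block": "loss"}

#: Concordant-site AUC cutoffs per direction.
CONCORDANT_AUC = {"gain": (0.75, "above"), "loss": (0.25, "below")}


def _check_non_overlapping(dmrs: pd.DataFrame, name: str) -> None:
    for chrom, g in dmrs.groupby("chrom", sort=False):
        g = g.sort_values("start")
        if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"dataset {name!r} has overlapping DMRs on {chrom}")


def partition_multi(dmr_sets: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Partition the genome at the union of all DMR boundaries.

    Input tables use the canonical 1-based inclusive coordinates and carry a
    ``state`` column.  Returns one row per atom with chrom/start/end plus a
    ``state_<dataset>`` column per input (label or ``"absent"``); the
    concatenation of atoms covered by a dataset reconstructs its DMRs
    exactly.  Adjacent atoms with identical membership vectors are merged
    back to avoid fragmentation artifacts.
    """
    names = list(dmr_sets)
    for name in names:
        _check_non_overlapping(dmr_sets[name], name)
    chroms: List[str] = []
    for name in names:
        for c in dmr_sets[name]["chrom"]:
            if c not in chroms:
                chroms.append(str(c))
    rows = []
    for chrom in chroms:
        bounds = set()
        per_ds = {}
        for name in names:
            g = dmr_sets[name]
            g = g[g["chrom"] == chrom].sort_values("start")
            per_ds[name] = g
            for s, e in zip(g["start"], g["end"]):
                bounds.add(int(s))
                bounds.add(int(e) + 1)
        cuts = sorted(bounds)
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            start, end = lo, hi - 1
            states = {}
            covered = False
            for name in names:
                g = per_ds[name]
                hit = g[(g["start"] <= start) & (g["end"] >= end)]
                if len(hit):
                    states[f"state_{name}"] = str(hit["state"].iloc[0])
                    covered = True
                else:
                    states[f"state_{name}"] = "absent"
            if covered:
                rows.append({"chrom": chrom, "start": start, "end": end, **states})
    atoms = pd.DataFrame(rows)
    return _merge_adjacent(atoms, [f"state_{n}" for n in names])


def _merge_adjacent(atoms: pd.DataFrame, state_cols: List[str]) -> pd.DataFrame:
    """Merge touching atoms with identical per-dataset state vectors."""
    if len(atoms) == 0:
        return atoms
    merged = []
    for _, row in atoms.iterrows():
        if (
            merged
            and merged[-1]["chrom"] == row["chrom"]
            and merged[-1]["end"] + 1 == row["start"]
            and all(merged[-1][c] == row[c] for c in state_cols)
        ):
            merged[-1]["end"] = int(row["end"])
        else:
            merged.append(dict(row))
    return pd.DataFrame(merged)


def _sites_in(atom_chrom: str, lo: int, hi: int, sites: pd.DataFrame) -> np.ndarray:
    g = sites[sites["chrom"] == atom_chrom]
    return g.index[(g["pos"] >= lo) & (g["pos"] <= hi)].to_numpy()


def refine_catalog(
    atoms: pd.DataFrame,
    data: Mapping[str, Tuple[BetaMatrix, BetaMatrix, AUCTrack]],
    config: RunConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Apply the per-dataset refinement filters and consensus-state rule.

    ``data`` maps each dataset name to its (tumor, normal, AUC track)
    triple.  A dataset *supports* an atom when it covered it in the
    partition and the atom passes all per-dataset predicates there.  The
    consensus state is the strict-majority direction among supporting
    datasets (with the 10 kb hypo/hypo-block split re-applied); atoms with
    no surviving support, or support tied between directions, are dropped.
    """
    state_cols = [c for c in atoms.columns if c.startswith("state_")]
    names = [c[len("state_"):] for c in state_cols]
    missing = [n for n in names if n not in data]
    if missing:
        raise ValueError(f"no beta/AUC data supplied for dataset(s): {missing}")

    # per-dataset tests over the atoms it covers, BH within dataset
    stats: Dict[str, pd.DataFrame] = {}
    for name in names:
        tumor, normal, track = data[name]
        recs = []
        for r, atom in atoms.iterrows():
            if atom[f"state_{name}"] == "absent":
                continue
            lo, hi = int(atom["start"]), int(atom["end"])
            idx = _sites_in(atom["chrom"], lo, hi, tumor.sites)
            t_idx = _sites_in(atom["chrom"], lo, hi, track.sites)
            n_sites = idx.size
            if n_sites:
                t_med = np.nanmedian(tumor.values[idx], axis=0)
                n_med = np.nanmedian(normal.values[idx], axis=0)
                p = segment_wmw_test(t_med, n_med)
                beta_diff = float(np.nanmean(t_med) - np.nanmean(n_med))
            else:
                p, beta_diff = np.nan, np.nan
            auc_vals = track.auc[t_idx] if t_idx.size else np.array([])
            direction = _DIRECTION[atom[f"state_{name}"]]
            cut, side = CONCORDANT_AUC[direction]
            n_conc = int(
                (auc_vals > cut).sum() if side == "above" else (auc_vals < cut).sum()
            )
            recs.append(
                {
                    "atom": r,
                    "n_sites": n_sites,
                    "p_value": p,
                    "mean_beta_diff": beta_diff,
                    "n_concordant": n_conc,
                    "direction": direction,
                }
            )
        df = pd.DataFrame(recs)
        if len(df):
            df["fdr"] = adjust_fdr(df["p_value"])
        stats[name] = df.set_index("atom") if len(df) else df

    rows = []
    for r, atom in atoms.iterrows():
        supporting = {}
        for name in names:
            df = stats[name]
            if len(df) == 0 or r not in df.index:
                continue
            s = df.loc[r]
            ok = (
                s["n_sites"] >= config.min_sites
                and np.isfinite(s["fdr"])
                and s["fdr"] < config.fdr_alpha
                and np.isfinite(s["mean_beta_diff"])
                and abs(s["mean_beta_diff"]) > 5.0
                and s["n_concordant"] >= 3
            )
            if ok:
                supporting[name] = s["direction"]
        if not supporting:
            continue
        dirs = pd.Series(list(supporting.values()))
        counts = dirs.value_counts()
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            continue  # no dominant state across projects
        direction = counts.index[0]
        length = int(atom["end"]) - int(atom["start"]) + 1
        if direction == "gain":
            consensus = "hyper"
        else:
            consensus = "hypo_block" if length > config.hypo_block_len else "hypo"
        row = {
            "chrom": atom["chrom"],
            "start": int(atom["start"]),
            "end": int(atom["end"]),
            "consensus_state": consensus,
            "n_supporting_datasets": int(
                sum(1 for d in supporting.values() if d == direction)
            ),
            "length_bp": length,
        }
        for name in names:
            row[f"state_{name}"] = (
                supporting.get(name, "absent")
                if atom[f"state_{name}"] != "absent"
                else "absent"
            )
        rows.append(row)
    return pd.DataFrame(rows)


def sharedness_profile(catalog: pd.DataFrame, n_datasets: int) -> pd.DataFrame:
    """Cumulative sharing curve: fraction of entries supported by >= k datasets.

    One column per consensus class, rows k = 1..n_datasets; each column is
    monotone non-increasing in k.
    """
    out = {}
    ks = np.arange(1, n_datasets + 1)
    for cls, g in catalog.groupby("consensus_state"):
        supp = g["n_supporting_datasets"].to_numpy()
        out[cls] = [(supp >= k).mean() for k in ks]
    return pd.DataFrame(out, index=pd.Index(ks, name="k"))
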