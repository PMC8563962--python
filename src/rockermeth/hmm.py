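"""Heterogeneous three-state HMM over the AUC track (pipeline step 2).

States are S1 = hypo-methylated, S2 = not differential, S3 =
hyper-methylated.  Emissions are Gaussian densities truncated to [0, 1]
(the support of AUC) with fixed means ``0.5 - mu, 0.5, 0.5 + mu`` and
standard deviations derived from a single variance-split factor F:

    sd(S1) = sd(S3) = (1 - F) * sigma_tot,    sd(S2) = F * sigma_tot,

where sigma_tot is the standard deviation of all observed AUC values.
Transitions depend on the genomic distance d_i between consecutive CpG
sites through f_i = d_i / d_norm:

    off-diagonal = p * (1 - exp(-f_i)) / 2,
    diagonal     = 1 - p * (1 - exp(-f_i)).

Nearby sites are therefore strongly coupled (the jump probability vanishes
as d_i -> 0) while distant sites approach the homogeneous jump probability
p.  All parameters are fixed a priori rather than fitted by EM: the state
means define the methylation states and p sets the resolution.  Decoding is
by the Viterbi algorithm in log space, independently per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import RunConfig, DEFAULT_CONFIG
from .io import AUCTrack

#: State codes used throughout: 1 = hypo, 2 = neutral, 3 = hyper.
STATE_LABELS = {1: "hypo", 2: "neutral", 3: "hyper"}

#: Floor for log-densities, just above log of the smallest double.
LOG_FLOOR = -745.0


@dataclass(frozen=True)
class HMMParams:
    """Fully specified parameters of the three-state model."""

    mu1: float
    mu2: float
    mu3: float
    sd1: float
    sd2: float
    sd3: float
    p: float
    d_norm: float
    pi: Tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    l: float = 0.0
    u: float = 1.0

    def __post_init__(self) -> None:
        if not (self.l <= self.mu1 < self.mu2 < self.mu3 <= self.u):
            raise ValueError("state means must satisfy l <= mu1 < mu2 < mu3 <= u")
        if min(self.sd1, self.sd2, self.sd3) <= 0:
            raise ValueError("state standard deviations must be positive")
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if abs(sum(self.pi) - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1")

    @property
    def means(self) -> np.ndarray:
        return np.array([self.mu1, self.mu2, self.mu3])

    @property
    def sds(self) -> np.ndarray:
        return np.array([self.sd1, self.sd2, self.sd3])


def set_params(config: RunConfig, sigma_tot: float) -> HMMParams:
    """Derive HMM parameters from the run configuration and observed sigma_tot.

    The differential means sit symmetrically around the AUC null value:
    ``mu1 = 0.5 - mu``, ``mu2 = 0.5``, ``mu3 = 0.5 + mu``.  The initial
    distribution is uniform; its influence decays within a few sites.
    """
    if not np.isfinite(sigma_tot) or sigma_tot <= 0:
        raise ValueError(f"sigma_tot must be positive and finite, got {sigma_tot}")
    sd_diff = (1.0 - config.F) * sigma_tot
    sd_neut = config.F * sigma_tot
    if min(sd_diff, sd_neut) <= 0:
        raise ValueError("variance split produced a non-positive sd; check F")
    return HMMParams(
        mu1=0.5 - config.mu,
        mu2=0.5,
        mu3=0.5 + config.mu,
        sd1=sd_diff,
        sd2=sd_neut,
        sd3=sd_diff,
        p=config.p,
        d_norm=config.d_norm,
    )


def emission_logdensity(auc, state: int, params: HMMParams) -> np.ndarray:
    """Log density of the truncated Gaussian emission for one state.

    ``phi((x - mu)/sd) / sd`` renormalised by the probability mass the
    untruncated Gaussian places on [l, u].  Vectorised over ``auc``.
    """
    x = np.asarray(auc, dtype=float)
    if np.any((x < params.l) | (x > params.u)):
        raise ValueError("AUC observations must lie within the truncation bounds")
    if state not in (1, 2, 3):
        raise ValueError(f"state must be 1, 2 or 3, got {state}")
    mu = params.means[state - 1]
    sd = params.sds[state - 1]
    z_mass = norm.cdf((params.u - mu) / sd) - norm.cdf((params.l - mu) / sd)
    out = norm.logpdf(x, loc=mu, scale=sd) - np.log(z_mass)
    return np.maximum(out, LOG_FLOOR)


def transition_matrix(d_i: float, p: float, d_norm: float) -> np.ndarray:
    """Distance-dependent 3x3 transition matrix for one inter-site step."""
    if d_i < 0:
        raise ValueError(f"inter-site distance must be >= 0, got {d_i}")
    jump = p * (1.0 - np.exp(-d_i / d_norm)) / 2.0
    a = np.full((3, 3), jump)
    np.fill_diagonal(a, 1.0 - 2.0 * jump)
    return a


def _chrom_blocks(sites: pd.DataFrame) -> Iterator[Tuple[str, np.ndarray]]:
    """Yield (chrom, index array) per chromosome in first-seen order."""
    chroms = sites["chrom"].to_numpy()
    boundaries = np.nonzero(chroms[1:] != chroms[:-1])[0] + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(chroms)]])
    for s, e in zip(starts, ends):
        yield chroms[s], np.arange(s, e)


def _viterbi_chrom(obs: np.ndarray, dists: np.ndarray, params: HMMParams) -> np.ndarray:
    """Log-space Viterbi over one chromosome; returns states in {1, 2, 3}."""
    n = obs.size
    if n == 0:
        return np.zeros(0, dtype=int)
    log_e = np.stack(
        [emission_logdensity(obs, k, params) for k in (1, 2, 3)], axis=1
    )  # (n, 3)
    with np.errstate(divide="ignore"):
        jump = params.p * (1.0 - np.exp(-dists / params.d_norm)) / 2.0
        log_jump = np.where(jump > 0, np.log(np.maximum(jump, 1e-300)), LOG_FLOOR)
        log_stay = np.log(np.maximum(1.0 - 2.0 * jump, 1e-300))

    delta = np.log(np.asarray(params.pi)) + log_e[0]
    back = np.zeros((n, 3), dtype=np.int8)
    order = np.empty(3, dtype=np.int64)
    for i in range(1, n):
        # best predecessor of k is either k itself (stay) or the best other
        # state (all jumps share one probability), so only the top two
        # predecessor scores matter.
        stay = delta + log_stay[i - 1]
        order = np.argsort(delta)  # ascending; order[2] is the argmax
        m1, m2 = int(order[2]), int(order[1])
        cand = np.empty(3)
        arg = np.empty(3, dtype=np.int8)
        for k in range(3):
            jump_from = m1 if k != m1 else m2
            jump_score = delta[jump_from] + log_jump[i - 1]
            if stay[k] >= jump_score:
                cand[k], arg[k] = stay[k], k
            else:
                cand[k], arg[k] = jump_score, jump_from
        delta = cand + log_e[i]
        back[i] = arg
    states = np.empty(n, dtype=int)
    states[-1] = int(np.argmax(delta))
    for i in range(n - 2, -1, -1):
        states[i] = back[i + 1, states[i + 1]]
    return states + 1


def viterbi_decode(track: AUCTrack, params: HMMParams) -> np.ndarray:
    """Maximum-a-posteriori state path over the AUC track.

    Decoding restarts (with the initial distribution) at every chromosome
    boundary; inter-site distances are taken between consecutive retained
    sites.  Returns an int array in {1, 2, 3}, aligned with ``track.sites``.
    """
    if len(track) == 0:
        return np.zeros(0, dtype=int)
    obs = np.asarray(track.auc, dtype=float)
    if np.any(~np.isfinite(obs)):
        raise ValueError("AUC track contains non-finite observations")
    pos = track.sites["pos"].to_numpy()
    out = np.empty(len(track), dtype=int)
    for _, idx in _chrom_blocks(track.sites):
        d = np.diff(pos[idx]).astype(float)
        out[idx] = _viterbi_chrom(obs[idx], d, params)
    return out


def states_to_segments(states: np.ndarray, sites: pd.DataFrame) -> pd.DataFrame:
    """Run-length encode a per-site state path into genomic segments.

    Segments never cross chromosome boundaries; bounds are the positions of
    the first and last site of each run (1-based inclusive).  Returns a
    DataFrame with chrom, start, end, state code, state label, n_sites and
    the site index range [i0, i1] into ``sites``.
    """
    states = np.asarray(states)
    if len(states) != len(sites):
        raise ValueError("states and sites must have equal length")
    if len(states) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "state_code", "state", "n_sites", "i0", "i1"]
        )
    pos = sites["pos"].to_numpy()
    rows = []
    for chrom, idx in _chrom_blocks(sites):
        s = states[idx]
        breaks = np.nonzero(s[1:] != s[:-1])[0] + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [len(s)]])
        for a, b in zip(starts, ends):
            i0, i1 = idx[a], idx[b - 1]
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[i0]),
                    "end": int(pos[i1]),
                    "state_code": int(s[a]),
                    "state": STATE_LABELS[int(s[a])],
                    "n_sites": int(b - a),
                    "i0": int(i0),
                    "i1": int(i1),
                }
            )
    return pd.DataFrame(rows)


def path_loglikelihood(
    track: AUCTrack, states: np.ndarray, params: HMMParams
) -> float:
    """Joint log-likelihood of a given state path (for testing/diagnostics)."""
    states = np.asarray(states, dtype=int)
    pos = track.sites["pos"].to_numpy()
    total = 0.0
    for _, idx in _chrom_blocks(track.sites):
        s = states[idx]
        obs = track.auc[idx]
        log_e = np.stack(
            [emission_logdensity(obs, k, params) for k in (1, 2, 3)], axis=1
        )
        total += float(np.log(params.pi[s[0] - 1]))
        total += float(log_e[np.arange(len(s)), s - 1].sum())
        d = np.diff(pos[idx]).astype(float)
        jump = params.p * (1.0 - np.exp(-d / params.d_norm)) / 2.0
        stay = 1.0 - 2.0 * jump
        pr = np.where(s[1:] == s[:-1], stay, jump)
        with np.errstate(divide="ignore"):
            total += float(np.sum(np.where(pr > 0, np.log(np.maximum(pr, 1e-300)), LOG_FLOOR)))
    return total


def simulate_track(
    n_sites: int,
    params: HMMParams,
    rng: np.random.Generator,
    spacing_mean: float = 1_000.0,
    chrom: str = "chrSim",
) -> Tuple[AUCTrack, np.ndarray]:
    """Sample (track, hidden states) from the generative model itself.

    Inter-site distances are geometric-like (exponential, floored at 1 bp);
    emissions are truncated-Gaussian draws.  Used for parameter-recovery
    checks of the decoder.
    """
    dists = np.maximum(1, rng.exponential(spacing_mean, size=n_sites - 1)).astype(int)
    pos = np.concatenate([[1], 1 + np.cumsum(dists)])
    states = np.empty(n_sites, dtype=int)
    states[0] = rng.choice([1, 2, 3], p=np.asarray(params.pi))
    for i in range(1, n_sites):
        a = transition_matrix(float(dists[i - 1]), params.p, params.d_norm)
        states[i] = rng.choice([1, 2, 3], p=a[states[i - 1] - 1])
    # truncated normal sampling by inverse CDF
    mus = params.means[states - 1]
    sds = params.sds[states - 1]
    lo = norm.cdf((params.l - mus) / sds)
    hi = norm.cdf((params.u - mus) / sds)
    q = rng.uniform(lo, hi)
    obs = np.clip(mus + sds * norm.ppf(q), params.l, params.u)
    sites = pd.DataFrame({"chrom": chrom, "pos": pos})
    track = AUCTrack(sites=sites, auc=obs, n_tumor=np.zeros(n_sites), n_normal=np.zeros(n_sites))
    track.sigma_tot = float(np.std(obs, ddof=1))
    return track, states
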