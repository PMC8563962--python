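import itertools

import numpy as np
import pandas as pd
import pytest

import rockermeth as rm
from conftest import make_beta


def enumeration_wmw_p(a, b):
    """Exact two-sided rank-sum p by enumerating all C(n+m, n) labelings."""
    from scipy.stats import rankdata

    a, b = list(a), list(b)
    pooled = np.array(a + b, dtype=float)
    ranks = rankdata(pooled)
    n = len(a)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    mean_u = n * len(b) / 2
    stat_obs = abs(u_obs - mean_u)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - mean_u) >= stat_obs - 1e-12:
            count += 1
    return count / total


class TestSegmentWMW:
    def test_identical_vectors_give_p_one(self):
        # ties everywhere force the normal approximation
        a = np.array([10.0, 20.0, 30.0])
        assert rm.segment_wmw_test(a, a) >= 0.99

    def test_exact_p_matches_enumeration(self):
        a, b = [10, 20, 30], [40, 50, 60]
        assert rm.segment_wmw_test(a, b) == pytest.approx(enumeration_wmw_p(a, b))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_vectors_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        m = int(rng.integers(3, 8))
        a = rng.normal(50, 10, n)
        b = rng.normal(55, 10, m)
        assert rm.segment_wmw_test(a, b) == pytest.approx(enumeration_wmw_p(a, b))

    def test_large_shift_is_overwhelming(self, rng):
        a = rng.normal(70, 2, 200)
        b = rng.normal(50, 2, 200)
        assert rm.segment_wmw_test(a, b) < 1e-10

    def test_empty_vector_gives_missing(self):
        assert np.isnan(rm.segment_wmw_test([], [1.0, 2.0]))


class TestAdjustFdr:
    def test_single_p_unchanged(self):
        assert rm.adjust_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        # p*(m/rank) = {.04, .04, .04, .04} after the cummin step
        got = rm.adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert np.allclose(rm.adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_nan_passthrough(self):
        got = rm.adjust_fdr([0.01, np.nan, 0.02])
        assert np.isnan(got[1]) and np.isfinite(got[0])

    def test_monotone_in_p_rank(self, rng):
        p = rng.uniform(0, 1, 50)
        q = rm.adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def seg_row(state_code=3, n_sites=8, start=100, end=900, i0=0, i1=7, chrom="chr1"):
    return pd.Series(
        {"chrom": chrom, "start": start, "end": end, "state_code": state_code,
         "state": {1: "hypo", 2: "neutral", 3: "hyper"}[state_code],
         "n_sites": n_sites, "i0": i0, "i1": i1,
         "mean_auc": 0.8, "p_value": 1e-4, "mean_beta_diff": 20.0}
    )


class TestFilterAndClassify:
    def make_tested(self, rows):
        df = pd.DataFrame(rows)
        df["length_bp"] = df["end"] - df["start"] + 1
        return df

    def test_boundary_semantics(self):
        rows = []
        r = seg_row(); r["fdr"] = 1e-9; r["n_sites"] = 5; rows.append(r)       # too few sites
        r = seg_row(); r["fdr"] = 0.049; r["n_sites"] = 6; rows.append(r)      # kept
        r = seg_row(); r["fdr"] = 0.05; r["n_sites"] = 60; rows.append(r)      # FDR at alpha: dropped
        r = seg_row(state_code=2); r["fdr"] = 1e-9; r["n_sites"] = 60; rows.append(r)  # neutral never a DMR
        out = rm.filter_segments(self.make_tested(rows), rm.RunConfig())
        assert len(out) == 1
        assert out.loc[0, "fdr"] == 0.049 and out.loc[0, "n_sites"] == 6

    def test_filtering_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(50):
            r = seg_row(state_code=int(rng.choice([1, 3])))
            r["fdr"] = float(rng.uniform(0, 0.2))
            r["n_sites"] = int(rng.integers(1, 20))
            rows.append(r)
        tested = self.make_tested(rows)
        base = len(rm.filter_segments(tested, rm.RunConfig()))
        stricter_sites = len(rm.filter_segments(tested, rm.RunConfig(min_sites=10)))
        stricter_fdr = len(rm.filter_segments(tested, rm.RunConfig(fdr_alpha=0.01)))
        assert stricter_sites <= base and stricter_fdr <= base

    @pytest.mark.parametrize(
        "state_code,length,expected",
        [
            (1, 12_000, "hypo_block"),   # loss > 10 kb
            (1, 10_000, "hypo"),         # loss at the boundary stays hypo
            (3, 2_000_000, "hyper"),     # gain of any size
            (3, 500, "hyper"),
        ],
    )
    def test_classification(self, state_code, length, expected):
        assert rm.classify_dmr(state_code, length, rm.RunConfig()) == expected

    def test_neutral_classification_rejected(self):
        with pytest.raises(ValueError):
            rm.classify_dmr(2, 100, rm.RunConfig())


class TestSplitByMaxDistance:
    def sites(self, positions):
        return pd.DataFrame({"chrom": "chr1", "pos": positions})

    def test_no_gap_no_split(self):
        seg = seg_row(n_sites=4, start=1, end=301, i0=0, i1=3)
        out = rm.split_by_max_distance(seg, self.sites([1, 101, 201, 301]), 1e5)
        assert len(out) == 1 and out[0]["n_sites"] == 4

    def test_splits_at_large_gap(self):
        pos = [1, 100, 200_000, 200_100]
        seg = seg_row(n_sites=4, start=1, end=200_100, i0=0, i1=3)
        out = rm.split_by_max_distance(seg, self.sites(pos), 1e5)
        assert len(out) == 2
        assert (out[0]["start"], out[0]["end"], out[0]["n_sites"]) == (1, 100, 2)
        assert (out[1]["start"], out[1]["end"], out[1]["n_sites"]) == (200_000, 200_100, 2)

    def test_sub_segments_partition_sites(self):
        rng = np.random.default_rng(11)
        pos = np.cumsum(rng.integers(1, 60_000, 30))
        seg = seg_row(n_sites=30, start=int(pos[0]), end=int(pos[-1]), i0=0, i1=29)
        out = rm.split_by_max_distance(seg, self.sites(pos), 20_000)
        assert sum(s["n_sites"] for s in out) == 30
        for s in out:  # no retained sub-segment contains an over-threshold gap
            internal = np.diff(pos[s["i0"]: s["i1"] + 1])
            assert (internal <= 20_000).all()

    def test_single_site_unchanged(self):
        seg = seg_row(n_sites=1, start=5, end=5, i0=0, i1=0)
        out = rm.split_by_max_distance(seg, self.sites([5]), 10)
        assert len(out) == 1

    def test_none_disables(self):
        seg = seg_row()
        assert rm.split_by_max_distance(seg, self.sites([1, 1_000_000]), None) == [seg]


class TestBurdenAndPipelineTable:
    def build(self, rng, shift=30.0):
        # 60 sites: neutral flank, hyper core (sites 20-39), neutral flank
        coords = [("chr1", 100 * (i + 1)) for i in range(60)]
        nor = np.clip(rng.normal(50, 3, (60, 12)), 0, 100)
        tum = nor.copy() + rng.normal(0, 1, (60, 12))
        tum[20:40] += shift
        return make_beta(coords, np.clip(tum, 0, 100)), make_beta(coords, nor)

    def test_burden_matches_hand_sum(self):
        segments = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [1, 1001, 5001],
             "end": [1000, 5000, 6000], "state": ["hyper", "neutral", "hypo"]}
        )
        dmrs = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [1, 5001], "end": [1000, 6000],
             "state": ["hyper", "hypo"], "length_bp": [1000, 1000]}
        )
        burden = rm.dmr_burden(dmrs, segments)
        assert burden["gain"] == pytest.approx(1000 / 6000)
        assert burden["loss"] == pytest.approx(1000 / 6000)

    def test_no_dmrs_zero_burden(self):
        segments = pd.DataFrame(
            {"chrom": ["chr1"], "start": [1], "end": [1000], "state": ["neutral"]}
        )
        assert rm.dmr_burden(pd.DataFrame(), segments) == {"gain": 0.0, "loss": 0.0}

    def test_empty_segmentation_is_an_error(self):
        with pytest.raises(ValueError):
            rm.dmr_burden(pd.DataFrame(), pd.DataFrame())

    def test_end_to_end_detects_implanted_hyper_segment(self, rng):
        tum, nor = self.build(rng)
        res = rm.call_dmrs(tum, nor)
        assert len(res.dmrs) == 1
        d = res.dmrs.iloc[0]
        assert d["state"] == "hyper"
        assert d["fdr"] < 0.05
        assert d["mean_beta_diff"] == pytest.approx(30, abs=5)
        assert rm.dmr_burden(res.dmrs, res.segments)["gain"] > 0

    def test_dmrs_from_one_run_never_overlap(self, rng):
        tum, nor, _ = rm.simulate_dataset(
            platform="wgbs", class_label=2, seed=77, n_sites=4000, n_dmrs=25
        )
        dmrs = rm.call_dmrs(tum, nor).dmrs
        for _, g in dmrs.groupby("chrom"):
            g = g.sort_values("start")
            assert (g["start"].to_numpy()[1:] > g["end"].to_numpy()[:-1]).all()

    def test_max_distance_invariant_on_sparse_array_run(self):
        # end-to-end on the array-like layout: with splitting enabled no
        # reported DMR may span an internal gap above the threshold
        tum, nor, truth = rm.simulate_dataset(platform="hm450", class_label=2, seed=3)
        max_d = 5e4
        res = rm.call_dmrs(tum, nor, rm.RunConfig(max_distance=max_d))
        pos = res.track.sites["pos"].to_numpy()
        assert len(res.dmrs) > 0
        for _, d in res.dmrs.iterrows():
            inside = pos[(pos >= d["start"]) & (pos <= d["end"])]
            assert (np.diff(inside) <= max_d).all()

    def test_null_data_yields_almost_no_dmr_genome(self, rng):
        # tumor and normal from the same distribution: called DMR fraction
        # of the segmented genome stays below 1%
        coords = [("chr1", int(p)) for p in np.cumsum(rng.integers(50, 300, 3000))]
        tum = make_beta(coords, np.clip(rng.normal(50, 10, (3000, 15)), 0, 100))
        nor = make_beta(coords, np.clip(rng.normal(50, 10, (3000, 15)), 0, 100))
        res = rm.call_dmrs(tum, nor)
        burden = rm.dmr_burden(res.dmrs, res.segments)
        assert burden["gain"] + burden["loss"] < 0.01
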