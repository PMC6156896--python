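import numpy as np
import pandas as pd
import pytest

from hdscan import homozygosity as hz
from hdscan.io_formats import MISSING

from conftest import wls_oracle


def brute_force_members(pos, anchor_idx, k):
    """Independent nearest-neighbor oracle: sort by (distance, index)."""
    d = np.abs(pos - pos[anchor_idx])
    order = sorted(range(len(pos)), key=lambda i: (d[i], i))
    return sorted(order[:k])


class TestBuildWindows:
    def test_equally_spaced_five_percent(self):
        pos = np.arange(1, 101) * 1000
        ws = hz.build_windows(np.array(["chr1"] * 100, dtype=object), pos, 0.05)
        assert ws.n_windows == 100
        assert all(len(m) == 5 for m in ws.members)

    def test_fraction_one_caps_at_chromosome(self):
        pos = np.arange(1, 21) * 50
        ws = hz.build_windows(np.array(["chr1"] * 20, dtype=object), pos, 1.0)
        assert all(len(m) == 20 for m in ws.members)

    def test_seven_snp_example(self):
        # anchor at position 10, k=3: candidates 3 (d=7) vs 12 (d=2)
        pos = np.array([1, 2, 3, 10, 11, 12, 30])
        ws = hz.build_windows(np.array(["chr1"] * 7, dtype=object), pos, 3 / 7)
        assert ws.k_per_chrom["chr1"] == 3
        anchor10 = list(ws.anchor).index(3)
        assert sorted(ws.members[anchor10].tolist()) == [3, 4, 5]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            pos = np.sort(rng.choice(10_000, size=50, replace=False)) + 1
            ws = hz.build_windows(np.array(["c"] * 50, dtype=object), pos, 0.2)
            k = ws.k_per_chrom["c"]
            for w in range(ws.n_windows):
                want = brute_force_members(pos, ws.anchor[w], k)
                assert ws.members[w].tolist() == want

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            hz.build_windows(np.array(["chr1"], dtype=object), np.array([5]))

    def test_every_snp_anchored(self):
        pos = np.sort(np.random.default_rng(1).choice(1000, 30, replace=False)) + 1
        ws = hz.build_windows(np.array(["chr1"] * 30, dtype=object), pos, 0.1)
        assert sorted(ws.anchor.tolist()) == list(range(30))


class TestIndicator:
    def test_definition(self):
        g = np.array([[0, 1, 2, MISSING]])
        x = hz.homozygosity_indicator(g)
        assert x[0, 0] == 1 and x[0, 1] == 0 and x[0, 2] == 1
        assert np.isnan(x[0, 3])

    def test_fully_homozygous_row(self):
        x = hz.homozygosity_indicator(np.array([[0, 2, 0, 2]]))
        assert (x == 1).all()

    def test_fully_heterozygous_row(self):
        x = hz.homozygosity_indicator(np.array([[1, 1, 1]]))
        assert (x == 0).all()


class TestLocusWeights:
    def test_common_snp_full_weight(self):
        assert hz.locus_weights(np.array([0.30]))[0] == 1.0

    def test_rare_snp_ramp(self):
        assert hz.locus_weights(np.array([0.025]))[0] == pytest.approx(0.5)

    def test_monomorphic_zero(self):
        assert hz.locus_weights(np.array([0.0]))[0] == 0.0

    def test_monotone_in_maf(self):
        maf = np.linspace(0, 0.5, 50)
        v = hz.locus_weights(maf)
        assert (np.diff(v) >= 0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hz.locus_weights(np.array([0.7]))


def _single_window(pos, anchor_pos):
    n = len(pos)
    a = int(np.argmin(np.abs(pos - anchor_pos)))
    return hz.WindowSet(
        anchor=np.array([a]), members=[np.arange(n)],
        chrom=np.array(["chr1"], dtype=object),
        anchor_pos=np.array([pos[a]]), k_per_chrom={"chr1": n},
    )


class TestEstimateIntensity:
    def test_all_homozygous_gives_one(self):
        pos = np.array([0, 50, 100, 150, 200])
        ws = _single_window(pos, 100)
        for degree in (0, 1, 2):
            H = hz.estimate_intensity(np.ones((1, 5)), ws, pos, np.ones(5), degree)
            assert H[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_all_heterozygous_gives_zero(self):
        pos = np.array([0, 50, 100, 150, 200])
        ws = _single_window(pos, 100)
        for degree in (0, 1):
            H = hz.estimate_intensity(np.zeros((1, 5)), ws, pos, np.ones(5), degree)
            assert H[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_five_member_example_matches_oracle(self):
        # u = (-1, -0.5, 0, 0.5, 1), x = (1,1,0,1,1), v = 1, degree 1
        pos = np.array([0, 50, 100, 150, 200])
        x = np.array([[1.0, 1.0, 0.0, 1.0, 1.0]])
        ws = _single_window(pos, 100)
        H = hz.estimate_intensity(x, ws, pos, np.ones(5), degree=1)
        u = (pos - 100) / 100.0
        w = hz.tricube(u)
        want = np.clip(wls_oracle(u, x[0], w, 1), 0, 1)
        assert H[0, 0] == pytest.approx(want, abs=1e-10)

    def test_oracle_equivalence_100_random_windows(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            m = rng.integers(3, 12)
            pos = np.sort(rng.choice(1000, size=m, replace=False))
            anchor = pos[rng.integers(0, m)]
            x = rng.integers(0, 2, size=(1, m)).astype(float)
            v = rng.uniform(0.1, 1.0, size=m)
            ws = _single_window(pos, anchor)
            H = hz.estimate_intensity(x, ws, pos, v, degree=1)
            h = max(np.abs(pos - anchor).max(), 1)
            u = (pos - anchor) / h
            w = hz.tricube(u) * v
            want = np.clip(wls_oracle(u, x[0], w, 1), 0.0, 1.0)
            assert H[0, 0] == pytest.approx(want, abs=1e-10)

    def test_degree0_equals_weighted_mean(self):
        rng = np.random.default_rng(1)
        m = 9
        pos = np.sort(rng.choice(500, m, replace=False))
        x = rng.integers(0, 2, (4, m)).astype(float)
        v = rng.uniform(0, 1, m)
        ws = _single_window(pos, pos[4])
        H = hz.estimate_intensity(x, ws, pos, v, degree=0)
        u = (pos - pos[4]) / max(np.abs(pos - pos[4]).max(), 1)
        w = hz.tricube(u) * v
        want = (x * w).sum(axis=1) / w.sum()
        np.testing.assert_allclose(H[:, 0], np.clip(want, 0, 1), atol=1e-12)

    def test_degree0_monotone_response(self):
        rng = np.random.default_rng(2)
        m = 8
        pos = np.sort(rng.choice(300, m, replace=False))
        v = rng.uniform(0.2, 1.0, m)
        ws = _single_window(pos, pos[3])
        x = rng.integers(0, 2, (1, m)).astype(float)
        base = hz.estimate_intensity(x, ws, pos, v, 0)[0, 0]
        for j in np.flatnonzero(x[0] == 0):
            x2 = x.copy()
            x2[0, j] = 1.0
            assert hz.estimate_intensity(x2, ws, pos, v, 0)[0, 0] >= base

    def test_all_missing_window_is_nan(self):
        pos = np.array([0, 10, 20])
        x = np.full((1, 3), np.nan)
        ws = _single_window(pos, 10)
        H = hz.estimate_intensity(x, ws, pos, np.ones(3), 1)
        assert np.isnan(H[0, 0])

    def test_zero_weights_is_nan(self):
        pos = np.array([0, 10, 20])
        x = np.ones((1, 3))
        ws = _single_window(pos, 10)
        H = hz.estimate_intensity(x, ws, pos, np.zeros(3), 1)
        assert np.isnan(H[0, 0])

    def test_boundedness_property(self, small_dataset):
        _, gm, *_ = small_dataset
        prof = hz.profile_genotypes(gm)
        finite = prof.intensity[np.isfinite(prof.intensity)]
        assert finite.min() >= 0.0 and finite.max() <= 1.0


def runscan_oracle(h, anchors, min_int, min_len):
    """Exhaustive run-scan oracle over a toy profile (independent of impl)."""
    out = []
    i = 0
    n = len(h)
    while i < n:
        if h[i] >= min_int:
            j = i
            while j + 1 < n and h[j + 1] >= min_int:
                j += 1
            if anchors[j] - anchors[i] + 1 >= min_len:
                out.append((anchors[i], anchors[j]))
            i = j + 1
        else:
            i += 1
    return out


def _profile_from_values(values, anchors):
    n = len(anchors)
    ws = hz.WindowSet(
        anchor=np.arange(n), members=[np.array([i]) for i in range(n)],
        chrom=np.array(["chr1"] * n, dtype=object),
        anchor_pos=np.asarray(anchors, dtype=np.int64), k_per_chrom={"chr1": 1},
    )
    return hz.IntensityProfile(
        intensity=np.asarray(values, dtype=float).reshape(1, -1),
        windows=ws, samples=["s1"], maf=np.full(n, 0.3),
    )


class TestExtractHdRegions:
    def test_six_mb_run_kept(self):
        anchors = np.arange(0, 61) * 100_000 + 1_000_000   # spans 6 Mb
        prof = _profile_from_values(np.full(61, 0.95), anchors)
        regions = hz.extract_hd_regions(prof)
        assert len(regions) == 1
        assert regions[0].length >= 5_000_000
        assert regions[0].start == anchors[0] and regions[0].end == anchors[-1]

    def test_three_mb_run_discarded(self):
        anchors = np.arange(0, 31) * 100_000 + 1_000_000   # spans 3 Mb
        prof = _profile_from_values(np.full(31, 0.95), anchors)
        assert hz.extract_hd_regions(prof) == []

    def test_split_runs_match_oracle(self):
        anchors = np.arange(0, 121) * 100_000 + 1
        h = np.full(121, 0.95)
        h[60] = 0.5                                        # splits the run
        prof = _profile_from_values(h, anchors)
        regions = hz.extract_hd_regions(prof)
        want = runscan_oracle(h, anchors, 0.9, 5_000_000)
        assert [(r.start, r.end) for r in regions] == want
        assert len(regions) == 2

    def test_random_profiles_match_oracle(self):
        rng = np.random.default_rng(9)
        for trial in range(20):
            anchors = np.sort(rng.choice(30_000_000, 40, replace=False)) + 1
            h = rng.uniform(0.5, 1.0, 40)
            prof = _profile_from_values(h, anchors)
            regions = hz.extract_hd_regions(prof, 0.9, 2_000_000)
            want = runscan_oracle(h, anchors, 0.9, 2_000_000)
            assert [(r.start, r.end) for r in regions] == want

    def test_nan_breaks_run(self):
        anchors = np.arange(0, 121) * 100_000 + 1
        h = np.full(121, 0.95)
        h[60] = np.nan
        prof = _profile_from_values(h, anchors)
        assert len(hz.extract_hd_regions(prof)) == 2

    def test_planted_roh_recovered(self, default_scale_dataset):
        _, gm, truth, _ = default_scale_dataset
        prof = hz.profile_genotypes(gm)
        regions = hz.extract_hd_regions(prof)
        c, st, en = truth.effect_span
        carriers = {s.sample for s in truth.segments}
        recovered = 0
        sample_rows = {s: i for i, s in enumerate(prof.samples)}
        W = prof.windows
        for carrier in carriers:
            # mean intensity inside the planted segment
            inside = (W.chrom == c) & (W.anchor_pos >= st) & (W.anchor_pos <= en)
            assert np.nanmean(prof.intensity[sample_rows[carrier], inside]) >= 0.9
            best = 0.0
            for r in regions:
                if r.sample == carrier and r.chrom == c:
                    ov = max(0, min(r.end, en) - max(r.start, st) + 1)
                    best = max(best, ov / (en - st + 1))
            if best >= 0.8:
                recovered += 1
        assert recovered / len(carriers) >= 0.8


class TestSummarizeHd:
    def test_odd_count_exact_quantiles(self):
        regions = [hz.HDRegion("s", "c", 1, L * 1_000_000, 0.95)
                   for L in (5, 6, 7, 8, 9)]
        t = hz.summarize_hd(regions).set_index("statistic")
        got = t["region_length_bp"]
        assert got["min"] == 5_000_000 and got["max"] == 9_000_000
        assert got["median"] == 7_000_000
        assert got["q1"] == 6_000_000 and got["q3"] == 8_000_000

    def test_per_sample_total(self):
        regions = [hz.HDRegion("s1", "c", 1, 5_000_000, 0.95),
                   hz.HDRegion("s1", "c", 10_000_001, 17_000_000, 0.92)]
        t = hz.summarize_hd(regions).set_index("statistic")
        assert t.loc["max", "total_length_bp"] == 12_000_000

    def test_matches_sort_based_quantile_oracle(self):
        rng = np.random.default_rng(4)
        lengths = rng.integers(5_000_000, 40_000_000, 1000)
        regions = [hz.HDRegion(f"s{i}", "c", 1, int(L), 0.95)
                   for i, L in enumerate(lengths)]
        t = hz.summarize_hd(regions).set_index("statistic")

        def oracle(vals, q):
            # linear interpolation between order statistics, from scratch
            v = sorted(vals)
            hpos = (len(v) - 1) * q
            lo, frac = int(hpos), hpos - int(hpos)
            return v[lo] if frac == 0 else v[lo] * (1 - frac) + v[lo + 1] * frac

        vals = [r.length for r in regions]
        for name, q in (("min", 0), ("q1", 0.25), ("median", 0.5),
                        ("q3", 0.75), ("max", 1.0)):
            assert t.loc[name, "region_length_bp"] == pytest.approx(oracle(vals, q))

    def test_empty_input(self):
        t = hz.summarize_hd([])
        assert t.empty
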