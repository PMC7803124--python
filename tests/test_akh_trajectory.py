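"""Pair-series construction, slope inference, permutation/bootstrap checks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rumenakp import akh_trajectory as akh
from rumenakp import beta_diversity as bd
from rumenakp import synthetic_data as sd


def linear_series(times, slope=0.001, intercept=0.2, pairs=("A|B", "A|C"),
                  noise=None, rng=None, category="treatment-treatment"):
    rows = []
    for pid in pairs:
        va, vb = pid.split("|")
        for t in times:
            y = intercept + slope * t
            if noise is not None:
                y += rng.normal(0, noise)
            rows.append(dict(vessel_a=va, vessel_b=vb, time_a=float(t),
                             time_b=float(t), time_h=float(t),
                             dissimilarity=y))
    return akh.PairSeries(category, pd.DataFrame(rows))


@pytest.fixture(scope="module")
def small_experiment():
    cfg = sd.SyntheticConfig(seed=12, depth=400, n_genera=30)
    table, tax, meta = sd.generate_communities(cfg)
    dm = bd.pairwise_distances(table, "bray_curtis", tax, "genus")
    return table, tax, meta, dm


class TestBuildPairSeries:
    def test_between_vessel_point_counts(self, small_experiment):
        """3 treatment vessels x 12 shared timepoints -> C(3,2)*12 points."""
        table, tax, meta, dm = small_experiment
        tt = akh.build_pair_series(table, tax, meta,
                                   pair_category="treatment-treatment", dm=dm)
        assert len(tt.points) == 3 * 12
        tc = akh.build_pair_series(table, tax, meta,
                                   pair_category="treatment-control", dm=dm)
        assert len(tc.points) == 9 * 12

    def test_within_vessel_point_counts(self, small_experiment):
        """12 timepoints -> C(12,2) = 66 points per vessel, 6 vessels."""
        table, tax, meta, dm = small_experiment
        wv = akh.build_pair_series(table, tax, meta,
                                   pair_category="within-vessel", dm=dm)
        assert len(wv.points) == 6 * 66
        assert (wv.points["vessel_a"] == wv.points["vessel_b"]).all()
        assert np.allclose(wv.points["time_h"],
                           np.abs(wv.points["time_a"] - wv.points["time_b"]))

    def test_identical_replicate_vessels_zero_dissimilarity(self):
        """Vessels with identical counts at each time give an all-zero TT
        series, zero slope and p = 1."""
        from rumenakp.community_data import CommunityTable, SampleMetadata

        rng = np.random.default_rng(3)
        times = [(1, 4), (1, 12), (1, 24), (2, 4), (2, 12)]
        rows, meta_rows, sids = [], [], []
        per_time = {t: rng.integers(1, 50, size=6) for t in times}
        for vessel in ("T1", "T2", "T3"):
            for day, hpf in times:
                sid = f"{vessel}_d{day}h{hpf}"
                sids.append(sid)
                rows.append(per_time[(day, hpf)])
                meta_rows.append(dict(sample_id=sid, vessel=vessel,
                                      condition="treatment", day=day,
                                      hours_post_feeding=hpf,
                                      time_h=24.0 * (day - 1) + hpf))
        table = CommunityTable(sids, [f"o{j}" for j in range(6)],
                               np.array(rows))
        meta = SampleMetadata(pd.DataFrame(meta_rows))
        tt = akh.build_pair_series(table, None, meta,
                                   pair_category="treatment-treatment")
        assert np.allclose(tt.y, 0.0, atol=1e-12)
        assert akh.fit_slope(tt)[0] == pytest.approx(0.0, abs=1e-12)
        assert akh.permutation_slope_test(tt, n_perm=99, seed=0) == \
            pytest.approx(1.0)

    def test_no_qualifying_pairs_rejected(self, small_experiment):
        table, tax, meta, dm = small_experiment
        control_only = meta.frame[meta.frame["condition"] == "control"]
        from rumenakp.community_data import SampleMetadata

        sub_meta = SampleMetadata(control_only)
        sub = table.select_samples(list(control_only["sample_id"]))
        with pytest.raises(ValueError):
            akh.build_pair_series(sub, tax, sub_meta,
                                  pair_category="treatment-treatment")


class TestFitSlope:
    def test_exact_line(self):
        s = linear_series([4, 24, 48, 96], slope=0.001, intercept=0.2)
        slope, intercept = akh.fit_slope(s)
        assert slope == pytest.approx(0.001, abs=1e-12)
        assert intercept == pytest.approx(0.2, abs=1e-12)

    def test_constant_series_zero_slope(self):
        s = linear_series([4, 24, 48], slope=0.0, intercept=0.37)
        assert akh.fit_slope(s)[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        s = linear_series([4, 12, 24, 48, 72], slope=0.002, noise=0.05,
                          rng=rng)
        x, y = s.x, s.y
        xm = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(xm.T @ xm, xm.T @ y)
        slope, intercept = akh.fit_slope(s)
        assert slope == pytest.approx(beta[1], abs=1e-12)
        assert intercept == pytest.approx(beta[0], abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        s = linear_series([10, 10, 10])
        with pytest.raises(ValueError):
            akh.fit_slope(s)


class TestPermutationSlopeTest:
    def test_strong_trend_minimum_p(self):
        rng = np.random.default_rng(1)
        s = linear_series(np.arange(4, 100, 8), slope=0.01, noise=1e-6,
                          rng=rng)
        assert akh.permutation_slope_test(s, n_perm=999, seed=0) == \
            pytest.approx(1 / 1000)

    def test_exhaustive_matches_enumeration_between(self):
        """Tiny between-vessel series: enumeration over time permutations."""
        rng = np.random.default_rng(4)
        s = linear_series([4, 12, 24, 48], slope=0.003, noise=0.05, rng=rng)
        p_impl = akh.permutation_slope_test(s, n_perm="all")
        # oracle: every permutation of the 4 distinct times, slope by polyfit
        times = np.unique(s.x)
        obs = abs(np.polyfit(s.x, s.y, 1)[0])
        hits = total = 0
        for perm in itertools.permutations(range(len(times))):
            mapping = dict(zip(times, times[list(perm)]))
            xs = np.array([mapping[t] for t in s.x])
            total += 1
            if abs(np.polyfit(xs, s.y, 1)[0]) >= obs - 1e-12:
                hits += 1
        assert p_impl == pytest.approx(hits / total, abs=1e-9)

    def test_exhaustive_matches_enumeration_within(self):
        """Tiny within-vessel series: per-vessel time relabelings, lags
        recomputed."""
        rng = np.random.default_rng(5)
        rows = []
        for vessel, times in (("V1", [0.0, 8.0, 24.0]),
                              ("V2", [0.0, 8.0, 24.0])):
            for ta, tb in itertools.combinations(times, 2):
                rows.append(dict(vessel_a=vessel, vessel_b=vessel,
                                 time_a=ta, time_b=tb, time_h=abs(tb - ta),
                                 dissimilarity=0.3 + 0.002 * abs(tb - ta)
                                 + rng.normal(0, 0.03)))
        s = akh.PairSeries("within-vessel", pd.DataFrame(rows))
        p_impl = akh.permutation_slope_test(s, n_perm="all")
        # oracle: product of per-vessel permutations of {0,8,24}
        df = s.points
        obs = abs(np.polyfit(s.x, s.y, 1)[0])
        times = [0.0, 8.0, 24.0]
        hits = total = 0
        for pa in itertools.permutations(times):
            for pb in itertools.permutations(times):
                maps = {"V1": dict(zip(times, pa)), "V2": dict(zip(times, pb))}
                xs = np.array([abs(maps[v][ta] - maps[v][tb])
                               for v, ta, tb in zip(df.vessel_a, df.time_a,
                                                    df.time_b)])
                if np.ptp(xs) == 0:
                    continue
                total += 1
                if abs(np.polyfit(xs, s.y, 1)[0]) >= obs - 1e-12:
                    hits += 1
        assert p_impl == pytest.approx(hits / total, abs=1e-9)

    def test_point_order_invariance(self):
        rng = np.random.default_rng(6)
        s = linear_series([4, 12, 24, 48, 72], slope=0.002, noise=0.05,
                          rng=rng)
        shuffled = akh.PairSeries(
            s.pair_category,
            s.points.sample(frac=1.0, random_state=3).reset_index(drop=True))
        p1 = akh.permutation_slope_test(s, n_perm="all")
        p2 = akh.permutation_slope_test(shuffled, n_perm="all")
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestBootstrapSlopeCI:
    def test_zero_noise_degenerate_ci(self):
        s = linear_series([4, 24, 48, 96], slope=0.001)
        lo, hi = akh.bootstrap_slope_ci(s, n_boot=200, seed=0)
        assert lo == pytest.approx(0.001, abs=1e-12)
        assert hi == pytest.approx(0.001, abs=1e-12)

    def test_single_pair_rejected(self):
        s = linear_series([4, 24, 48], pairs=("A|B",))
        with pytest.raises(ValueError):
            akh.bootstrap_slope_ci(s, n_boot=10)

    def test_coverage_of_true_slope(self):
        """Cluster bootstrap CI covers the generating slope at ~95%.

        Series have a random intercept per cluster plus iid noise; with 40
        clusters the percentile interval's coverage sits within the binomial
        95% band around 0.95.
        """
        beta = 0.002
        n_rep, covered = 300, 0
        for r in range(n_rep):
            rng = np.random.default_rng(1000 + r)
            rows = []
            for c in range(40):
                u = rng.normal(0, 0.05)
                for t in np.linspace(4, 96, 6):
                    rows.append(dict(vessel_a=f"V{c}", vessel_b=f"W{c}",
                                     time_a=t, time_b=t, time_h=t,
                                     dissimilarity=0.3 + u + beta * t
                                     + rng.normal(0, 0.03)))
            s = akh.PairSeries("treatment-treatment", pd.DataFrame(rows))
            lo, hi = akh.bootstrap_slope_ci(s, n_boot=999, seed=rng)
            covered += lo <= beta <= hi
        assert 0.925 <= covered / n_rep <= 0.975

    def test_wider_noise_wider_ci(self):
        widths = []
        for noise in (0.01, 0.05, 0.25):
            los, his = [], []
            for r in range(20):
                rng = np.random.default_rng(100 * r + 1)
                s = linear_series(np.arange(4, 100, 8), slope=0.002,
                                  noise=noise, rng=rng,
                                  pairs=("A|B", "A|C", "B|C"))
                lo, hi = akh.bootstrap_slope_ci(s, n_boot=300, seed=rng)
                los.append(lo)
                his.append(hi)
            widths.append(np.mean(np.array(his) - np.array(los)))
        assert widths[0] < widths[1] < widths[2]


class TestMultiRankAkh:
    def test_full_grid_and_determinism(self, small_experiment):
        table, tax, meta, _ = small_experiment
        kwargs = dict(metric="bray_curtis", ranks=("genus", "phylum"),
                      n_perm=49, n_boot=49, seed=7)
        out1 = akh.multi_rank_akh(table, tax, meta, **kwargs)
        out2 = akh.multi_rank_akh(table, tax, meta, **kwargs)
        assert len(out1) == 2 * len(akh.PAIR_CATEGORIES)
        for a, b in zip(out1, out2):
            assert (a.slope, a.p_value, a.ci95) == (b.slope, b.p_value, b.ci95)
        df = akh.slope_table(out1)
        assert set(df["rank"]) == {"genus", "phylum"}
        assert (df["ci_lo"] <= df["slope"]).all()
        assert (df["slope"] <= df["ci_hi"]).all()
        assert (df["p_value"] >= 1 / 50).all()


class TestDispersionPeak:
    def test_monotone_series_peaks_at_end(self):
        s = linear_series(np.arange(4, 100, 8), slope=0.002)
        assert akh.dispersion_peak_estimate(s) == 92.0

    def test_constant_series_ties_to_earliest(self):
        s = linear_series(np.arange(4, 100, 8), slope=0.0)
        assert akh.dispersion_peak_estimate(s) == 4.0

    def test_too_few_times_rejected(self):
        s = linear_series([4, 24, 48])
        with pytest.raises(ValueError):
            akh.dispersion_peak_estimate(s)
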