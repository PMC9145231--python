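"""Permutation inference: cluster tests, FDR, sliding window, robust
correlation, correlation contrasts and median splits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tntfusion import stats


class TestClusterPermutation:
    def test_null_level_paired(self):
        # exchangeable null: false-positive rate compatible with alpha=0.05
        rng = np.random.default_rng(0)
        hits = 0
        n_sim = 120
        for s in range(n_sim):
            d = rng.standard_normal((10, 4, 12))
            res = stats.cluster_permutation_test(
                d, None, unit="participant", n_perm=200, seed=s)
            hits += res.min_p() < 0.05
        assert hits / n_sim < 0.12  # generous binomial bound at n=120

    def test_enumeration_oracle_small_n(self):
        # single-bin map, 5 paired units: Monte-Carlo p must match the
        # exhaustive 2^5 sign-flip p within +-0.02
        rng = np.random.default_rng(1)
        d = rng.standard_normal((5, 1)) + 1.2
        res = stats.cluster_permutation_test(
            d, None, unit="participant", n_perm=5000, seed=2)

        def tstat(x):
            return x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))

        t_obs = abs(tstat(d[:, 0]))
        count = 0
        for bits in range(32):
            signs = np.array([1 if bits >> k & 1 else -1 for k in range(5)])
            count += abs(tstat(signs * d[:, 0])) >= t_obs - 1e-12
        p_exact = count / 32
        assert res.clusters, "observed effect should form a cluster"
        assert abs(res.clusters[0].p_value - p_exact) <= 0.02

    def test_injected_tf_effect_found(self):
        rng = np.random.default_rng(3)
        d = rng.standard_normal((14, 8, 20))
        d[:, 2:5, 5:12] += 1.2
        res = stats.cluster_permutation_test(
            d, None, unit="participant", n_perm=500, seed=4)
        assert res.significant
        fi, ti = np.unravel_index(res.significant[0].bins, (8, 20))
        assert ((fi >= 2) & (fi <= 4) & (ti >= 5) & (ti <= 11)).any()

    def test_trial_level_labels_exchange(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((40, 6)) + 1.0
        b = rng.standard_normal((40, 6))
        res = stats.cluster_permutation_test(
            a, b, unit="trial", n_perm=500, seed=6)
        assert res.min_p() < 0.05

    def test_max_statistic_mode_single_bins(self):
        rng = np.random.default_rng(7)
        d = rng.standard_normal((12, 10))
        d[:, 3] += 2.0
        res = stats.cluster_permutation_test(
            d, None, unit="participant", mode="max_statistic",
            n_perm=500, seed=8)
        sig_bins = [c.bins[0] for c in res.significant]
        assert 3 in sig_bins
        assert all(len(c.bins) == 1 for c in res.clusters)

    def test_determinism_given_seed(self):
        rng = np.random.default_rng(9)
        d = rng.standard_normal((8, 5, 5))
        r1 = stats.cluster_permutation_test(d, None, n_perm=200, seed=42)
        r2 = stats.cluster_permutation_test(d, None, n_perm=200, seed=42)
        assert [c.p_value for c in r1.clusters] == [c.p_value
                                                   for c in r2.clusters]

    def test_refuses_too_few_permutations(self):
        with pytest.raises(ValueError):
            stats.cluster_permutation_test(np.ones((5, 3)), None, n_perm=50)

    def test_refuses_no_variance(self):
        with pytest.raises(ValueError):
            stats.cluster_permutation_test(np.ones((5, 3)), None, n_perm=200)

    def test_channel_adjacency_merges_clusters(self):
        # two channels adjacent: one supra-threshold blob spanning both must
        # form a single cluster
        rng = np.random.default_rng(10)
        d = 0.1 * rng.standard_normal((12, 2, 10))
        d[:, :, 4:7] += 2.5
        adj = np.array([[0, 1], [1, 0]])
        res = stats.cluster_permutation_test(
            d, None, adjacency=adj, n_perm=200, seed=11)
        biggest = max(res.clusters, key=lambda c: len(c.bins))
        assert len(biggest.bins) == 6  # 2 channels x 3 bins


class TestFDR:
    def test_stepup_oracle(self):
        mask = stats.fdr_bh(np.array([0.01, 0.02, 0.5]), q=0.05)
        assert mask.tolist() == [True, True, False]

    def test_all_ones_rejects_none(self):
        assert not stats.fdr_bh(np.ones(7)).any()

    def test_single_p_reduces_to_raw_threshold(self):
        assert stats.fdr_bh(np.array([0.04]), q=0.05).all()
        assert not stats.fdr_bh(np.array([0.06]), q=0.05).any()

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_matches_closed_form_stepup(self, ps):
        p = np.array(ps)
        mask = stats.fdr_bh(p, q=0.05)
        # independent closed-form step-up
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        ranked = p[order]
        below = ranked <= 0.05 * (np.arange(1, m + 1) / m)
        expected = np.zeros(m, dtype=bool)
        if below.any():
            k = np.max(np.flatnonzero(below))
            expected[order[: k + 1]] = True
        assert mask.tolist() == expected.tolist()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stats.fdr_bh(np.array([]))


class TestSlidingWindow:
    freqs = np.arange(2.0, 9.0)
    times = np.arange(25.0, 2700.0, 50.0)

    def test_null_mostly_empty(self):
        rng = np.random.default_rng(12)
        empty = 0
        n_sim = 30
        for s in range(n_sim):
            d = rng.standard_normal((10, self.freqs.size, self.times.size))
            res = stats.sliding_window_cluster(
                d, None, self.times, self.freqs, n_perm=200, seed=s)
            empty += not res.significant
        assert empty / n_sim >= 0.8

    def test_sustained_effect_unified(self):
        rng = np.random.default_rng(13)
        d = rng.standard_normal((12, self.freqs.size, self.times.size))
        sel = (self.times >= 600) & (self.times <= 2200)
        d[:, 2:5, sel] += 1.0
        res = stats.sliding_window_cluster(
            d, None, self.times, self.freqs, n_perm=300, seed=14)
        assert res.significant
        bins = np.concatenate([c.bins for c in res.significant])
        fi, ti = np.unravel_index(bins, (self.freqs.size, self.times.size))
        inj = (fi >= 2) & (fi <= 4) & sel[ti]
        n_injected = 3 * sel.sum()
        assert inj.sum() >= 0.5 * n_injected

    def test_single_window_effect_reduces_to_window_test(self):
        rng = np.random.default_rng(15)
        d = 0.3 * rng.standard_normal((12, self.freqs.size, self.times.size))
        sel = (self.times >= 500) & (self.times < 800)
        d[:, 3, sel] += 2.0
        res = stats.sliding_window_cluster(
            d, None, self.times, self.freqs, n_perm=300, seed=16)
        assert res.significant
        bins = np.concatenate([c.bins for c in res.significant])
        fi, ti = np.unravel_index(bins, (self.freqs.size, self.times.size))
        assert (fi == 3).mean() >= 0.8  # dominated by the injected frequency


class TestRobustPearson:
    def test_collinear(self):
        x = np.arange(10.0)
        out = stats.robust_pearson(x, 2 * x + 1)
        assert out["rho"] == pytest.approx(1.0)

    def test_outlier_removed(self):
        x = np.arange(20.0)
        y = 3 * x.copy()
        y[-1] = -200.0
        plain = np.corrcoef(x, y)[0, 1]
        out = stats.robust_pearson(x, y)
        assert 19 not in out["kept"]
        assert out["rho"] > 0.99 > plain + 0.2

    def test_independent_null(self):
        rng = np.random.default_rng(17)
        out = stats.robust_pearson(rng.standard_normal(1000),
                                   rng.standard_normal(1000))
        assert abs(out["rho"]) < 0.1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            stats.robust_pearson(np.arange(3.0), np.arange(3.0))


class TestCorrelationContrast:
    def test_identical_conditions_null(self):
        rng = np.random.default_rng(18)
        bold = rng.standard_normal(12)
        tf = rng.standard_normal((12, 20))
        res = stats.correlation_condition_contrast(
            bold, bold, tf, tf, n_perm=300, seed=19)
        assert not res.significant

    def test_coupling_in_one_condition_detected(self):
        rng = np.random.default_rng(20)
        n = 24
        bold_a = rng.standard_normal(n)
        bold_b = rng.standard_normal(n)
        tf_a = 0.5 * rng.standard_normal((n, 30))
        tf_b = 0.5 * rng.standard_normal((n, 30))
        tf_a[:, 8:18] += 1.0 * bold_a[:, None]
        res = stats.correlation_condition_contrast(
            bold_a, bold_b, tf_a, tf_b, n_perm=400, seed=21)
        assert res.significant
        bins = res.significant[0].bins
        assert ((bins >= 8) & (bins < 18)).any()

    def test_symmetric_coupling_null(self):
        rng = np.random.default_rng(22)
        n = 20
        bold_a = rng.standard_normal(n)
        bold_b = rng.standard_normal(n)
        tf_a = rng.standard_normal((n, 15)) + 0.8 * bold_a[:, None]
        tf_b = rng.standard_normal((n, 15)) + 0.8 * bold_b[:, None]
        res = stats.correlation_condition_contrast(
            bold_a, bold_b, tf_a, tf_b, n_perm=300, seed=23)
        assert not res.significant

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            stats.correlation_condition_contrast(
                np.ones(4), np.ones(4), np.ones((4, 3)), np.ones((4, 3)))


class TestMedianSplit:
    def test_one_to_ten(self):
        low, high = stats.median_split(np.arange(1.0, 11.0))
        assert low.tolist() == [0, 1, 2, 3, 4]
        assert high.tolist() == [5, 6, 7, 8, 9]

    def test_odd_count_median_goes_low(self):
        low, high = stats.median_split(np.array([1.0, 2.0, 3.0]))
        assert 1 in low and len(low) == 2 and len(high) == 1

    def test_nan_omitted(self):
        low, high = stats.median_split(np.array([1.0, np.nan, 2.0, 3.0]))
        assert 1 not in low and 1 not in high

    def test_bimodal_recovers_groups(self):
        rng = np.random.default_rng(24)
        truth = rng.random(200) < 0.5
        vals = np.where(truth, 5.0, 0.0) + 0.5 * rng.standard_normal(200)
        low, high = stats.median_split(vals)
        pred = np.zeros(200, dtype=bool)
        pred[high] = True
        assert (pred == truth).mean() >= 0.9

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            stats.median_split(np.full(6, 2.0))

    @given(st.integers(0, 2**31 - 1), st.integers(3, 30))
    @settings(max_examples=25, deadline=None)
    def test_partition_properties(self, seed, n):
        vals = np.random.default_rng(seed).standard_normal(n)
        low, high = stats.median_split(vals)
        assert len(low) + len(high) == n
        assert set(low).isdisjoint(high)
        if len(high):
            assert vals[low].max() <= vals[high].min()
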