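"""Distribution comparison statistics: smoothing, KS, FDR, effect sizes,
the meaningful-difference rule, Lilliefors, and moment skewness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcdomains.compare import (
    compare_distributions,
    fdr_adjust,
    hedges_g,
    ks_two_sample,
    lilliefors_normality,
    nonoverlap_pct,
    skewness,
    smooth_distribution,
)


def brute_force_ks(x, y):
    """sup |ECDF_x - ECDF_y| by direct evaluation at every pooled point."""
    pts = np.concatenate([x, y])
    d = 0.0
    for t in pts:
        fx = np.mean(np.asarray(x) <= t)
        fy = np.mean(np.asarray(y) <= t)
        d = max(d, abs(fx - fy))
    return d


def brute_force_bh(pvals):
    """Adjusted p_i = smallest level alpha at which the BH step-up
    procedure (run literally) rejects hypothesis i."""
    p = np.asarray(pvals, dtype=float)
    n = p.size

    def rejected_at(alpha):
        order = np.sort(p)
        ks = [k for k in range(1, n + 1) if order[k - 1] <= k * alpha / n + 1e-12]
        if not ks:
            return np.zeros(n, dtype=bool)
        return p <= order[max(ks) - 1]

    candidates = sorted({min(1.0, pi * n / k) for pi in p for k in range(1, n + 1)})
    adj = np.ones(n)
    for alpha in candidates:
        rej = rejected_at(alpha)
        adj[rej] = np.minimum(adj[rej], alpha)
    return adj


class TestSmoothing:
    def test_thousand_values_groups_of_one(self, rng):
        vals = rng.random(1000)
        h = smooth_distribution(vals, transform="identity", value_range=(0, 1))
        np.testing.assert_allclose(h.group_means, np.sort(vals))

    def test_two_thousand_values_pairs_of_sorted(self, rng):
        vals = rng.random(2000)
        h = smooth_distribution(vals, transform="identity", value_range=(0, 1))
        expected = np.sort(vals).reshape(1000, 2).mean(axis=1)
        np.testing.assert_allclose(h.group_means, expected)

    def test_uneven_groups_larger_first(self):
        h = smooth_distribution(
            np.arange(7, dtype=float), transform="identity",
            n_groups=3, value_range=(0, 7),
        )
        # sizes 3,2,2 over sorted values
        np.testing.assert_allclose(h.group_means, [1.0, 3.5, 5.5])

    def test_freq_sums_to_one(self, rng):
        h = smooth_distribution(rng.lognormal(9, 1, 5000), transform="log")
        assert h.freq.sum() == pytest.approx(1.0, abs=1e-12)
        assert len(h.freq) == 38
        assert len(h.bin_edges) == 39

    def test_out_of_range_clipped_into_end_bins(self):
        h = smooth_distribution(
            [0.1, 100.0], transform="identity", n_groups=2, value_range=(1.0, 2.0)
        )
        assert h.freq[0] == pytest.approx(0.5)
        assert h.freq[-1] == pytest.approx(0.5)

    def test_group_means_nondecreasing(self, rng):
        h = smooth_distribution(rng.random(3137), transform="identity",
                                value_range=(0, 1))
        assert np.all(np.diff(h.group_means) >= 0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            smooth_distribution([], transform="identity", value_range=(0, 1))


class TestKs:
    def test_identical_samples_zero(self):
        D, _ = ks_two_sample([1, 2, 3], [3, 2, 1])
        assert D == 0.0

    def test_disjoint_supports_one(self):
        D, p = ks_two_sample([1, 2], [10, 20])
        assert D == 1.0
        assert p < 0.5

    def test_hand_example(self):
        D, _ = ks_two_sample([1, 2, 3, 4], [1.5, 2.5, 3.5, 4.5])
        assert D == pytest.approx(0.25)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    @given(
        st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=12),
        st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=12),
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_brute_force_ecdf(self, x, y):
        D, _ = ks_two_sample(x, y)
        assert D == pytest.approx(brute_force_ks(x, y), abs=1e-12)


class TestFdr:
    def test_hand_example(self):
        adj = fdr_adjust([0.01, 0.02, 0.04, 0.5])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.0533333, 0.5], atol=1e-6)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.3])[0] == pytest.approx(0.3)

    def test_ties_monotone(self):
        np.testing.assert_allclose(fdr_adjust([0.03, 0.03, 0.03]), [0.03] * 3)

    def test_adjusted_at_least_raw_capped_at_one(self, rng):
        p = rng.random(20)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8))
    @settings(max_examples=80, deadline=None)
    def test_matches_brute_force_threshold_scan(self, p):
        np.testing.assert_allclose(fdr_adjust(p), brute_force_bh(p), atol=1e-9)


class TestEffectSizes:
    def _hist(self, freq):
        from gcdomains.compare import SmoothedHistogram

        freq = np.asarray(freq, dtype=float)
        edges = np.linspace(0, 1, freq.size + 1)
        return SmoothedHistogram(n_raw=100, group_means=np.array([]),
                                 bin_edges=edges, freq=freq)

    def test_identical_histograms_zero(self):
        h = self._hist([0.25, 0.5, 0.25])
        assert nonoverlap_pct(h, h) == 0.0

    def test_disjoint_histograms_full(self):
        assert nonoverlap_pct(self._hist([1, 0, 0]), self._hist([0, 0, 1])) == 100.0

    def test_half_overlap(self):
        a, b = self._hist([0.5, 0.5, 0]), self._hist([0, 0.5, 0.5])
        assert nonoverlap_pct(a, b) == pytest.approx(50.0)

    def test_symmetric(self, rng):
        f1, f2 = rng.random(5), rng.random(5)
        a, b = self._hist(f1 / f1.sum()), self._hist(f2 / f2.sum())
        assert nonoverlap_pct(a, b) == pytest.approx(nonoverlap_pct(b, a))

    def test_mismatched_edges_raise(self):
        a = self._hist([1, 0])
        b = self._hist([1, 0, 0])
        with pytest.raises(ValueError):
            nonoverlap_pct(a, b)

    def test_hedges_equal_means_zero(self):
        assert hedges_g([1, 2, 3], [3, 2, 1]) == 0.0

    def test_hedges_hand_example(self):
        assert abs(hedges_g([1, 2, 3], [2, 3, 4])) == pytest.approx(0.8)

    def test_hedges_antisymmetric(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        assert hedges_g(x, y) == pytest.approx(-hedges_g(y, x))

    def test_hedges_zero_variance_unequal_means_signals(self):
        with pytest.raises(ZeroDivisionError):
            hedges_g([1, 1, 1], [2, 2, 2])


class TestMeaningfulRule:
    def test_same_generator_not_meaningful(self):
        # at genome-scale sample sizes (tens of thousands of domains) the
        # histogram noise sits well below the 2% nonoverlap threshold
        flagged = 0
        for s in range(10):
            rng = np.random.default_rng(1000 + s)
            x = rng.lognormal(9, 1.2, 40_000)
            y = rng.lognormal(9, 1.2, 40_000)
            res = compare_distributions(x, y, kind="length")
            flagged += res.meaningful
        assert flagged <= 1  # type-I rate of the verdict stays low

    def test_three_sd_shift_meaningful(self, rng):
        x = rng.normal(0.40, 0.05, 5000)
        y = x + 0.15
        res = compare_distributions(x, y, kind="gc")
        assert res.meaningful
        assert abs(res.hedges_g) > 2

    def test_smoothed_ks_switch(self, rng):
        x = rng.lognormal(9, 1, 4000)
        y = rng.lognormal(9.5, 1, 4000)
        raw = compare_distributions(x, y, kind="length", ks_on="raw")
        smoothed = compare_distributions(x, y, kind="length", ks_on="smoothed")
        assert raw.ks_D != smoothed.ks_D  # different substrates
        assert 0 < smoothed.ks_D <= 1

    def test_result_invariants(self, rng):
        x = rng.lognormal(9, 1, 4000)
        y = rng.lognormal(9.2, 1, 4000)
        res = compare_distributions(x, y, kind="length")
        assert 0 <= res.ks_D <= 1
        assert 0 <= res.nonoverlap_pct <= 100
        assert np.isnan(res.p_fdr)  # filled by the caller's batch pass


class TestLilliefors:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(42)
        _, p = lilliefors_normality(rng.normal(0, 1, 1000))
        assert p > 0.05

    def test_uniform_sample_rejected(self):
        rng = np.random.default_rng(42)
        _, p = lilliefors_normality(rng.random(1000))
        assert p < 0.05

    def test_statistic_affine_invariant(self, rng):
        x = rng.normal(5, 2, 200)
        d1, _ = lilliefors_normality(x)
        d2, _ = lilliefors_normality(3.0 * x - 7.0)
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            lilliefors_normality([1.0] * 10)


class TestSkewness:
    def test_symmetric_sample_zero(self):
        assert skewness([1, 2, 3, 4, 5]).gamma == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        s = skewness([0, 0, 0, 1])
        assert s.gamma == pytest.approx(2 / np.sqrt(3), abs=1e-6)

    def test_exponential_limit(self):
        rng = np.random.default_rng(7)
        s = skewness(rng.exponential(1.0, 10**6))
        assert s.gamma == pytest.approx(2.0, abs=0.02)

    def test_positive_affine_invariance(self, rng):
        x = rng.exponential(1.0, 500)
        assert skewness(2.5 * x + 3).gamma == pytest.approx(skewness(x).gamma)

    def test_sign_flips_under_negation(self, rng):
        x = rng.exponential(1.0, 500)
        assert skewness(-x).gamma == pytest.approx(-skewness(x).gamma)

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            skewness([2.0, 2.0, 2.0])
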