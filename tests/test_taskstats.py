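"""Task-marker and statistics tests, with exact enumeration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as spstats

from interopipe.rates import RateSeries
from interopipe.taskstats import (
    align_transitions,
    bonferroni_channels,
    counting_accuracy,
    friedman_test,
    group_median_mad,
    monte_carlo_correct,
    spearman_p,
    wilcoxon_signed_rank,
)


class TestCountingAccuracy:
    @pytest.mark.parametrize("counted,beats,expected", [
        (60, 60, 1.0),
        (45, 60, 0.75),
        (0, 60, 0.0),
        (75, 60, 1.25),  # over-counting exceeds 1: no absolute value
    ])
    def test_percentage_error_form(self, counted, beats, expected):
        assert counting_accuracy(counted, beats) == pytest.approx(expected)

    def test_absolute_variant_symmetric(self):
        assert counting_accuracy(75, 60, absolute_error=True) == pytest.approx(0.75)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            counting_accuracy(10, 0)
        with pytest.raises(ValueError):
            counting_accuracy(-1, 60)


class TestAlignTransitions:
    def _marker(self, values, fs=4.0):
        return RateSeries(t=np.arange(values.size) / fs, value=values, source="heart")

    def test_constant_marker_zero_epochs_flagged(self):
        m = self._marker(np.full(2000, 1.2))
        ep = align_transitions(m, np.array([200.0]), (-30.0, 30.0))
        assert ep.zero_variance
        assert np.allclose(ep.average, 0.0)

    def test_step_gives_exact_antisymmetry(self):
        v = np.zeros(2000)
        v[800:] = 1.0  # step at t = 200 s
        ep = align_transitions(self._marker(v), np.array([200.0]), (-30.0, 30.0))
        pre, post = ep.pre_post_means()
        assert pre == pytest.approx(-post, abs=1e-12)
        # z-scored step halves sit at ~±1 (bin-center interpolation blurs
        # only the sample adjacent to the transition)
        assert pre == pytest.approx(-1.0, abs=0.02)

    def test_zscore_window_mean_sd(self):
        rng = np.random.default_rng(0)
        m = self._marker(1.2 + 0.1 * rng.normal(size=4000))
        ep = align_transitions(m, np.array([300.0, 500.0, 700.0]), (-30.0, 30.0))
        assert abs(ep.average.mean()) < 1e-9
        assert abs(ep.average.std() - 1.0) < 1e-9
        assert ep.aligned.shape[0] == 3

    def test_uncovered_transition_dropped_with_warning(self):
        m = self._marker(np.arange(400.0))
        with pytest.warns(UserWarning):
            ep = align_transitions(m, np.array([5.0, 50.0]), (-30.0, 30.0))
        assert ep.n_dropped == 1 and ep.aligned.shape[0] == 1

    def test_all_uncovered_rejected(self):
        m = self._marker(np.arange(100.0))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                align_transitions(m, np.array([1.0]), (-30.0, 30.0))

    def test_display_smoothing_runs(self):
        rng = np.random.default_rng(1)
        m = self._marker(1.2 + 0.1 * rng.normal(size=2000))
        ep = align_transitions(m, np.array([200.0]), (-30.0, 30.0), smooth_s=10.0)
        assert ep.average.size == ep.rel_t.size


class TestGroupMedianMad:
    @pytest.mark.parametrize("values,expected", [
        ([1, 2, 3], (2.0, 1.0)),
        ([5, 5, 5, 5], (5.0, 0.0)),
        ([1.1, 1.2, 1.3, 1.4, 10], (1.3, 0.1)),
    ])
    def test_unscaled_mad(self, values, expected):
        med, mad = group_median_mad(np.array(values, dtype=float))
        assert med == pytest.approx(expected[0])
        assert mad == pytest.approx(expected[1])


def _exact_two_sided_p(d):
    """Enumeration oracle: two-sided sign-flip p of the signed-rank W+."""
    n = d.size
    r = spstats.rankdata(np.abs(d))
    mu = n * (n + 1) / 4.0
    w_obs = r[d > 0].sum()
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(ri for ri, s in zip(r, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_identical_pairs_rejected(self):
        x = np.arange(6.0)
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(x, x)

    def test_normal_approx_close_to_exact_enumeration_in_tail(self):
        # the normal approximation matters where decisions are made: for
        # one-sided-extreme difference sets its two-sided p tracks the exact
        # sign-flip enumeration closely (n=6 all-positive: exact 2/64)
        rng = np.random.default_rng(3)
        for n in (6, 8, 10):
            d = np.abs(rng.normal(0.5, 1.0, n)) + 1e-6
            out = wilcoxon_signed_rank(d, np.zeros_like(d))
            exact = _exact_two_sided_p(d)
            if n == 6:
                assert exact == pytest.approx(2 / 64)
            assert abs(out.p - exact) <= 0.02

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(1, 1, 12), rng.normal(0, 1, 12)
        a = wilcoxon_signed_rank(x, y)
        b = wilcoxon_signed_rank(y, x)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_magnitude_matches_scipy_approx(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0.5, 1, 15), rng.normal(0, 1, 15)
        mine = wilcoxon_signed_rank(x, y)
        ref = spstats.wilcoxon(x, y, method="approx", correction=False)
        assert abs(mine.z) == pytest.approx(abs(ref.zstatistic), abs=1e-9)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-9)


class TestMonteCarlo:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0.5, 1, 10), rng.normal(0, 1, 10)
        a = monte_carlo_correct(x, y, n_perm=2000, seed=11)
        b = monte_carlo_correct(x, y, n_perm=2000, seed=11)
        assert a.p_mc == b.p_mc

    def test_converges_to_exact_enumeration(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.8, 1.0, 8)
        y = rng.normal(0.0, 1.0, 8)
        out = monte_carlo_correct(x, y, n_perm=10_000, seed=2)
        d = x - y
        d = d[d != 0]
        r = spstats.rankdata(np.abs(d))
        n = d.size
        mu = n * (n + 1) / 4.0
        sig = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        count = 0
        for signs in itertools.product((0, 1), repeat=n):
            w = sum(ri for ri, s in zip(r, signs) if s)
            p = 2 * spstats.norm.sf(abs((w - mu) / sig))
            count += p <= out.p + 1e-12
        exact = count / 2**n
        assert abs(out.p_mc - exact) <= 0.01

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(20):
            x = rng.normal(2.0, 1.0, 19)
            y = rng.normal(0.0, 1.0, 19)
            out = monte_carlo_correct(x, y, n_perm=2000, seed=int(rng.integers(2**31)))
            hits += out.p_mc <= 0.01
        assert hits >= 19

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_correct(np.arange(6.0), np.zeros(6), n_perm=0)


class TestFriedman:
    def test_identical_conditions(self):
        data = np.tile(np.arange(10.0)[:, None], (1, 4))
        out = friedman_test(data)
        assert out.statistic == 0.0 and out.p == 1.0

    def test_matches_rank_formula_without_ties(self):
        rng = np.random.default_rng(9)
        data = rng.normal(0, 1, (10, 3)) + np.array([0.0, 0.5, 1.0])
        out = friedman_test(data)
        ranks = np.vstack([spstats.rankdata(row) for row in data])
        n, k = data.shape
        chi2 = 12.0 / (n * k * (k + 1)) * np.sum(ranks.sum(axis=0) ** 2) - 3 * n * (k + 1)
        assert out.statistic == pytest.approx(chi2, rel=1e-9)
        assert out.p == pytest.approx(spstats.chi2.sf(chi2, k - 1), rel=1e-9)

    def test_label_permutation_preserves_null(self):
        rng = np.random.default_rng(10)
        data = rng.normal(0, 1, (12, 4))
        a = friedman_test(data).statistic
        b = friedman_test(data[:, [2, 0, 3, 1]]).statistic
        assert a == pytest.approx(b)

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.ones((1, 3)))


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        out = spearman_p(x, np.exp(x))
        assert out.statistic == pytest.approx(1.0)
        assert out.p == 0.0

    def test_t_approximation_matches_scipy(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 1, 19), rng.normal(0, 1, 19)
        mine = spearman_p(x, y)
        rho_ref, p_ref = spstats.spearmanr(x, y)
        assert mine.statistic == pytest.approx(rho_ref, abs=1e-12)
        assert mine.p == pytest.approx(p_ref, rel=1e-6)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(12)
        ps = [spearman_p(rng.random(20), rng.random(20)).p for _ in range(500)]
        assert spstats.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_p(np.arange(3.0), np.arange(3.0))


class TestProperties:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30),
           st.floats(-10, 10), st.floats(0.1, 10))
    def test_median_mad_affine_equivariance(self, values, shift, scale):
        x = np.asarray(values)
        med, mad = group_median_mad(x)
        med2, mad2 = group_median_mad(scale * x + shift)
        assert med2 == pytest.approx(scale * med + shift, abs=1e-9 * (1 + abs(med)))
        assert mad2 == pytest.approx(scale * mad, abs=1e-9 * (1 + mad))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(6, 25))
    def test_wilcoxon_antisymmetry_property(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.3, 1, n)
        y = rng.normal(0.0, 1, n)
        if np.count_nonzero(x - y) < 5:
            return
        a = wilcoxon_signed_rank(x, y)
        b = wilcoxon_signed_rank(y, x)
        assert a.z == pytest.approx(-b.z, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)


class TestBonferroni:
    def test_threshold_arithmetic(self):
        flags = bonferroni_channels(np.array([0.002, 0.0025, 1.0]))
        assert flags.tolist() == [True, False, False]

    def test_all_ones_unflagged(self):
        assert not bonferroni_channels(np.ones(23)).any()
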