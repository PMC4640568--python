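"""Permutation linear models: OLS, significance, runs, FDR, windows."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import spikeswitch as ss
from spikeswitch.linear import (BinwiseModelResult, bh_fdr,
                                build_permutation_null, encoding_window,
                                fit_bin_regression, max_run_length,
                                per_bin_significance, run_length_pvalue)


class TestBinRegression:
    def test_exact_fit(self):
        slope, intercept, r2 = fit_bin_regression([1, 2, 3], [2, 4, 6])
        assert (slope, intercept, r2) == pytest.approx((2.0, 0.0, 1.0))

    def test_constant_y_contract(self):
        slope, intercept, r2 = fit_bin_regression([1, 2, 3], [5, 5, 5])
        assert (slope, r2) == (0.0, 0.0)
        assert intercept == 5.0

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            fit_bin_regression([2, 2, 2], [1, 2, 3])

    def test_matches_statsmodels_ols(self, rng):
        for _ in range(50):
            n = rng.integers(5, 40)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            slope, intercept, r2 = fit_bin_regression(x, y)
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            assert slope == pytest.approx(fit.params[1], abs=1e-10)
            assert intercept == pytest.approx(fit.params[0], abs=1e-10)
            assert r2 == pytest.approx(fit.rsquared, abs=1e-10)


class TestPermutationNull:
    def test_null_shapes(self, rng):
        Y = rng.normal(size=(30, 25))
        x = rng.normal(size=30)
        ns, nr = build_permutation_null(Y, x, n_surrogates=100, rng=rng)
        assert ns.shape == nr.shape == (100, 25)

    def test_surrogate_count_validated(self, rng):
        with pytest.raises(ValueError):
            build_permutation_null(rng.normal(size=(10, 25)),
                                   rng.normal(size=10), n_surrogates=0)

    def test_surrogate_rows_match_scalar_refits(self, rng):
        """Each surrogate row equals bin-by-bin OLS on the permuted labels."""
        Y = rng.normal(size=(12, 5))
        x = rng.normal(size=12)
        rng2 = np.random.default_rng(77)
        ns, nr = build_permutation_null(Y, x, n_surrogates=3, rng=rng2)
        rng3 = np.random.default_rng(77)
        for s in range(3):
            xp = x[rng3.permutation(12)]
            for b in range(5):
                slope, _, r2 = fit_bin_regression(xp, Y[:, b])
                assert ns[s, b] == pytest.approx(slope, abs=1e-12)
                assert nr[s, b] == pytest.approx(r2, abs=1e-12)


class TestPerBinSignificance:
    def test_median_observed_not_significant(self, rng):
        null = rng.normal(size=(200, 25))
        obs = np.median(null, axis=0)
        assert not per_bin_significance(obs, null, "slope").any()

    def test_extreme_observed_significant(self, rng):
        null = rng.normal(size=(200, 25))
        obs = null.max(axis=0) + 1.0
        assert per_bin_significance(obs, null, "slope").all()
        assert per_bin_significance(obs, null, "r2").all()

    def test_agrees_with_sorting_oracle(self, rng):
        """Two-sided slope rule vs an independently coded interpolated
        percentile (sort + linear interpolation)."""
        def quantile_oracle(v, q):
            s = np.sort(v)
            pos = q * (s.size - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, s.size - 1)
            return s[lo] + (pos - lo) * (s[hi] - s[lo])

        null = rng.normal(size=(101, 10))
        obs = rng.normal(size=10) * 2
        got = per_bin_significance(obs, null, "slope", alpha=0.05)
        want = np.array([
            obs[b] < quantile_oracle(null[:, b], 0.025)
            or obs[b] > quantile_oracle(null[:, b], 0.975)
            for b in range(10)])
        np.testing.assert_array_equal(got, want)


class TestRuns:
    @pytest.mark.parametrize("mask,expected", [
        ([False] * 25, 0),
        ([True] * 25, 25),
        ([True, True, False, True, True, True] + [False] * 19, 3),
    ])
    def test_max_run_length(self, mask, expected):
        assert max_run_length(np.array(mask)) == expected

    def test_run_pvalue_add_one_rule(self):
        null = np.zeros(100, dtype=int)
        assert run_length_pvalue(5, null) == pytest.approx(1 / 101)
        assert run_length_pvalue(0, null) == 1.0
        null[:50] = 10
        assert run_length_pvalue(10, null) == pytest.approx(51 / 101)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=26))
    def test_run_pvalue_monotone(self, k):
        null = np.random.default_rng(3).integers(0, 25, size=100)
        assert run_length_pvalue(k, null) >= run_length_pvalue(k + 1, null)


class TestBhFdr:
    def test_all_ones_no_rejections(self):
        assert not bh_fdr([1.0, 1.0, 1.0], 0.05).any()

    def test_small_pvalues_all_rejected(self):
        # largest i with p(i) <= i q/m is i=4 here: every hypothesis rejected
        assert bh_fdr([0.001, 0.01, 0.02, 0.05], 0.05).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5], 0.05)

    def test_matches_brute_force_step_up(self, rng):
        def brute_force(p, q):
            p = np.asarray(p)
            m = p.size
            order = np.argsort(p, kind="stable")
            thresh = 0.0
            for i in range(1, m + 1):
                if p[order[i - 1]] <= i * q / m:
                    thresh = p[order[i - 1]]
            return p <= thresh if thresh > 0 else np.zeros(m, bool)

        for _ in range(1000):
            m = rng.integers(1, 12)
            p = rng.random(m).clip(1e-9, 1.0)
            q = rng.choice([0.01, 0.05, 0.1, 0.2])
            np.testing.assert_array_equal(bh_fdr(p, q), brute_force(p, q))


def _result(slope_sig, r2_sig, nid=0):
    n = len(slope_sig)
    z = np.zeros(n)
    return BinwiseModelResult(
        neuron_id=nid, model="lm_mt", slope=z, intercept=z, r2=z,
        slope_sig=np.array(slope_sig, bool), r2_sig=np.array(r2_sig, bool),
        max_run_slope=0, max_run_r2=0, p_run_slope=1.0, p_run_r2=1.0,
        n_surrogates=100, n_trials=10)


class TestEncodingWindow:
    def test_intersection_of_masks(self):
        sl = [5 <= k <= 15 for k in range(25)]
        r2 = [10 <= k <= 20 for k in range(25)]
        assert encoding_window(_result(sl, r2)) == (10, 15)

    def test_disjoint_masks_absent(self):
        sl = [k < 5 for k in range(25)]
        r2 = [k > 10 for k in range(25)]
        assert encoding_window(_result(sl, r2)) is None

    def test_longer_model_wins(self):
        a = _result([k < 3 for k in range(25)], [k < 3 for k in range(25)])
        b = _result([5 <= k < 10 for k in range(25)],
                    [5 <= k < 10 for k in range(25)])
        assert encoding_window(a, b) == (5, 9)

    def test_tie_breaks_to_earlier_interval(self):
        a = _result([10 <= k < 13 for k in range(25)],
                    [10 <= k < 13 for k in range(25)])
        b = _result([2 <= k < 5 for k in range(25)],
                    [2 <= k < 5 for k in range(25)])
        assert encoding_window(a, b) == (2, 4)


class TestRunLinearModel:
    def test_deterministic_given_seed(self, demo_session):
        r1, _ = ss.linear.run_linear_model(demo_session, "lm_mt",
                                           n_surrogates=20, seed=7)
        r2, _ = ss.linear.run_linear_model(demo_session, "lm_mt",
                                           n_surrogates=20, seed=7)
        for nid in r1:
            assert r1[nid].p_run_slope == r2[nid].p_run_slope
            np.testing.assert_array_equal(r1[nid].slope, r2[nid].slope)

    def test_trial_order_invariance(self, demo_session):
        """Observed statistics are label-based: shuffling trial order of
        the session leaves per-bin slopes unchanged."""
        res, _ = ss.linear.run_linear_model(demo_session, "lm_diff",
                                            n_surrogates=1, seed=0)
        import copy
        shuffled = copy.deepcopy(demo_session)
        rng = np.random.default_rng(5)
        ids = shuffled.trial_ids
        remap = dict(zip(ids, rng.permutation(ids)))
        shuffled.trials = {remap[t.trial_id]:
                           ss.TrialRecord(remap[t.trial_id], t.s1_deg,
                                          t.s2_deg, t.tro_deg, t.choice,
                                          t.correct, t.mt_ms, t.saccade_ms)
                           for t in shuffled.trials.values()}
        for sp in shuffled.spikes:
            sp.trial_id = remap[sp.trial_id]
        res2, _ = ss.linear.run_linear_model(shuffled, "lm_diff",
                                             n_surrogates=1, seed=0)
        for nid in res:
            np.testing.assert_allclose(res[nid].slope, res2[nid].slope,
                                       atol=1e-9)

    def test_mt_neurons_detected_nulls_not(self, demo_session):
        fit = ss.BinwiseLinearModel(demo_session, "lm_mt").fit(
            n_surrogates=100, seed=3)
        flagged = set(fit.flagged(0.05))
        gt = demo_session.ground_truth
        mt_ids = {n for n, d in gt.items() if d["mechanism"] == "mt_code"}
        assert mt_ids <= flagged
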