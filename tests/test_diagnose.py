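"""Summaries, Gelman-Rubin, DIC and posterior tests against hand oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddmbayes import diagnose, infer
from ddmbayes.diagnose import dic, gelman_rubin, prob_greater, summarize


class TestSummarize:
    def test_constant_samples(self):
        tab = summarize({"x": np.full(50, 2.5)})
        row = tab.loc["x"]
        assert row["std"] == 0.0
        for q in ("2.5q", "25q", "50q", "75q", "97.5q"):
            assert row[q] == 2.5

    def test_median_interpolation(self):
        tab = summarize({"x": np.arange(1, 101, dtype=float)})
        assert tab.loc["x", "50q"] == pytest.approx(50.5)

    def test_column_order(self):
        tab = summarize({"x": np.arange(10.0)})
        assert list(tab.columns) == ["mean", "std", "2.5q", "25q", "50q",
                                     "75q", "97.5q"]

    def test_quantiles_match_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        s = rng.gamma(2.0, 1.5, size=777)
        tab = summarize({"x": s})
        # brute force: sort, then linear interpolation between order stats
        xs = np.sort(s)
        for q, col in [(0.025, "2.5q"), (0.25, "25q"), (0.5, "50q"),
                       (0.75, "75q"), (0.975, "97.5q")]:
            h = q * (len(xs) - 1)
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            expect = xs[lo] + (h - lo) * (xs[hi] - xs[lo])
            assert tab.loc["x", col] == pytest.approx(expect)

    def test_autocorrelation_columns(self):
        rng = np.random.default_rng(0)
        tab = summarize({"x": rng.standard_normal(500)}, acf_lags=3)
        assert {"acf.1", "acf.2", "acf.3"} <= set(tab.columns)
        assert abs(tab.loc["x", "acf.1"]) < 0.15

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError, match="empty"):
            summarize({})
        with pytest.raises(ValueError, match="empty"):
            summarize({"x": np.array([])})


class TestGelmanRubin:
    def test_iid_chains_are_converged(self):
        rng = np.random.default_rng(1)
        chains = [{"x": rng.normal(0, 1, 10000)} for _ in range(5)]
        r = gelman_rubin(chains)["x"]
        # the classical statistic can dip a fraction below 1 by sampling
        # noise ((n-1)/n * W + B/n slightly under W)
        assert 0.999 <= r <= 1.02

    def test_separated_chains_match_hand_formula(self):
        rng = np.random.default_rng(2)
        c1 = rng.normal(0, 1, 1000)
        c2 = rng.normal(10, 1, 1000)
        r = gelman_rubin([{"x": c1}, {"x": c2}])["x"]
        n = 1000
        W = (c1.var(ddof=1) + c2.var(ddof=1)) / 2
        B_over_n = np.var([c1.mean(), c2.mean()], ddof=1)
        expect = np.sqrt(((n - 1) / n * W + B_over_n) / W)
        assert r == pytest.approx(expect, rel=1e-12)
        assert r > 1.1

    def test_identical_copies_give_r_below_one(self):
        rng = np.random.default_rng(3)
        c = rng.normal(0, 1, 500)
        r = gelman_rubin([{"x": c}, {"x": c.copy()}])["x"]
        assert r <= 1.0 + 1e-12  # between-variance is exactly 0

    def test_errors(self):
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin([{"x": np.arange(10.0)}])
        with pytest.raises(ValueError, match="equal stored lengths"):
            gelman_rubin([{"x": np.arange(10.0)}, {"x": np.arange(9.0)}])
        with pytest.raises(ValueError, match="degenerate"):
            gelman_rubin([{"x": np.ones(10)}, {"x": np.ones(10)}])


class TestDic:
    def test_constant_deviance_has_zero_complexity(self, standard_normal_model):
        model = standard_normal_model
        model.loglik = lambda: -7.5  # independent of the state
        trace = infer.sample(model, n_samples=500, burn=50, seed=0)
        val = dic(model, trace)
        assert val == pytest.approx(15.0, abs=1e-9)

    def test_conjugate_matches_analytic_deviance(self, conjugate_model):
        trace = infer.sample(conjugate_model, n_samples=8000, burn=500,
                             seed=11)
        val = dic(conjugate_model, trace)
        # deviance is quadratic in theta: D(theta) = D(mean) + n (theta -
        # mean)^2 / sigma^2, so DIC = D(post mean) + 2 n tau*^2 / sigma^2
        mean, tau = conjugate_model.posterior
        conjugate_model.set_state({"theta": mean})
        d_hat = -2.0 * conjugate_model.loglik()
        n = len(conjugate_model.y)
        expect = d_hat + 2 * n * tau**2 / conjugate_model.sigma**2
        assert val == pytest.approx(expect, abs=0.25)

    def test_missing_node_raises(self, conjugate_model):
        trace = infer.sample(conjugate_model, n_samples=100, burn=10, seed=0)
        del trace.samples["theta"]
        trace.samples["other"] = np.zeros(len(trace.deviance))
        with pytest.raises(ValueError, match="does not cover"):
            dic(conjugate_model, trace)


class TestProbGreater:
    def test_complete_separation(self):
        assert prob_greater([1, 2, 3], [0, 0, 0]) == 1.0

    def test_ties_count_as_not_greater(self):
        x = np.array([1.0, 2.0, 3.0])
        assert prob_greater(x, x) == 0.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 500)
        b = rng.normal(0.3, 1, 500)
        count = sum(1 for ai, bi in zip(a, b) if ai > bi)
        assert prob_greater(a, b) == pytest.approx(count / 500)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            prob_greater([1, 2], [1, 2, 3])

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=30),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_complementarity(self, vals, seed):
        rng = np.random.default_rng(seed)
        a = np.array(vals)
        b = rng.permutation(a)
        total = prob_greater(a, b) + prob_greater(b, a)
        assert total <= 1.0 + 1e-12
        if len(np.unique(a)) == len(a):
            ties = np.sum(a == b) / len(a)
            assert total == pytest.approx(1.0 - ties)
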