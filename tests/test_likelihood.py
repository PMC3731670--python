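"""Likelihood kernel checks against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from ddmbayes.likelihood import (
    DDMParams,
    LikelihoodConfig,
    choice_prob_upper,
    dataset_loglik,
    full_density,
    wfpt_density,
)


def series_oracle_lower(rt, v, a, z, t, n_terms=2000):
    """Direct partial sums of the sine-series first-passage density at the
    lower boundary, far past machine-precision stability."""
    x = rt - t
    k = np.arange(1, n_terms + 1)
    s = np.sum(k * np.exp(-k**2 * np.pi**2 * x / (2 * a**2))
               * np.sin(k * np.pi * z))
    return np.pi / a**2 * np.exp(-v * a * z - v**2 * x / 2) * s


class TestWfptDensity:
    @pytest.mark.parametrize("rt,v,a,z,t", [
        (1.0, 1.0, 2.0, 0.5, 0.3),     # large-time branch
        (0.35, 1.0, 2.0, 0.5, 0.3),    # small-time branch
        (2.5, -0.8, 1.4, 0.3, 0.2),
        (0.6, 0.0, 2.5, 0.7, 0.1),
    ])
    def test_matches_long_series_oracle(self, rt, v, a, z, t):
        p = DDMParams(v=v, a=a, z=z, t=t)
        expected = series_oracle_lower(rt, v, a, z, t)
        assert wfpt_density(rt, "lower", p) == pytest.approx(
            expected, abs=1e-10)
        # upper boundary via the mirror map on the oracle side
        expected_up = series_oracle_lower(rt, -v, a, 1 - z, t)
        assert wfpt_density(rt, "upper", p) == pytest.approx(
            expected_up, abs=1e-10)

    def test_driftless_unbiased_symmetry(self):
        p = DDMParams(v=0.0, a=2.0, z=0.5, t=0.0)
        for rt in (0.2, 0.5, 1.0, 3.0):
            assert wfpt_density(rt, "upper", p) == \
                wfpt_density(rt, "lower", p)

    def test_zero_before_nondecision_time(self):
        p = DDMParams(v=1.0, a=2.0, z=0.5, t=0.3)
        assert wfpt_density(0.2, "upper", p) == 0.0
        assert wfpt_density(0.3, "lower", p) == 0.0

    def test_mirror_symmetry_exact(self):
        rt = np.linspace(0.05, 4.0, 50)
        p = DDMParams(v=0.7, a=1.8, z=0.35, t=0.0)
        pm = DDMParams(v=-0.7, a=1.8, z=0.65, t=0.0)
        np.testing.assert_array_equal(
            full_density(rt, "lower", p), full_density(rt, "upper", pm))

    def test_rejects_inter_trial_params(self):
        with pytest.raises(ValueError, match="sv=st=sz=0"):
            wfpt_density(1.0, "upper", DDMParams(v=1, a=2, z=0.5, sv=0.5))

    @given(v=st.floats(-3, 3), a=st.floats(0.5, 3), z=st.floats(0.1, 0.9),
           rt=st.floats(0.01, 5))
    @settings(max_examples=50, deadline=None)
    def test_density_nonnegative_and_mirror(self, v, a, z, rt):
        p = DDMParams(v=v, a=a, z=z, t=0.0)
        pm = DDMParams(v=-v, a=a, z=1 - z, t=0.0)
        d = wfpt_density(rt, "lower", p)
        assert d >= 0
        # 1 - (1 - z) can round by one ulp, so near-exact here; the exact
        # identity is asserted in test_mirror_symmetry_exact
        assert d == pytest.approx(wfpt_density(rt, "upper", pm),
                                  rel=1e-9, abs=1e-300)


class TestFullDensity:
    def test_reduces_to_simple_kernel(self):
        p = DDMParams(v=1.2, a=1.7, z=0.4, t=0.25)
        rt = np.linspace(0.3, 3.0, 40)
        np.testing.assert_array_equal(
            full_density(rt, "upper", p), wfpt_density(rt, "upper", p))

    def test_sv_matches_quadrature_oracle(self):
        p = DDMParams(v=1.0, a=2.0, z=0.5, t=0.3, sv=0.5)
        for rt in (0.6, 1.0, 2.0):
            oracle = quad(
                lambda vv: wfpt_density(
                    rt, "upper", DDMParams(v=vv, a=2.0, z=0.5, t=0.3))
                * norm.pdf(vv, 1.0, 0.5), -6, 8, limit=200)[0]
            assert full_density(rt, "upper", p) == pytest.approx(
                oracle, rel=1e-8)

    def test_st_matches_dense_grid_oracle(self):
        p = DDMParams(v=1.0, a=2.0, z=0.5, t=0.3, st=0.2)
        ts = np.linspace(0.2, 0.4, 10001)
        for rt in (0.8, 1.5):
            vals = wfpt_density(
                np.full(ts.shape, rt) - ts + 0.3, "upper",
                DDMParams(v=1.0, a=2.0, z=0.5, t=0.3))
            oracle = np.trapezoid(vals, ts) / 0.2
            assert full_density(rt, "upper", p) == pytest.approx(
                oracle, rel=1e-4)

    def test_sz_matches_dense_grid_oracle(self):
        p = DDMParams(v=0.8, a=2.0, z=0.5, t=0.2, sz=0.2)
        zs = np.linspace(0.4, 0.6, 10001)
        rt = 1.0
        vals = [wfpt_density(rt, "upper",
                             DDMParams(v=0.8, a=2.0, z=zz, t=0.2))
                for zz in zs]
        oracle = np.trapezoid(vals, zs) / 0.2
        assert full_density(rt, "upper", p) == pytest.approx(
            oracle, rel=1e-4)

    def test_normalizes_on_parameter_grid(self):
        rt = np.linspace(1e-4, 40.0, 8001)
        for v, a, z in [(1, 2, 0.5), (-0.5, 1.2, 0.3), (2, 2.5, 0.7)]:
            p = DDMParams(v=v, a=a, z=z, t=0.0)
            total = np.trapezoid(
                full_density(rt, "upper", p) + full_density(rt, "lower", p),
                rt)
            assert total == pytest.approx(1.0, abs=1e-3)


class TestDatasetLoglik:
    def _trials(self, rts, resps):
        import pandas as pd
        return pd.DataFrame({"rt": rts, "response": resps})

    def test_single_trial_equals_log_density(self):
        p = DDMParams(v=1.0, a=2.0, z=0.5, t=0.3)
        ll = dataset_loglik(self._trials([1.0], [1]), p)
        assert ll == pytest.approx(np.log(full_density(1.0, "upper", p)))

    def test_impossible_observation_gives_neg_inf(self):
        p = DDMParams(v=1.0, a=2.0, z=0.5, t=0.5)
        assert dataset_loglik(self._trials([0.4, 1.0], [1, 0]), p) == -np.inf

    def test_pure_outlier_mixture_arithmetic(self):
        p = DDMParams(v=1.0, a=2.0, z=0.5, t=0.3)
        cfg = LikelihoodConfig(p_outlier=1.0, max_rt=5.0)
        n = 7
        ll = dataset_loglik(
            self._trials([0.9] * n, [1, 0, 1, 1, 0, 1, 0]), p, cfg)
        assert ll == pytest.approx(n * np.log(1 / (2 * 5.0)))

    def test_outlier_mixture_rescues_early_rt(self):
        p = DDMParams(v=1.0, a=2.0, z=0.5, t=0.5)
        cfg = LikelihoodConfig(p_outlier=0.05, max_rt=5.0)
        ll = dataset_loglik(self._trials([0.4], [1]), p, cfg)
        assert ll == pytest.approx(np.log(0.05 / 10.0))

    def test_errors(self):
        p = DDMParams(v=1.0, a=2.0, z=0.5)
        with pytest.raises(ValueError, match="empty"):
            dataset_loglik(self._trials([], []), p)
        with pytest.raises(ValueError, match="> 0"):
            dataset_loglik(self._trials([-0.1], [1]), p)


class TestChoiceProbUpper:
    def test_driftless_returns_start_point(self):
        assert choice_prob_upper(0.0, 2.0, 0.7) == 0.7

    def test_closed_form_value(self):
        expected = (1 - np.exp(-2 * 1 * 1)) / (1 - np.exp(-2 * 1 * 2))
        assert choice_prob_upper(1.0, 2.0, 0.5) == pytest.approx(
            expected, abs=1e-12)
        assert choice_prob_upper(1.0, 2.0, 0.5) == pytest.approx(
            0.88080, abs=1e-5)

    def test_strong_drift_limit(self):
        assert choice_prob_upper(50.0, 2.0, 0.5) == pytest.approx(1.0)
        assert choice_prob_upper(-50.0, 2.0, 0.5) == pytest.approx(
            0.0, abs=1e-12)

    def test_monotone_in_drift(self):
        vs = np.linspace(-3, 3, 25)
        ps = [choice_prob_upper(v, 1.8, 0.4) for v in vs]
        assert np.all(np.diff(ps) > 0)

    def test_equals_integrated_upper_density(self):
        rt = np.linspace(1e-4, 40.0, 8001)
        for v, a, z in [(0.5, 1.5, 0.4), (1.5, 2.2, 0.6), (-1.0, 1.0, 0.5)]:
            p = DDMParams(v=v, a=a, z=z, t=0.0)
            integral = np.trapezoid(full_density(rt, "upper", p), rt)
            assert choice_prob_upper(v, a, z) == pytest.approx(
                integral, abs=1e-4)


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        {"v": 1, "a": -1, "z": 0.5},
        {"v": 1, "a": 2, "z": 0.0},
        {"v": 1, "a": 2, "z": 1.2},
        {"v": 1, "a": 2, "z": 0.5, "t": -0.1},
        {"v": 1, "a": 2, "z": 0.5, "sv": -0.2},
        {"v": 1, "a": 2, "z": 0.1, "sz": 0.4},
        {"v": 1, "a": 2, "z": 0.5, "t": 0.05, "st": 0.2},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DDMParams(**kwargs)
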