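"""Model graph construction, priors, and the regression builder."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from ddmbayes.model import (
    ModelSpec,
    PriorSpec,
    build_model,
    build_regression_model,
    prior_logpdf,
)
from ddmbayes.simulate import ExperimentDesign, sample_group_dataset


@pytest.fixture(scope="module")
def small_data():
    design = ExperimentDesign(n_subjects=3, n_trials=12, seed=5, dt=1e-3)
    data, _ = sample_group_dataset(design)
    return data


def _make_data(n_subjects, n_levels, n_per_cell=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for lv in range(n_levels):
            for _ in range(n_per_cell):
                rows.append({"subj_idx": s,
                             "rt": 0.3 + rng.uniform(0.1, 1.5),
                             "response": int(rng.integers(0, 2)),
                             "stim": f"s{lv}"})
    return pd.DataFrame(rows)


class TestBuildModel:
    def test_condition_split_node_counts(self):
        data = _make_data(12, 3)
        g = build_model(data, ModelSpec(depends_on={"v": "stim"}))
        names = g.free_names
        v_means = [n for n in names if n.startswith("v(") and
                   not n.endswith("_std") and "_subj" not in n]
        v_stds = [n for n in names if n.startswith("v(") and
                  n.endswith("_std")]
        v_subj = [n for n in names if n.startswith("v(") and "_subj" in n]
        assert len(v_means) == 3
        assert len(v_stds) == 3
        assert len(v_subj) == 36

    def test_no_split_gives_one_group_distribution_per_param(self, small_data):
        g = build_model(small_data)
        params = [gd.param for gd in g.group_distributions]
        assert sorted(params) == ["a", "t", "v"]

    def test_single_subject_uses_group_mean_priors(self):
        data = _make_data(1, 1)
        g = build_model(data)
        assert g.group_distributions == []
        assert set(g.free_names) == {"v", "a", "t"}

    def test_group_only_intertrial_nodes(self, small_data):
        g = build_model(small_data, ModelSpec(include=("sv", "st", "sz")))
        for p in ("sv", "st", "sz"):
            assert p in g.free_names
            assert not any(n.startswith(f"{p}_subj")
                           for n in g.free_names)

    def test_missing_depends_on_column(self, small_data):
        with pytest.raises(ValueError, match="missing column"):
            build_model(small_data, ModelSpec(depends_on={"v": "nope"}))

    def test_missing_required_column(self):
        with pytest.raises(ValueError, match="required column"):
            build_model(pd.DataFrame({"rt": [0.5]}))

    def test_joint_logp_is_finite(self, small_data):
        g = build_model(small_data, ModelSpec(include=("sv",)))
        assert np.isfinite(g.logp())
        # joint = sum of priors + data loglik; both pieces finite
        assert np.isfinite(g.loglik())

    def test_every_trial_binds_one_parameter_set(self, small_data):
        g = build_model(small_data, ModelSpec(depends_on={"v": "cond"}))
        for p in ("v", "a", "z", "t"):
            assert g._trial_cache[p].shape == g.rt.shape


class TestRegressionModel:
    def test_printed_coefficient_names(self, capsys):
        rng = np.random.default_rng(0)
        n = 40
        data = pd.DataFrame({
            "subj_idx": np.repeat([0, 1], n // 2),
            "rt": 0.4 + rng.uniform(0.1, 1.0, n),
            "response": rng.integers(0, 2, n),
            "theta": rng.standard_normal(n),
            "conf": rng.choice(["HC", "LC"], n),
        })
        g = build_regression_model(
            data, "a ~ theta:C(conf, Treatment('LC'))")
        assert g.regression_coef_names == [
            "a_Intercept",
            "a_theta:C(conf, Treatment('LC'))[HC]",
            "a_theta:C(conf, Treatment('LC'))[LC]",
        ]
        out = capsys.readouterr().out
        assert "Adding these covariates:" in out

    def test_intercept_only_matches_plain_model_structure(self, small_data):
        g_reg = build_regression_model(small_data, "a ~ 1")
        g_plain = build_model(small_data)
        reg_nodes = {n.replace("a_Intercept", "a") for n in g_reg.free_names}
        assert reg_nodes == set(g_plain.free_names)

    def test_trial_value_is_design_row_times_coefficients(self):
        data = pd.DataFrame({
            "subj_idx": [0, 0, 0, 0],
            "rt": [0.8, 0.9, 1.0, 1.1],
            "response": [1, 0, 1, 1],
            "x": [1.5, 0.0, -1.0, 2.0],
        })
        g = build_regression_model(data, "a ~ x",
                                   ModelSpec(is_group_model=False))
        g.set_state({"a_Intercept": 2.0, "a_x": 0.3})
        np.testing.assert_allclose(
            g._trial_cache["a"], 2.0 + 0.3 * np.array([1.5, 0.0, -1.0, 2.0]))
        assert g._trial_cache["a"][0] == pytest.approx(2.45)

    def test_unknown_outcome_rejected(self, small_data):
        with pytest.raises(ValueError, match="outcome"):
            build_regression_model(small_data, "q ~ cond")

    def test_rank_deficient_design_rejected(self, small_data):
        data = small_data.copy()
        data["x1"] = 1.0  # constant column duplicates the intercept
        with pytest.raises(ValueError, match="rank-deficient"):
            build_regression_model(data, "v ~ x1")


class TestPriors:
    def test_halfnormal_negative_is_impossible(self):
        spec = PriorSpec("halfnormal", (1.0,))
        assert prior_logpdf(spec, -0.1) == -np.inf
        assert np.isfinite(prior_logpdf(spec, 0.5))

    def test_uniform_beta_is_flat(self):
        spec = PriorSpec("beta", (1.0, 1.0))
        for x in (0.1, 0.5, 0.9):
            assert prior_logpdf(spec, x) == pytest.approx(0.0, abs=1e-12)

    def test_gamma_mean_rate_parameterization(self):
        # shape = mean * rate; density must integrate to 1 and have the
        # declared mean
        spec = PriorSpec("gamma", (1.5, 2.0))
        total = quad(lambda x: np.exp(prior_logpdf(spec, x)), 0, 60,
                     limit=200)[0]
        assert total == pytest.approx(1.0, abs=1e-8)
        mean = quad(lambda x: x * np.exp(prior_logpdf(spec, x)), 0, 60,
                    limit=200)[0]
        assert mean == pytest.approx(1.5, abs=1e-6)

    def test_normal_matches_scipy(self):
        from scipy.stats import norm
        spec = PriorSpec("normal", (2.0, 3.0))
        assert prior_logpdf(spec, 0.7) == pytest.approx(
            norm.logpdf(0.7, 2.0, 3.0))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec("normal", (0.0, -1.0))
        with pytest.raises(ValueError):
            PriorSpec("cauchy", (0.0, 1.0))
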