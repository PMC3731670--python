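"""Comparison estimators and parameter-recovery experiments.

Implements the two classical single-subject estimators the hierarchical
model is benchmarked against — maximum likelihood on the first-passage
density, and the chi-square quantile method (observed vs. predicted counts
in RT-quantile bins per boundary) — together with the experiment driver
that simulates multi-subject datasets, fits every method, and scores
recovery error (trimmed mean absolute error) and effect detection.

Detection rules: the non-hierarchical methods declare a drift-rate
difference when a paired t-test across subjects is significant at 0.05
(one-sample t-test against zero for covariate effects); the hierarchical
model declares an effect when the central 95% posterior interval of the
group-level difference (or group covariate coefficient) excludes zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import infer
from .likelihood import DDMParams, choice_prob_upper, wiener_logpdf
from .model import ModelSpec, build_model, build_regression_model
from .simulate import ExperimentDesign, generate_covariate_dataset, \
    sample_group_dataset

__all__ = [
    "SubjectFit",
    "RecoveryResult",
    "fit_ml",
    "fit_quantile_chisq",
    "run_recovery",
    "trimmed_mae",
    "detection_decision",
    "chi_square_statistic",
]

logger = logging.getLogger(__name__)

DEFAULT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class SubjectFit:
    """Point estimates for one subject from one method."""

    estimates: dict[str, float]
    score: float  # log-likelihood (ML) or chi-square statistic (quantiles)
    method: str
    degenerate: bool = False

    def to_ddm_params(self) -> DDMParams:
        e = self.estimates
        v = e.get("v", e.get("v(c0)", 0.0))
        return DDMParams(v=v, a=e["a"], z=e.get("z", 0.5), t=e["t"],
                         sv=e.get("sv", 0.0))


@dataclass
class RecoveryResult:
    """Tidy results of a recovery experiment.

    ``errors``: one row per dataset x method x subject x parameter with the
    estimate, the generating truth and the absolute error.
    ``detections``: one row per cell x dataset x method with the boolean
    detection flag.
    """

    errors: pd.DataFrame
    detections: pd.DataFrame


# ---------------------------------------------------------------------------
# shared free-parameter machinery for the point estimators
# ---------------------------------------------------------------------------

class _FreeParams:
    """Map between an unconstrained optimizer vector and DDM parameters.

    Free parameters: one drift per condition level (or intercept+slopes
    when regressing drift on a covariate), log-threshold, logit
    non-decision time scaled to (0, min rt), and optionally log-sv.
    """

    def __init__(self, trials, split_v_by=None, regress_v_on=None,
                 include_sv=True, z=0.5):
        self.rt = trials["rt"].to_numpy(dtype=float)
        self.resp = trials["response"].to_numpy(dtype=int)
        self.min_rt = float(self.rt.min())
        self.include_sv = include_sv
        self.z = z
        self.levels = [None]
        self.lev_codes = np.zeros(len(self.rt), dtype=int)
        self.x_cov = None
        if split_v_by is not None:
            labels = trials[split_v_by].astype(str).to_numpy()
            self.levels = sorted(set(labels))
            self.lev_codes = np.searchsorted(np.array(self.levels), labels)
        elif regress_v_on is not None:
            self.x_cov = trials[regress_v_on].to_numpy(dtype=float)
        self.n_v = 2 if self.x_cov is not None else len(self.levels)
        self.n = self.n_v + 2 + (1 if include_sv else 0)

    def unpack(self, y):
        vs = y[:self.n_v]
        a = float(np.exp(y[self.n_v]))
        t = float(self.min_rt * expit(y[self.n_v + 1]))
        sv = float(np.exp(y[self.n_v + 2])) if self.include_sv else 0.0
        return vs, a, t, sv

    def pack(self, vs, a, t, sv):
        y = list(vs) + [np.log(a), logit(np.clip(t / self.min_rt,
                                                 1e-6, 1 - 1e-6))]
        if self.include_sv:
            y.append(np.log(max(sv, 1e-3)))
        return np.array(y, dtype=float)

    def v_per_trial(self, vs):
        if self.x_cov is not None:
            return vs[0] + vs[1] * self.x_cov
        return np.asarray(vs)[self.lev_codes]

    def estimates(self, y):
        vs, a, t, sv = self.unpack(y)
        out = {}
        if self.x_cov is not None:
            out["v_Intercept"], out["v_x"] = float(vs[0]), float(vs[1])
        elif self.levels == [None]:
            out["v"] = float(vs[0])
        else:
            for lv, v in zip(self.levels, vs):
                out[f"v({lv})"] = float(v)
        out.update(a=a, t=t)
        if self.include_sv:
            out["sv"] = sv
        return out

    def start(self, rng=None, jitter=0.0):
        acc = self.resp.mean()
        v0 = 1.0 if acc >= 0.5 else -1.0
        vs = ([v0, 0.0] if self.x_cov is not None
              else [v0] * len(self.levels))
        y = self.pack(vs, 1.5, 0.9 * self.min_rt, 0.3)
        if jitter and rng is not None:
            y = y + jitter * rng.standard_normal(y.size)
        return y


def _multistart(objective, fp, n_starts, seed):
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        y0 = fp.start(rng, jitter=0.0 if s == 0 else 0.5)
        res = minimize(objective, y0, method="Nelder-Mead",
                       options={"maxiter": 200 * fp.n, "xatol": 1e-5,
                                "fatol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_ml(trials, split_v_by=None, regress_v_on=None, include_sv=True,
           n_starts: int = 2, seed: int = 0) -> SubjectFit:
    """Maximum-likelihood DDM fit for a single subject.

    Maximizes the first-passage log-likelihood (no outlier mixture) over
    drift (per condition level, or intercept+slope on a covariate),
    threshold, non-decision time and optionally sv, using multi-start
    Nelder-Mead on unconstrained coordinates.  Data in which only one
    boundary is ever hit are flagged degenerate (the drift estimate then
    runs toward the boundary of the feasible range).
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    fp = _FreeParams(trials, split_v_by, regress_v_on, include_sv)
    degenerate = len(np.unique(fp.resp)) < 2
    if degenerate:
        logger.warning("all responses hit one boundary: ML drift estimate "
                       "is weakly identified")

    def neg_loglik(y):
        vs, a, t, sv = fp.unpack(y)
        ld = wiener_logpdf(fp.rt, fp.resp, fp.v_per_trial(vs), a, fp.z, t,
                           sv=sv, err=1e-6)
        val = float(ld.sum())
        return -val if np.isfinite(val) else 1e12

    best = _multistart(neg_loglik, fp, n_starts, seed)
    return SubjectFit(fp.estimates(best.x), -best.fun, "ml",
                      degenerate=degenerate)


# ---------------------------------------------------------------------------
# chi-square quantile method
# ---------------------------------------------------------------------------

def chi_square_statistic(observed, expected) -> float:
    """Sum of (O - E)^2 / E with a small floor on expected counts."""
    observed = np.asarray(observed, dtype=float)
    expected = np.maximum(np.asarray(expected, dtype=float), 1e-8)
    return float(np.sum((observed - expected) ** 2 / expected))


def _defective_cdf(cuts, v, a, z, t, sv, boundary, n_grid=192):
    """P(T <= cut, response = boundary) via trapezoidal integration of the
    first-passage density on a fixed grid."""
    hi = float(np.max(cuts)) * 1.02 + 1e-4
    grid = np.linspace(max(t + 1e-5, 1e-5), hi, n_grid)
    resp = np.ones_like(grid) if boundary == 1 else np.zeros_like(grid)
    dens = np.exp(wiener_logpdf(grid, resp, v, a, z, t, sv=sv, err=1e-6))
    cdf = np.concatenate([[0.0], np.cumsum(
        (dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
    return np.interp(cuts, grid, cdf)


def fit_quantile_chisq(trials, quantiles=DEFAULT_QUANTILES, split_v_by=None,
                       include_sv=True, n_starts: int = 2,
                       seed: int = 0, min_boundary_n: int = 5) -> SubjectFit:
    """Chi-square quantile fit for a single subject.

    Observed RT quantiles (default 0.1/0.3/0.5/0.7/0.9) per boundary define
    six bins whose observed counts are compared with the counts predicted
    by the model's defective RT distribution; the summed chi-square
    discrepancy is minimized over the same free parameters as the ML fit.
    A boundary with fewer than ``min_boundary_n`` observations collapses
    to a single choice-probability term.
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    fp = _FreeParams(trials, split_v_by, None, include_sv)
    qprops = np.diff([0.0, *quantiles, 1.0])  # bin proportions

    # precompute observed cuts/counts per (condition level, boundary)
    cells = []
    for lv_ix in range(len(fp.levels)):
        m = fp.lev_codes == lv_ix
        n_cond = int(m.sum())
        for b in (0, 1):
            rts = fp.rt[m & (fp.resp == b)]
            if len(rts) >= min_boundary_n:
                cuts = np.quantile(rts, quantiles)
                obs = len(rts) * qprops
            else:
                cuts, obs = None, np.array([float(len(rts))])
            cells.append((lv_ix, b, n_cond, cuts, obs))

    def objective(y):
        vs, a, t, sv = fp.unpack(y)
        if t >= fp.min_rt:
            return 1e12
        stat = 0.0
        for lv_ix, b, n_cond, cuts, obs in cells:
            v = vs[lv_ix]
            p_b = choice_prob_upper(v, a, fp.z) if b == 1 else \
                1.0 - choice_prob_upper(v, a, fp.z)
            if cuts is None:
                exp_counts = np.array([n_cond * p_b])
            else:
                cdf = _defective_cdf(cuts, v, a, fp.z, t, sv, b)
                edges = np.concatenate([[0.0], cdf, [p_b]])
                probs = np.maximum(np.diff(edges), 0.0)
                exp_counts = n_cond * probs
            stat += chi_square_statistic(obs, exp_counts)
        return stat if np.isfinite(stat) else 1e12

    best = _multistart(objective, fp, n_starts, seed)
    return SubjectFit(fp.estimates(best.x), best.fun, "quantiles")


# ---------------------------------------------------------------------------
# scoring utilities
# ---------------------------------------------------------------------------

def trimmed_mae(errors, trim: float = 0.05) -> float:
    """Mean absolute error after discarding the ceil(trim * n) largest
    absolute errors (guards against the occasional wildly misrecovered
    parameter)."""
    errors = np.abs(np.asarray(errors, dtype=float))
    if errors.size == 0:
        raise ValueError("empty error vector")
    if not 0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    k = int(np.ceil(trim * errors.size))
    if k:
        errors = np.sort(errors)[:errors.size - k]
    return float(errors.mean())


def detection_decision(fits_or_trace, method: str,
                       alpha: float = 0.05) -> bool:
    """Decide whether an effect was detected.

    method 'paired_t': input (est_a, est_b) per-subject arrays; two-sided
    paired t-test at ``alpha``.
    method 'one_sample_t': per-subject coefficient array tested against 0.
    method 'posterior_interval': posterior draws of the group difference;
    detected when the central 95% interval excludes 0.
    """
    if method == "paired_t":
        a, b = (np.asarray(x, dtype=float) for x in fits_or_trace)
        if len(a) < 2 or len(a) != len(b):
            raise ValueError("paired_t needs >= 2 paired subject estimates")
        if np.allclose(a, b):
            return False
        res = stats.ttest_rel(a, b)
        return bool(res.pvalue < alpha)
    if method == "one_sample_t":
        x = np.asarray(fits_or_trace, dtype=float)
        if len(x) < 2:
            raise ValueError("one_sample_t needs >= 2 subjects")
        if np.allclose(x, x[0]) and np.allclose(x[0], 0):
            return False
        res = stats.ttest_1samp(x, 0.0)
        return bool(res.pvalue < alpha)
    if method == "posterior_interval":
        x = np.asarray(fits_or_trace, dtype=float)
        lo, hi = np.quantile(x, [0.025, 0.975])
        return bool(lo > 0 or hi < 0)
    raise ValueError(f"unknown detection method {method!r}")


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

def _truth_map(truth_row, covariate):
    if covariate:
        return {"v_Intercept": truth_row["alpha"], "v_x": truth_row["beta"],
                "a": truth_row["a"], "t": truth_row["t"],
                "sv": truth_row["sv"]}
    out = {"v(c0)": truth_row["v1"], "a": truth_row["a"],
           "t": truth_row["t"], "sv": truth_row["sv"]}
    if "v2" in truth_row:
        out["v(c1)"] = truth_row["v2"]
    return out


def _hb_fit(data, covariate, n_samples, burn, seed):
    """Hierarchical fit with a within-subject drift effect node."""
    spec = ModelSpec(include=("sv",))
    if covariate:
        graph = build_regression_model(data, "v ~ x", spec)
        effect_node = "v_x"
    else:
        graph = build_regression_model(
            data, "v ~ C(cond, Treatment('c0'))", spec)
        effect_node = "v_C(cond, Treatment('c0'))[T.c1]"
    infer.find_starting_values(graph, n_passes=2)
    trace = infer.sample(graph, n_samples=n_samples, burn=burn, seed=seed)
    return graph, trace, effect_node


def _hb_subject_estimates(graph, trace, covariate, subj_ix):
    est = {}
    if covariate:
        b0 = np.mean(trace[f"v_Intercept_subj.{subj_ix}"])
        b1 = np.mean(trace[f"v_x_subj.{subj_ix}"])
        est["v_Intercept"], est["v_x"] = float(b0), float(b1)
    else:
        b0 = np.mean(trace[f"v_Intercept_subj.{subj_ix}"])
        b1 = np.mean(
            trace[f"v_C(cond, Treatment('c0'))[T.c1]_subj.{subj_ix}"])
        est["v(c0)"], est["v(c1)"] = float(b0), float(b0 + b1)
    est["a"] = float(np.mean(trace[f"a_subj.{subj_ix}"]))
    est["t"] = float(np.mean(trace[f"t_subj.{subj_ix}"]))
    est["sv"] = float(np.mean(trace["sv"]))
    return est


def _nhb_fit_subject(sub_df, covariate, n_samples, burn, seed):
    spec = ModelSpec(include=("sv",), is_group_model=False)
    if covariate:
        graph = build_regression_model(sub_df, "v ~ x", spec)
    else:
        spec.depends_on = {"v": "cond"}
        graph = build_model(sub_df, spec)
    infer.find_starting_values(graph, n_passes=2)
    trace = infer.sample(graph, n_samples=n_samples, burn=burn, seed=seed)
    return {n: float(np.mean(trace[n])) for n in trace.node_names}


def run_recovery(designs, methods=("hb", "nhb", "ml", "quantiles"),
                 n_datasets: int = 5, seed: int = 0,
                 n_samples: int = 800, burn: int = 200,
                 nhb_samples: int = 500, nhb_burn: int = 100,
                 progress: bool = False) -> RecoveryResult:
    """Run a recovery/detection experiment over a grid of designs.

    For every design cell, ``n_datasets`` datasets are simulated; each
    requested method is fitted (the hierarchical model once per dataset
    with a within-subject drift-effect node; the others per subject) and
    per-parameter absolute errors plus a detection flag are recorded.
    Method failures are logged and recorded as missing, not fatal.
    """
    err_rows, det_rows = [], []
    for cell_ix, design in enumerate(designs):
        covariate = design.effect_size is not None
        for d in range(n_datasets):
            ds_seed = (seed * 100003 + cell_ix * 1009 + d * 13) % (2**31)
            dsn = ExperimentDesign(**{**design.__dict__, "seed": ds_seed})
            data, truth = (generate_covariate_dataset(dsn) if covariate
                           else sample_group_dataset(dsn))
            cell = {"cell": cell_ix, "n_subjects": dsn.n_subjects,
                    "n_trials": dsn.n_trials, "dataset": d, "seed": ds_seed,
                    "effect_size": dsn.effect_size,
                    "drift_rule": dsn.drift_rule if not covariate else None}
            if progress:
                print(f"cell {cell_ix} dataset {d} "
                      f"({dsn.n_subjects} subj x {dsn.n_trials} trials)")
            for method in methods:
                try:
                    subj_est, detected = _run_method(
                        method, data, truth, covariate, ds_seed,
                        n_samples, burn, nhb_samples, nhb_burn)
                except Exception:
                    logger.exception("method %s failed on cell %d dataset "
                                     "%d", method, cell_ix, d)
                    det_rows.append({**cell, "method": method,
                                     "detected": None})
                    continue
                for i, est in subj_est.items():
                    tr = _truth_map(truth.iloc[i], covariate)
                    for p, true_val in tr.items():
                        if p in est:
                            err_rows.append({
                                **cell, "method": method, "subj_idx": i,
                                "parameter": p, "estimate": est[p],
                                "truth": true_val,
                                "abs_error": abs(est[p] - true_val)})
                det_rows.append({**cell, "method": method,
                                 "detected": detected})
    return RecoveryResult(pd.DataFrame(err_rows), pd.DataFrame(det_rows))


def _run_method(method, data, truth, covariate, seed,
                n_samples, burn, nhb_samples, nhb_burn):
    n_subj = truth.shape[0]
    subj_est: dict[int, dict] = {}
    if method == "hb":
        graph, trace, effect_node = _hb_fit(
            data, covariate, n_samples, burn, seed)
        for i in range(n_subj):
            subj_est[i] = _hb_subject_estimates(graph, trace, covariate, i)
        detected = detection_decision(trace[effect_node],
                                      "posterior_interval")
        return subj_est, detected
    if method == "nhb":
        for i in range(n_subj):
            sub = data[data.subj_idx == i]
            est = _nhb_fit_subject(sub, covariate, nhb_samples, nhb_burn,
                                   seed + 17 * i + 1)
            subj_est[i] = est
        detected = _point_detection(subj_est, covariate)
        return subj_est, detected
    if method in ("ml", "quantiles"):
        if covariate and method == "quantiles":
            raise ValueError("the quantile method cannot estimate "
                             "trial-by-trial effects")
        for i in range(n_subj):
            sub = data[data.subj_idx == i]
            if method == "ml":
                fit = fit_ml(sub, regress_v_on="x" if covariate else None,
                             split_v_by=None if covariate else "cond",
                             seed=seed + i)
            else:
                fit = fit_quantile_chisq(sub, split_v_by="cond",
                                         seed=seed + i)
            subj_est[i] = fit.estimates
        detected = _point_detection(subj_est, covariate)
        return subj_est, detected
    raise ValueError(f"unknown method {method!r}")


def _point_detection(subj_est, covariate):
    if covariate:
        coefs = [e["v_x"] for e in subj_est.values()]
        return detection_decision(coefs, "one_sample_t")
    v1 = [e["v(c0)"] for e in subj_est.values()]
    v2 = [e["v(c1)"] for e in subj_est.values()]
    return detection_decision((v2, v1), "paired_t")
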