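"""Hierarchical model graphs for the DDM.

The hierarchy follows the standard group/subject layout: for each estimated
DDM parameter there is a group mean node and a group spread node, and one
subject node per subject (and per condition level when the parameter is
split by condition).  Subject parameters are modelled as draws around the
group mean with the group spread as SD; the bias ``z`` lives on a logit
scale at the group level so the (0, 1) domain is respected.  The inter-trial
variabilities ``sv``, ``st``, ``sz`` are estimated at the group level only —
their influence on single-subject likelihoods is too weak to support
individual estimates.

Regression models replace a DDM parameter with a trial-level linear model:
``"a ~ theta:C(conf, Treatment('LC'))"`` makes the threshold of trial j equal
to the design row of that trial times a subject-specific coefficient vector;
coefficients receive the same group-mean/group-spread hierarchical treatment
as ordinary parameters.  Design matrices and coefficient naming use the
patsy formula language (treatment-coded categoricals).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy.special import betaln, expit, gammaln, log_ndtr, logit

_LOG2PI = float(np.log(2.0 * np.pi))

from .likelihood import DEFAULT_CONFIG, LikelihoodConfig, wiener_logpdf, _simpson_nodes

__all__ = [
    "PriorSpec",
    "GroupDistribution",
    "ModelSpec",
    "ModelGraph",
    "build_model",
    "build_regression_model",
    "prior_logpdf",
    "default_priors",
]


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """A prior family with its hyperparameters.

    Families: ``normal(mean, sd)``, ``halfnormal(sd)``, ``gamma(mean, rate)``
    (note: mean/rate, not shape/rate — shape = mean * rate), and
    ``beta(alpha, beta)``.
    """

    family: str
    params: tuple

    def __post_init__(self):
        fam = self.family
        p = self.params
        if fam == "normal":
            if len(p) != 2 or p[1] <= 0:
                raise ValueError("normal prior needs (mean, sd>0)")
        elif fam == "halfnormal":
            if len(p) != 1 or p[0] <= 0:
                raise ValueError("halfnormal prior needs (sd>0,)")
        elif fam == "gamma":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValueError("gamma prior needs (mean>0, rate>0)")
        elif fam == "beta":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValueError("beta prior needs (alpha>0, beta>0)")
        else:
            raise ValueError(f"unknown prior family {fam!r}")

    def logpdf(self, value):
        value = np.asarray(value, dtype=float)
        fam, p = self.family, self.params
        with np.errstate(divide="ignore", invalid="ignore"):
            if fam == "normal":
                out = (-0.5 * ((value - p[0]) / p[1]) ** 2
                       - np.log(p[1]) - 0.5 * _LOG2PI)
            elif fam == "halfnormal":
                out = np.where(
                    value >= 0,
                    -0.5 * (value / p[0]) ** 2 - np.log(p[0])
                    - 0.5 * _LOG2PI + np.log(2.0),
                    -np.inf)
            elif fam == "gamma":
                shape = p[0] * p[1]
                out = np.where(
                    value > 0,
                    shape * np.log(p[1]) - gammaln(shape)
                    + (shape - 1) * np.log(np.maximum(value, 1e-300))
                    - p[1] * value,
                    -np.inf)
            elif fam == "beta":
                inside = (value > 0) & (value < 1)
                val = np.where(inside, value, 0.5)
                out = np.where(
                    inside,
                    (p[0] - 1) * np.log(val) + (p[1] - 1) * np.log1p(-val)
                    - betaln(p[0], p[1]),
                    -np.inf)
        return np.where(np.isnan(out), -np.inf, out)

    def mean(self) -> float:
        fam, p = self.family, self.params
        if fam == "normal":
            return p[0]
        if fam == "halfnormal":
            return p[0] * float(np.sqrt(2.0 / np.pi))
        if fam == "gamma":
            return p[0]
        return p[0] / (p[0] + p[1])


def prior_logpdf(node_or_spec, value):
    """Exact log-density of a node's declared prior family (-inf outside
    the support)."""
    spec = node_or_spec.prior if hasattr(node_or_spec, "prior") else node_or_spec
    out = spec.logpdf(value)
    return float(out) if np.ndim(out) == 0 else out


def default_priors(informative: bool = True) -> dict[str, PriorSpec]:
    """Hyperpriors per group node.

    The informative set keeps parameters in the plausible range reported in
    the fitting literature (drift of a few units, thresholds near 1-2.5,
    non-decision time a few hundred ms); the exact constants here are this
    package's defaults and can be overridden per node via
    ``ModelSpec.prior_overrides``.
    """
    if informative:
        return {
            "v": PriorSpec("normal", (2.0, 3.0)),
            "v_std": PriorSpec("halfnormal", (2.0,)),
            "a": PriorSpec("gamma", (1.5, 1.0)),
            "a_std": PriorSpec("halfnormal", (1.0,)),
            "t": PriorSpec("gamma", (0.4, 2.0)),
            "t_std": PriorSpec("halfnormal", (0.3,)),
            "z": PriorSpec("beta", (10.0, 10.0)),
            "z_std": PriorSpec("halfnormal", (0.5,)),
            "sv": PriorSpec("halfnormal", (2.0,)),
            "st": PriorSpec("halfnormal", (0.3,)),
            "sz": PriorSpec("beta", (1.0, 3.0)),
            "slope": PriorSpec("normal", (0.0, 3.0)),
            "slope_std": PriorSpec("halfnormal", (1.0,)),
        }
    return {
        "v": PriorSpec("normal", (0.0, 10.0)),
        "v_std": PriorSpec("halfnormal", (10.0,)),
        "a": PriorSpec("halfnormal", (10.0,)),
        "a_std": PriorSpec("halfnormal", (10.0,)),
        "t": PriorSpec("halfnormal", (5.0,)),
        "t_std": PriorSpec("halfnormal", (10.0,)),
        "z": PriorSpec("beta", (1.0, 1.0)),
        "z_std": PriorSpec("halfnormal", (10.0,)),
        "sv": PriorSpec("halfnormal", (10.0,)),
        "st": PriorSpec("halfnormal", (1.0,)),
        "sz": PriorSpec("beta", (1.0, 1.0)),
        "slope": PriorSpec("normal", (0.0, 10.0)),
        "slope_std": PriorSpec("halfnormal", (10.0,)),
    }


# ---------------------------------------------------------------------------
# transforms (sampling happens on the unconstrained scale)
# ---------------------------------------------------------------------------

class Transform:
    """Bijection between the natural parameter scale and the sampling scale.

    ``logjac(y)`` is log|dx/dy| so that a density in x becomes a density in
    y by adding it.
    """

    name = "identity"

    def forward(self, x):  # natural -> sampling
        return np.asarray(x, dtype=float)

    def inverse(self, y):
        return np.asarray(y, dtype=float)

    def logjac(self, y):
        return np.zeros_like(np.asarray(y, dtype=float))


class LogTransform(Transform):
    name = "log"

    def forward(self, x):
        return np.log(np.asarray(x, dtype=float))

    def inverse(self, y):
        return np.exp(np.asarray(y, dtype=float))

    def logjac(self, y):
        return np.asarray(y, dtype=float)


class LogitTransform(Transform):
    name = "logit"

    def forward(self, x):
        return logit(np.asarray(x, dtype=float))

    def inverse(self, y):
        return expit(np.asarray(y, dtype=float))

    def logjac(self, y):
        y = np.asarray(y, dtype=float)
        return -np.abs(y) - 2.0 * np.log1p(np.exp(-np.abs(y)))


IDENTITY, LOG, LOGIT = Transform(), LogTransform(), LogitTransform()

#: sampling-scale transform per DDM parameter (natural-scale nodes)
PARAM_TRANSFORM = {"v": IDENTITY, "a": LOG, "t": LOG, "z": LOGIT,
                   "sv": LOG, "st": LOG, "sz": LOGIT}
PARAM_DOMAIN_POSITIVE = {"a", "t", "sv", "st"}


# ---------------------------------------------------------------------------
# graph nodes and blocks
# ---------------------------------------------------------------------------

@dataclass
class GroupDistribution:
    """Group-level law of one parameter (per condition level): mean node,
    spread node, and the link on which subjects scatter around the mean."""

    param: str
    level: str | None
    mean_node: str
    std_node: str
    link: str = "identity"  # 'logit' for z


def _subject_prior_logpdf(param: str, value, mu, sigma):
    """Log-density (in the natural-scale value) of one subject parameter
    given its group mean and spread.

    v and regression coefficients: Normal(mu, sigma).
    a, t: Normal truncated to (0, inf), renormalized.
    z: logit-normal — Normal(logit value; logit mu, sigma) with Jacobian.
    """
    value = np.asarray(value, dtype=float)
    if param == "z":
        ok = (value > 0) & (value < 1) & (0 < mu < 1)
        val = np.where(ok, value, 0.5)
        mu_l = logit(np.clip(mu, 1e-9, 1 - 1e-9))
        lp = (-0.5 * ((logit(val) - mu_l) / sigma) ** 2 - np.log(sigma)
              - 0.5 * _LOG2PI - np.log(val * (1.0 - val)))
        return np.where(ok, lp, -np.inf)
    lp = -0.5 * ((value - mu) / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG2PI
    if param in PARAM_DOMAIN_POSITIVE:
        # renormalize the normal truncated to (0, inf)
        lp = lp - log_ndtr(mu / sigma)
        lp = np.where(value > 0, lp, -np.inf)
    return lp


class Block:
    """A set of conditionally independent scalar nodes updated together.

    ``conditional_logp(x)`` returns, for each component i, the log of the
    full conditional of node i evaluated at x[i] given the *current* state
    of every other node (terms constant in x[i] may be dropped).  Components
    must be conditionally independent of one another for the vectorized
    slice update to be valid; scalar nodes simply use length-1 blocks.
    """

    def __init__(self, names, values, transform, width=1.0):
        self.names = list(names)
        self.values = np.asarray(values, dtype=float).copy()
        self.transform = transform
        self.width = width

    def conditional_logp(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def on_commit(self) -> None:
        """Called after new values are committed (cache refresh hook)."""


class _GroupMeanBlock(Block):
    def __init__(self, graph, fam, level_ix, name, prior, transform):
        self.graph, self.fam, self.level_ix = graph, fam, level_ix
        self.prior = prior
        super().__init__([name], [prior.mean()], transform)

    def conditional_logp(self, x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        fam = self.fam
        lp = np.atleast_1d(self.prior.logpdf(x)).astype(float)
        subj = fam.subj_values[:, self.level_ix]
        sigma = fam.group_stds[self.level_ix]
        out = np.empty_like(x)
        for i, mu in enumerate(x):
            out[i] = lp[i]
            if np.isfinite(out[i]):
                out[i] += _subject_prior_logpdf(
                    fam.base_param, subj, mu, sigma).sum()
        return out

    def on_commit(self):
        self.fam.group_means[self.level_ix] = self.values[0]


class _GroupStdBlock(Block):
    def __init__(self, graph, fam, level_ix, name, prior):
        self.graph, self.fam, self.level_ix = graph, fam, level_ix
        self.prior = prior
        super().__init__([name], [max(prior.mean(), 0.1)], LOG, width=0.5)

    def conditional_logp(self, x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        fam = self.fam
        lp = np.atleast_1d(self.prior.logpdf(x)).astype(float)
        subj = fam.subj_values[:, self.level_ix]
        mu = fam.group_means[self.level_ix]
        out = np.empty_like(x)
        for i, sig in enumerate(x):
            if sig <= 0 or not np.isfinite(lp[i]):
                out[i] = -np.inf
                continue
            out[i] = lp[i] + _subject_prior_logpdf(
                fam.base_param, subj, mu, sig).sum()
        return out

    def on_commit(self):
        self.fam.group_stds[self.level_ix] = self.values[0]


class _SubjectBlock(Block):
    """Subject nodes of one (parameter, condition level): conditionally
    independent across subjects given the group nodes."""

    def __init__(self, graph, fam, level_ix, names, init):
        self.graph, self.fam, self.level_ix = graph, fam, level_ix
        transform = PARAM_TRANSFORM.get(fam.base_param, IDENTITY) \
            if fam.kind == "basic" else IDENTITY
        super().__init__(names, init, transform, width=0.5)

    def conditional_logp(self, x):
        x = np.asarray(x, dtype=float)
        fam, g = self.fam, self.graph
        if fam.hierarchical:
            mu = fam.group_means[self.level_ix]
            sigma = fam.group_stds[self.level_ix]
            lp = _subject_prior_logpdf(fam.base_param, x, mu, sigma)
        else:
            lp = fam.fixed_prior.logpdf(x)
        lp = np.atleast_1d(np.asarray(lp, dtype=float)).copy()
        mask = fam.trial_mask(self.level_ix)
        override = fam.trial_values_for(self.level_ix, x, mask)
        ld = g._trial_logdens({fam.base_param: override}, mask)
        sub = g.subj_codes[mask]
        # -inf * 0 pitfalls: bincount handles -inf weights by summation
        lp += np.bincount(sub, weights=ld, minlength=g.n_subjects)
        return lp

    def on_commit(self):
        self.fam.subj_values[:, self.level_ix] = self.values
        self.graph._refresh(self.fam.base_param)


class _GroupOnlyBlock(Block):
    """A single group-level node whose value enters every trial's
    likelihood directly (inter-trial variabilities sv, st, sz)."""

    def __init__(self, graph, param, prior):
        self.graph, self.param, self.prior = graph, param, prior
        init = max(prior.mean(), 0.05)
        if param == "sz":
            init = min(init, 0.2)
        super().__init__([param], [init], PARAM_TRANSFORM[param], width=0.3)

    def conditional_logp(self, x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        g = self.graph
        out = np.atleast_1d(self.prior.logpdf(x)).astype(float).copy()
        for i, val in enumerate(x):
            if np.isfinite(out[i]):
                out[i] += g._trial_logdens({self.param: float(val)}).sum()
        return out

    def on_commit(self):
        self.graph.group_only_values[self.param] = self.values[0]


# ---------------------------------------------------------------------------
# parameter families
# ---------------------------------------------------------------------------

class _ParamFamily:
    """All nodes belonging to one DDM parameter, or to one regression
    coefficient column treated as a pseudo-parameter.

    kind 'basic': the parameter itself, optionally split by condition level.
    kind 'coef':  one column of a regression design matrix; the trial-level
    parameter is assembled by the owning :class:`_Regression`.
    """

    def __init__(self, param, base_param, kind, levels, n_subjects,
                 hierarchical, fixed_prior=None, regression=None, col_ix=None):
        self.param = param            # node-name stem, e.g. "v" or "a_Intercept"
        self.base_param = base_param  # underlying DDM parameter for priors/likelihood
        self.kind = kind
        self.levels = levels          # list of level labels or [None]
        self.hierarchical = hierarchical
        self.fixed_prior = fixed_prior
        self.regression = regression
        self.col_ix = col_ix
        self.graph = None
        self.group_means = np.zeros(len(levels))
        self.group_stds = np.full(len(levels), 0.2)
        self.subj_values = np.zeros((n_subjects, len(levels)))
        self.lev_codes = None  # per-trial level index for split basic params

    def trial_mask(self, level_ix):
        if self.kind == "coef" or self.lev_codes is None:
            return slice(None)
        return self.lev_codes == level_ix

    def trial_values_for(self, level_ix, subj_vals, mask):
        """Per-trial values of the underlying DDM parameter on ``mask`` when
        this family's subject values at ``level_ix`` are replaced by
        ``subj_vals``."""
        g = self.graph
        sub = g.subj_codes[mask] if isinstance(mask, np.ndarray) \
            else g.subj_codes
        if self.kind == "basic":
            return np.asarray(subj_vals, dtype=float)[sub]
        return self.regression.trial_values(override_col=self.col_ix,
                                            override_vals=subj_vals)


class _Regression:
    """Trial-level linear model for one DDM parameter."""

    def __init__(self, param, formula, X, coef_names, graph):
        self.param = param
        self.formula = formula
        self.X = X                    # (n_trials, K)
        self.coef_names = coef_names  # prefixed, e.g. 'a_Intercept'
        self.families: list[_ParamFamily] = []
        self.graph = graph

    def coef_matrix(self):
        return np.column_stack([f.subj_values[:, 0] for f in self.families])

    def trial_values(self, override_col=None, override_vals=None):
        B = self.coef_matrix()  # (S, K)
        sub = self.graph.subj_codes
        vals = np.einsum("jk,jk->j", self.X, B[sub])
        if override_col is not None:
            col = self.X[:, override_col]
            vals = vals + col * (np.asarray(override_vals, dtype=float)[sub]
                                 - B[sub, override_col])
        return vals


# ---------------------------------------------------------------------------
# model specification and graph
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """What to estimate and how.

    ``depends_on`` maps a parameter to a condition column; separate group
    distributions are created per level.  ``include`` adds optional
    parameters from {"sv", "st", "sz", "z"}.  ``regressions`` is a list of
    linear-model descriptor strings like ``"v ~ x"``.  ``p_outlier`` is a
    fixed mixture weight of the likelihood config, not a sampled node.
    """

    depends_on: dict = field(default_factory=dict)
    include: tuple = ()
    informative_priors: bool = True
    is_group_model: bool | None = None
    regressions: list = field(default_factory=list)
    p_outlier: float = 0.0
    prior_overrides: dict = field(default_factory=dict)
    config: LikelihoodConfig = field(default_factory=lambda: DEFAULT_CONFIG)

    def __post_init__(self):
        bad = set(self.include) - {"sv", "st", "sz", "z"}
        if bad:
            raise ValueError(f"include must be a subset of sv/st/sz/z, got {bad}")
        if self.p_outlier:
            self.config = replace(self.config, p_outlier=self.p_outlier)


class ModelGraph:
    """The assembled hierarchical node graph bound to one dataset.

    Holds the trial data as arrays, a list of sampling blocks (scalar group
    nodes and vectorized subject blocks), and the machinery to evaluate the
    joint log-posterior and the data log-likelihood at the current state.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        self.config = spec.config
        missing = {"rt", "response"} - set(data.columns)
        if missing:
            raise ValueError(f"data is missing required column(s): "
                             f"{sorted(missing)}")
        if len(data) == 0:
            raise ValueError("empty dataset")
        data = data.reset_index(drop=True)
        self.data = data
        self.rt = data["rt"].to_numpy(dtype=float)
        self.resp = data["response"].to_numpy(dtype=int)
        if (self.rt <= 0).any():
            raise ValueError("all response times must be > 0")
        if not np.isin(self.resp, [0, 1]).all():
            raise ValueError("response must be binary 0/1")

        if "subj_idx" in data.columns:
            self.subj_labels, self.subj_codes = np.unique(
                data["subj_idx"].to_numpy(), return_inverse=True)
        else:
            self.subj_labels = np.array([0])
            self.subj_codes = np.zeros(len(data), dtype=int)
        self.n_subjects = len(self.subj_labels)
        self.is_group = spec.is_group_model
        if self.is_group is None:
            self.is_group = self.n_subjects > 1

        self.priors = default_priors(spec.informative_priors)
        self.families: dict[str, _ParamFamily] = {}
        self.regressions: dict[str, _Regression] = {}
        self.group_only_values: dict[str, float] = {
            "sv": 0.0, "st": 0.0, "sz": 0.0}
        self.group_distributions: list[GroupDistribution] = []
        self.blocks: list[Block] = []
        self._trial_cache: dict[str, np.ndarray] = {}

        self._build()
        for p in ("v", "a", "z", "t"):
            self._refresh(p)

    # -- construction ----------------------------------------------------
    def _prior_for(self, key, fallback):
        if key in self.spec.prior_overrides:
            return self.spec.prior_overrides[key]
        return self.priors[fallback]

    def _build(self):
        spec = self.spec
        regressed = set()
        for formula in spec.regressions:
            regressed.add(self._add_regression(formula))
        base_params = ["v", "a", "t"] + (["z"] if "z" in spec.include else [])
        for p in base_params:
            if p not in regressed:
                self._add_basic_param(p)
        for p in ("sv", "st", "sz"):
            if p in spec.include:
                blk = _GroupOnlyBlock(self, p, self._prior_for(p, p))
                self.blocks.append(blk)
                blk.on_commit()

    def _levels_for(self, p):
        col = self.spec.depends_on.get(p)
        if col is None:
            return [None], None
        if col not in self.data.columns:
            raise ValueError(f"depends_on[{p!r}] names a missing column "
                             f"{col!r}")
        labels = self.data[col].astype(str).to_numpy()
        levels = sorted(set(labels))
        codes = np.searchsorted(np.array(levels), labels)
        return levels, codes

    def _node_name(self, p, level, suffix="", subj=None):
        stem = p if level is None else f"{p}({level})"
        if subj is not None:
            return f"{stem}_subj.{subj}"
        return stem + suffix

    def _t_init(self):
        return max(0.5 * float(self.rt.min()), 1e-3)

    def _add_basic_param(self, p):
        levels, codes = self._levels_for(p)
        fam = _ParamFamily(p, p, "basic", levels, self.n_subjects,
                           hierarchical=self.is_group,
                           fixed_prior=self._prior_for(p, p))
        fam.graph = self
        fam.lev_codes = codes
        self.families[p] = fam
        init = {"v": 1.0, "a": 1.5, "t": self._t_init(), "z": 0.5}[p]
        init_std = {"v": 0.3, "a": 0.3, "t": 0.1, "z": 0.3}[p]
        fam.group_means[:] = init
        fam.group_stds[:] = init_std
        fam.subj_values[:, :] = init
        for ix, lv in enumerate(levels):
            if self.is_group:
                mean_name = self._node_name(p, lv)
                std_name = self._node_name(p, lv, "_std")
                mb = _GroupMeanBlock(self, fam, ix, mean_name,
                                     self._prior_for(mean_name, p),
                                     PARAM_TRANSFORM[p])
                mb.values[0] = init
                sb = _GroupStdBlock(self, fam, ix, std_name,
                                    self._prior_for(std_name, f"{p}_std"))
                sb.values[0] = init_std
                self.blocks += [mb, sb]
                mb.on_commit()
                sb.on_commit()
                self.group_distributions.append(GroupDistribution(
                    p, lv, mean_name, std_name,
                    link="logit" if p == "z" else "identity"))
                names = [self._node_name(p, lv, subj=i)
                         for i in range(self.n_subjects)]
            else:
                names = ([self._node_name(p, lv)] if self.n_subjects == 1
                         else [self._node_name(p, lv, subj=i)
                               for i in range(self.n_subjects)])
            blk = _SubjectBlock(self, fam, ix, names,
                                np.full(self.n_subjects, init))
            self.blocks.append(blk)
            blk.on_commit()

    def _add_regression(self, formula):
        if "~" not in formula:
            raise ValueError(f"formula {formula!r} lacks '~'")
        outcome, rhs = (s.strip() for s in formula.split("~", 1))
        if outcome not in ("v", "a", "t", "z"):
            raise ValueError(f"unknown outcome parameter {outcome!r}")
        dm = dmatrix(rhs, self.data, return_type="dataframe")
        X = dm.to_numpy(dtype=float)
        cols = list(dm.columns)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient design for {formula!r}; "
                             f"columns: {cols}")
        coef_names = [f"{outcome}_{c}" for c in cols]
        print("Adding these covariates:")
        print(coef_names)
        reg = _Regression(outcome, formula, X, coef_names, self)
        self.regressions[outcome] = reg
        plan = []
        for k, cname in enumerate(coef_names):
            if cols[k] == "Intercept":
                mean_prior = self._prior_for(cname, outcome)
                std_prior = self._prior_for(f"{cname}_std", f"{outcome}_std")
                init = {"v": 1.0, "a": 1.5, "t": self._t_init(),
                        "z": 0.5}[outcome]
            else:
                mean_prior = self._prior_for(cname, "slope")
                std_prior = self._prior_for(f"{cname}_std", "slope_std")
                init = 0.0
            fam = _ParamFamily(cname, outcome, "coef", [None],
                               self.n_subjects, hierarchical=self.is_group,
                               fixed_prior=mean_prior, regression=reg,
                               col_ix=k)
            fam.graph = self
            fam.group_means[:] = init
            fam.group_stds[:] = 0.2
            fam.subj_values[:, :] = init
            self.families[cname] = fam
            reg.families.append(fam)
            plan.append((cname, fam, mean_prior, std_prior, init))
        # blocks are created only after every coefficient family exists,
        # since committing any of them rebuilds the full trial-level values
        for cname, fam, mean_prior, std_prior, init in plan:
            if self.is_group:
                mb = _GroupMeanBlock(self, fam, 0, cname, mean_prior,
                                     IDENTITY)
                mb.values[0] = init
                sb = _GroupStdBlock(self, fam, 0, f"{cname}_std", std_prior)
                self.blocks += [mb, sb]
                mb.on_commit()
                sb.on_commit()
                self.group_distributions.append(
                    GroupDistribution(cname, None, cname, f"{cname}_std"))
                names = [f"{cname}_subj.{i}" for i in range(self.n_subjects)]
            else:
                names = ([cname] if self.n_subjects == 1
                         else [f"{cname}_subj.{i}"
                               for i in range(self.n_subjects)])
            blk = _SubjectBlock(self, fam, 0, names,
                                np.full(self.n_subjects, init))
            self.blocks.append(blk)
            blk.on_commit()
        return outcome

    # -- state access ----------------------------------------------------
    @property
    def free_names(self):
        return [n for b in self.blocks for n in b.names]

    def get_state(self) -> dict[str, float]:
        return {n: float(b.values[i])
                for b in self.blocks for i, n in enumerate(b.names)}

    def set_state(self, state: dict[str, float]) -> None:
        for b in self.blocks:
            for i, n in enumerate(b.names):
                if n in state:
                    b.values[i] = state[n]
            b.on_commit()

    # -- trial-level evaluation ------------------------------------------
    def _refresh(self, param):
        """Recompute the cached per-trial array of one DDM parameter."""
        if param in self.regressions:
            self._trial_cache[param] = self.regressions[param].trial_values()
        elif param in self.families:
            fam = self.families[param]
            if fam.lev_codes is None:
                self._trial_cache[param] = fam.subj_values[self.subj_codes, 0]
            else:
                self._trial_cache[param] = fam.subj_values[
                    self.subj_codes, fam.lev_codes]
        else:
            default = {"v": 0.0, "a": 1.0, "z": 0.5, "t": 0.0}[param]
            self._trial_cache[param] = np.full(len(self.rt), default)

    def _trial_logdens(self, overrides=None, mask=slice(None)):
        """Per-trial log mixture density with optional per-parameter
        overrides, restricted to ``mask`` (boolean array or slice).  An
        override that is a full-length per-trial array is masked; shorter
        arrays are assumed to be already restricted."""
        overrides = overrides or {}
        rt = self.rt[mask]
        resp = self.resp[mask]
        vals = {}
        for p in ("v", "a", "z", "t"):
            arr = overrides.get(p, None)
            if arr is None:
                arr = self._trial_cache[p][mask]
            elif np.ndim(arr) and np.shape(arr) == self.rt.shape \
                    and isinstance(mask, np.ndarray):
                arr = arr[mask]
            vals[p] = np.asarray(arr, dtype=float)
        sv = float(overrides.get("sv", self.group_only_values["sv"]))
        st = float(overrides.get("st", self.group_only_values["st"]))
        sz = float(overrides.get("sz", self.group_only_values["sz"]))
        cfg = self.config

        bad = ~(np.isfinite(vals["a"]) & (vals["a"] > 0)
                & (vals["z"] > 0) & (vals["z"] < 1) & (vals["t"] >= 0))
        if st > 0:
            bad = bad | (vals["t"] - st / 2 < 0)
        if sz > 0:
            bad = bad | (vals["z"] - sz / 2 <= 0) | (vals["z"] + sz / 2 >= 1)
        bad = np.broadcast_to(bad, rt.shape)
        if bad.all():
            return np.full(rt.shape, -np.inf)
        # replace invalid entries by harmless values; they get -inf below
        safe = {}
        for p, dflt in (("v", 0.0), ("a", 1.0), ("z", 0.5), ("t", 0.0)):
            arr = np.broadcast_to(vals[p], rt.shape).copy()
            arr[bad] = dflt
            safe[p] = arr

        if st == 0 and sz == 0:
            ld = wiener_logpdf(rt, resp, safe["v"], safe["a"], safe["z"],
                               safe["t"], sv=sv, err=cfg.series_tolerance,
                               p_outlier=cfg.p_outlier, max_rt=cfg.max_rt)
        else:
            t_off, t_w = _simpson_nodes(0.0, st, cfg.n_quad_st)
            z_off, z_w = _simpson_nodes(0.0, sz, cfg.n_quad_sz)
            dens = np.zeros(rt.shape)
            for to, tw in zip(t_off, t_w):
                for zo, zw in zip(z_off, z_w):
                    dens += tw * zw * np.exp(wiener_logpdf(
                        rt, resp, safe["v"], safe["a"], safe["z"] + zo,
                        safe["t"] + to, sv=sv, err=cfg.series_tolerance))
            if cfg.p_outlier > 0:
                dens = (1 - cfg.p_outlier) * dens \
                    + cfg.p_outlier / (2 * cfg.max_rt) * (rt <= cfg.max_rt)
            with np.errstate(divide="ignore"):
                ld = np.log(dens)
        return np.where(bad, -np.inf, ld)

    # -- joint quantities -------------------------------------------------
    def loglik(self) -> float:
        """Data log-likelihood at the current state (all trials)."""
        return float(self._trial_logdens().sum())

    def logp(self) -> float:
        """Joint log-posterior (up to a constant) at the current state: the
        data log-likelihood plus every free node's prior term."""
        total = self.loglik()
        if not np.isfinite(total):
            return -np.inf
        for b in self.blocks:
            if isinstance(b, _SubjectBlock):
                fam = b.fam
                if fam.hierarchical:
                    lp = _subject_prior_logpdf(
                        fam.base_param, b.values,
                        fam.group_means[b.level_ix],
                        fam.group_stds[b.level_ix])
                else:
                    lp = fam.fixed_prior.logpdf(b.values)
                total += float(np.sum(lp))
            else:
                total += float(np.sum(b.prior.logpdf(b.values)))
        return total

    @property
    def regression_coef_names(self):
        return [n for reg in self.regressions.values()
                for n in reg.coef_names]


def build_model(data: pd.DataFrame, spec: ModelSpec | None = None) -> ModelGraph:
    """Construct the hierarchical DDM graph for a trial table.

    One group mean + group spread per (estimated parameter x condition
    level), one subject node per (subject x level), group-only nodes for
    the included inter-trial variabilities.  With ``is_group_model=False``
    (or a single subject) the subject nodes receive the group-mean priors
    directly and no group nodes are created.
    """
    return ModelGraph(data, spec or ModelSpec())


def build_regression_model(data: pd.DataFrame, formula: str,
                           spec: ModelSpec | None = None) -> ModelGraph:
    """Construct a graph in which one DDM parameter varies per trial
    according to a linear-model descriptor string (patsy dialect, e.g.
    ``"a ~ theta:C(conf, Treatment('LC'))"``)."""
    spec = replace(spec) if spec is not None else ModelSpec()
    if formula not in spec.regressions:
        spec.regressions = list(spec.regressions) + [formula]
    return ModelGraph(data, spec)
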