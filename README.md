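# ddmbayes

Hierarchical Bayesian estimation of the drift-diffusion model (DDM) from
trial-by-trial choice and response-time data.

The DDM describes two-choice decisions as noisy evidence accumulation
between two absorbing boundaries: drift rate *v* (evidence per second),
boundary separation *a*, relative starting point *z* ∈ (0, 1), and
non-decision time *t*, optionally extended with inter-trial variabilities
*sv*, *st*, *sz* (the "full DDM"). The likelihood of a response time and
choice is the Wiener first-passage-time density

f(x | v, a, z) = (π/a²) · exp(−v a z − v² x / 2) · Σ_{k≥1} k · exp(−k²π²x / (2a²)) · sin(kπz),

evaluated by switching between its large-time and small-time series
expansions so the truncation error stays below a configurable bound.

Cognitive and clinical studies rarely have the hundreds of trials per
subject that single-subject fitting needs. `ddmbayes` therefore estimates
all subjects jointly in a hierarchical model — subject parameters drawn
from group-level distributions, x_ij ~ F(a_i, z_i, v_i, t_i, sv, st, sz) —
by MCMC (component-wise slice sampling), which both pools statistical
strength across subjects and yields full posterior uncertainty. Trial-level
measurements (EEG power, BOLD amplitude, ...) can drive any DDM parameter
through a patsy-style linear-model descriptor. Built-in comparison
estimators (maximum likelihood and the χ²-quantile method) and a
simulation-study driver reproduce the classical result that hierarchical
estimation recovers parameters better, and detects effects more often, when
trials are scarce.

## Worked example

Simulate a two-condition experiment (6 subjects, 100 trials per condition,
condition-1 drift twice condition-0 at the group level), fit a hierarchical
model with drift split by condition, and test the condition effect on the
posterior:

```python
from ddmbayes import diagnose, infer
from ddmbayes.model import ModelSpec, build_model
from ddmbayes.simulate import ExperimentDesign, sample_group_dataset

design = ExperimentDesign(n_subjects=6, n_trials=100,
                          drift_rule="double", seed=42)
data, truth = sample_group_dataset(design)   # trial table + ground truth

graph = build_model(data, ModelSpec(depends_on={"v": "cond"},
                                    include=("sv",)))
infer.find_starting_values(graph)            # MAP start
trace = infer.sample(graph, n_samples=1200, burn=200, seed=7)

print(diagnose.summarize(trace).loc[["v(c0)", "v(c1)", "a", "t", "sv"]])
print(diagnose.prob_greater(trace["v(c1)"], trace["v(c0)"]))
```

Output (generating group values: v1 = 1.274, v2 = 2.548, a = 1.939,
t = 0.372):

```
        mean    std   2.5q    25q    50q    75q  97.5q
v(c0)  1.194  0.173  0.858  1.090  1.187  1.285  1.560
v(c1)  2.462  0.238  2.075  2.342  2.450  2.592  2.867
a      1.790  0.193  1.426  1.690  1.796  1.889  2.151
t      0.294  0.131  0.014  0.215  0.323  0.389  0.494
sv     0.369  0.153  0.052  0.278  0.384  0.477  0.631
P(v_c1 > v_c0 | data) = 0.995
```

Each row summarizes one group-level posterior (mean, SD and percentiles);
the generating values sit inside the 95% intervals, and the posterior
probability that the condition-1 drift exceeds the condition-0 drift is
0.995 — the effect is detected directly on the posterior, no t-test needed.

Regression models tie a parameter to trial-level covariates:

```python
from ddmbayes.model import build_regression_model
m = build_regression_model(data, "a ~ theta:C(conf, Treatment('LC'))")
# Adding these covariates:
# ['a_Intercept', "a_theta:C(conf, Treatment('LC'))[HC]",
#  "a_theta:C(conf, Treatment('LC'))[LC]"]
```

A command line wraps the same workflow: `ddmbayes simulate`, `ddmbayes
fit` (multi-chain), `ddmbayes diagnose` (Gelman-Rubin across chains) and
`ddmbayes recover` (recovery/detection experiments). Data files are plain
CSV with required columns `subj_idx`, `rt` (seconds), `response` (0/1) and
arbitrary extra condition/covariate columns.

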