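# Methods

## The model

`ddmbayes` estimates the drift-diffusion model (DDM) of two-choice decision
making. A latent evidence variable starts at `z·a` between two absorbing
boundaries 0 and `a`, accumulates with mean drift `v` and unit within-trial
noise (the standard identifiability convention: the noise coefficient `s`
is fixed at 1), and the response time is the boundary-crossing time plus a
non-decision time `t`. The "full DDM" adds inter-trial variability: drift
drawn per trial from Normal(v, sv), start point from a uniform range of
width `sz` around `z`, and non-decision time from a uniform range of width
`st` around `t`.

### Likelihood

The first-passage density at the lower boundary has two classical series
representations: a sine series that converges quickly at large normalized
times `tt = (rt − t)/a²` and an image (reflection) expansion that converges
quickly at small `tt`. For every evaluation point the kernel computes the
number of terms each expansion needs to push the truncation error below
`series_tolerance` (default 1e-8, absolute error on the normalized-density
scale) and uses whichever needs fewer. The upper-boundary density is the
exact mirror map `(v, z) → (−v, 1−z)` of the lower-boundary kernel, and the
density is exactly 0 (not an epsilon) for `rt ≤ t` — penalizing impossible
observations is left to callers, where it surfaces as a −inf log-likelihood.

Drift variability `sv` is integrated in closed form (Gaussian integral over
the drift). `st` and `sz` are integrated numerically with Simpson's rule
over their uniform intervals (default 11 nodes each; an even request is
rounded up to the next odd count). Tests verify both against dense-grid
quadrature oracles.

An optional outlier mixture replaces the trial density with
`(1−p_outlier)·f_DDM + p_outlier·u`, where `u` is uniform on (0, max_rt]
with equal mass on the two responses (density `1/(2·max_rt)`). The default
`p_outlier` is 0 and it is a fixed configuration scalar, not a sampled node.

### Hierarchy and priors

For each estimated parameter (optionally split by condition via
`depends_on`) there is a group mean node and a group spread node; subject
parameters scatter around the group mean with the spread as SD. Thresholds
and non-decision times use a zero-truncated (renormalized) normal subject
law; the bias `z` scatters on the logit scale (the logit link keeps (0,1)
respected without clipping). The
inter-trial variabilities sv/st/sz are group-only nodes — single subjects
carry too little information about them. With `is_group_model=False` (or a
single subject) the subject nodes take the group-mean priors directly.

Informative hyperpriors (defaults; family written as in the code, gamma
parameterized by mean and rate):

| node | prior | rationale |
|---|---|---|
| v | Normal(2, 3) | drifts of a few units/s |
| a | Gamma(mean 1.5, rate 1.0) | thresholds ~1–2.5 |
| t | Gamma(mean 0.4, rate 2.0) | a few hundred ms |
| z | Beta(10, 10) | centred on 0.5 |
| v_std, a_std, t_std | Half-normal(2 / 1 / 0.3) | weak positive spreads |
| sv, st | Half-normal(2 / 0.3) | weak |
| sz | Beta(1, 3) | small ranges favoured |
| regression slopes | Normal(0, 3), spread Half-normal(1) | weak |

These constants are this package's defaults, chosen to sit in the plausible
range of the fitting literature; every one can be replaced per node through
`ModelSpec.prior_overrides`. A non-informative set is available via
`informative_priors=False`.

### Regression models

A linear-model descriptor such as `"a ~ theta:C(conf, Treatment('LC'))"`
replaces the threshold of trial j with the design row of that trial times a
subject-specific coefficient vector. Design matrices, treatment coding of
categoricals and coefficient naming come from patsy; each coefficient gets
the same group-mean/group-spread hierarchical treatment as an ordinary
parameter (intercepts inherit the outcome parameter's priors, slopes the
weak normal slope prior). Trial-level parameter values that leave the
valid domain (e.g. a non-positive threshold) yield a −inf likelihood
contribution rather than being clipped.

## Inference

### Sampling

The sampler is component-wise slice sampling (stepping-out with a randomly
split budget, then shrinkage) on unconstrained coordinates: log scale for
positive nodes, logit scale for interval nodes, with the Jacobian added to
the target. Slice sampling needs no step-size tuning and every update
leaves the joint posterior invariant. Subject nodes of one parameter are
conditionally independent given the group nodes, so they are updated in a
single vectorized sweep — one likelihood evaluation serves all subjects —
which is what makes multi-subject fits affordable. Defaults: 2000 samples,
burn-in 20, no thinning. Chain c of a multi-chain run uses seed `seed + c`;
fixed seeds give bit-identical traces. The deviance (−2 log-likelihood) is
recorded at every stored draw.

### Starting values

The joint mode of a hierarchical posterior is degenerate: the density grows
without bound as a group spread shrinks to zero with the subjects pinned to
the mean. `find_starting_values` therefore coordinate-ascends every node
*except* the group spreads (bounded Brent on the sampling scale, accepting
only improvements) and then sets each spread to the empirical SD of the
subject optima, floored at 0.05 and kept only when the joint log-posterior
does not decrease. For a single free node with a smooth conditional this
reduces to exact mode finding (verified on the conjugate toy at 1e-6).

### Diagnostics and model comparison

`gelman_rubin` is the original between/within-chain statistic
`sqrt(((n−1)/n·W + B/n)/W)` without rank normalization or chain splitting
(a split-chain variant sits behind `split=True`); values above 1.02 are
flagged. `dic` computes `D̄ + pD` with `pD = D̄ − D(θ̄)`; θ̄ is the
posterior mean on the unconstrained sampling scale by default (the natural
scale is available via `scale="natural"`). Posterior summary quantiles use
linear interpolation between order statistics; the posterior hypothesis
test `prob_greater` uses strict inequality, so ties count as "not greater".

## The synthetic-data generator

`simulate_trials` integrates the generative process by Euler–Maruyama at
`dt = 1e-4 s` (default) with a 20 s cap per trial; capped walks are logged
and resampled, and subject parameter draws that violate domain constraints
are redrawn rather than clipped (avoids boundary pile-up). Halving `dt`
leaves simulated RT quantiles stable within Monte-Carlo error, and the
empirical CDF of 1e5 simulated trials matches the analytic CDF to
sup-distance < 0.01 per boundary (tested).

The experiment generators reproduce three recovery-study designs. Group
parameters are drawn uniformly from `v1 ∈ [0.5, 1.5]`, `a ∈ [1.5, 2.5]`,
`t ∈ [0.2, 0.4]`, `sv ∈ [0, 0.5]` — plausible-range conventions from the
DDM fitting literature, exposed in `ExperimentDesign.group_ranges` rather
than baked in. Subjects add zero-centred normal noise with SDs 0.2, 0.2,
0.1, 0.1 on v1, a, t, sv; st and sz are zero; z is 0.5. In the
two-condition design the group drift of the second condition is twice the
first and the subject noise on both drifts is the *same* draw, so the
within-subject drift difference is constant across subjects. "Trials" means
trials per subject per condition. The covariate design draws a per-subject
drift mean `α_i` with the usual noise and sets the drift of trial j to
`α_i + β·x_ij` with `x_ij ~ N(0,1)` and β ∈ {0.1, 0.3, 0.5}.

What the generator does *not* emulate: contaminant/outlier response
processes beyond the uniform mixture, non-stationarity across a session,
response-time rounding or device quantization, and any within-trial noise
structure beyond the Wiener process. Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to real-data violations of them.

## Benchmark estimators

The ML comparator maximizes the same first-passage likelihood per subject
(no outlier mixture, series tolerance 1e-6 for speed) with multi-start
Nelder-Mead on unconstrained coordinates (`t` is mapped into (0, min rt) by
a scaled logit). The χ²-quantile comparator forms six bins per boundary
from the observed 0.1/0.3/0.5/0.7/0.9 RT quantiles and minimizes
Σ(O−E)²/E against expected counts from the defective model CDF (trapezoid
integration of the density on a 192-point grid); a boundary with fewer
than 5 observations collapses to a single choice-probability term. The
hierarchical comparison model expresses the within-subject effect through
a treatment-coded drift regression (`v ~ C(cond, Treatment('c0'))` or
`v ~ x`), so the effect has its own group-level node whose 95% central
posterior interval drives detection; the non-hierarchical methods use
paired or one-sample t-tests at 0.05 across subjects.

Recovery error is scored as trimmed mean absolute error: the largest 5% of
absolute errors are discarded before averaging (the point estimators
occasionally return wild values on 20-trial subjects).

## Problem sizes in the shipped validation runs

The test suite and the acceptance script run everything at sizes chosen for
a single CPU: likelihood normalization on a 27-point parameter grid;
simulation agreement at 1e5 trials; sampler calibration over 20 replicates
of 4 subjects × 200 trials with 500-draw chains; the five-chain convergence
check at its natural scale (5 × 2000 samples on 5 subjects × 200 trials);
recovery at 5 datasets × 12 subjects × {20, 150} trials; detection at one
cell per design × 4 datasets (plus a 20-dataset ML null calibration); DIC
model selection over 3 replicates. The full-scale grids (30 datasets,
seven trial counts, six subject counts) are reachable through
`benchmark.run_recovery` and the `recover` CLI subcommand with a custom
config.

## Known limitations

- The slice sampler is serial per chain; no gradient-based kernels.
- DIC is known to favour complexity; no WAIC/LOO or Bayes factors.
- `depends_on` creates independent group distributions per condition level
  (as in a between-group split), not a shared-variance ANOVA structure.
- MAP values are coordinate-wise optima (exact only for smooth
  one-dimensional conditionals); they are used solely as chain starts.
- The regression builder detects rank deficiency but not near-collinearity;
  an (accidentally) constant covariate duplicating the intercept is
  rejected rather than being re-expressed.
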