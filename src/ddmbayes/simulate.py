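"""Trial-level DDM simulator and multi-subject experiment generators.

Single trials are generated by an Euler-Maruyama random walk of the evidence
process between the absorbing boundaries 0 and ``a``: starting from ``z*a``
the walk takes steps ``v*dt + sqrt(dt)*N(0,1)`` until it crosses either
boundary; the response time is the crossing time plus the non-decision time.
Inter-trial variability jitters the drift (normal, sd ``sv``), the start
point and the non-decision time (uniform ranges ``sz``, ``st``) per trial.

The experiment generators reproduce three recovery-study designs:

* a two-condition design in which the second drift rate is twice the first
  at the group level and subject noise on both drifts is the *same* draw,
  so the within-subject drift difference is constant across subjects;
* the same design with the drift effect switched off (null control);
* a trial-by-trial covariate design where each subject's drift on trial j
  is ``alpha_i + beta * x_ij`` with a standard-normal covariate ``x``.

Group parameters are drawn uniformly from configurable ranges; subject
parameters add zero-centered normal noise with per-parameter SDs
(defaults 0.2, 0.2, 0.1, 0.1 for v, a, t, sv).  Subjects violating domain
constraints are redrawn, not clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import DDMParams

__all__ = [
    "ExperimentDesign",
    "simulate_trials",
    "sample_group_dataset",
    "generate_covariate_dataset",
]

logger = logging.getLogger(__name__)

#: default uniform sampling ranges for the group-level parameters
DEFAULT_GROUP_RANGES: dict[str, tuple[float, float]] = {
    "v": (0.5, 1.5),
    "a": (1.5, 2.5),
    "t": (0.2, 0.4),
    "sv": (0.0, 0.5),
}

#: default SD of the zero-centered subject-level noise per parameter
DEFAULT_SUBJECT_SD: dict[str, float] = {"v": 0.2, "a": 0.2, "t": 0.1, "sv": 0.1}


@dataclass
class ExperimentDesign:
    """Configuration of one synthetic multi-subject experiment.

    ``n_trials`` is the number of trials per subject *per condition*.
    ``drift_rule`` selects the two-condition drift structure: ``"double"``
    sets the group-level second drift to twice the first (with identical
    subject noise on both), ``None`` generates a single condition, and
    ``"null"`` generates two conditions with identical drift (control).
    ``effect_size`` (beta) switches on the trial-by-trial covariate design.
    """

    n_subjects: int = 12
    n_trials: int = 20
    group_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_RANGES))
    subject_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBJECT_SD))
    drift_rule: str | None = "double"
    effect_size: float | None = None
    dt: float = 1e-4
    t_max: float = 20.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("n_subjects and n_trials must be >= 1")
        if any(sd < 0 for sd in self.subject_sd.values()):
            raise ValueError("subject noise SDs must be >= 0")
        if self.drift_rule not in (None, "double", "null"):
            raise ValueError(f"unknown drift_rule {self.drift_rule!r}")


# ---------------------------------------------------------------------------
# core first-passage walk
# ---------------------------------------------------------------------------

def _first_passage(v, a, x0, dt, rng, t_max=20.0, block=128):
    """Vectorized Euler-Maruyama first passage between 0 and ``a``.

    ``v`` and ``x0`` are per-walker arrays.  Returns (decision_time, upper)
    arrays and the number of walkers that hit the time cap (these are
    returned with NaN times and must be resampled by the caller).
    Walks are advanced in blocks of ``block`` steps; within a block the
    cumulative path is scanned for its first boundary crossing.
    """
    v = np.asarray(v, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    n = v.shape[0]
    dec_t = np.full(n, np.nan)
    upper = np.zeros(n, dtype=bool)
    active = np.arange(n)
    pos = x0.copy()
    steps_done = 0
    max_steps = int(np.ceil(t_max / dt))
    sdt = np.sqrt(dt)
    while active.size and steps_done < max_steps:
        b = min(block, max_steps - steps_done)
        incr = v[active, None] * dt + sdt * rng.standard_normal((active.size, b))
        path = pos[active, None] + np.cumsum(incr, axis=1)
        hit_up = path >= a
        hit_lo = path <= 0.0
        hit = hit_up | hit_lo
        any_hit = hit.any(axis=1)
        if any_hit.any():
            rows = np.nonzero(any_hit)[0]
            first = hit[rows].argmax(axis=1)
            idx = active[rows]
            dec_t[idx] = (steps_done + first + 1) * dt
            upper[idx] = hit_up[rows, first]
        pos[active] = path[:, -1]
        active = active[~any_hit]
        steps_done += b
    return dec_t, upper, active.size


def simulate_trials(params: DDMParams, n: int, dt: float = 1e-4,
                    seed=None, t_max: float = 20.0,
                    subj_idx: int = 0) -> pd.DataFrame:
    """Simulate ``n`` trials from one DDM parameter set.

    Per-trial drift, start point and non-decision time are jittered by
    ``sv``/``sz``/``st``.  Walks that have not been absorbed after ``t_max``
    seconds are logged and resampled.  Returns a DataFrame with columns
    ``subj_idx``, ``rt``, ``response`` (1 = upper boundary).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    v_trial = params.v + params.sv * rng.standard_normal(n) \
        if params.sv > 0 else np.full(n, params.v)
    z_trial = rng.uniform(params.z - params.sz / 2, params.z + params.sz / 2, n) \
        if params.sz > 0 else np.full(n, params.z)
    t_trial = rng.uniform(params.t - params.st / 2, params.t + params.st / 2, n) \
        if params.st > 0 else np.full(n, params.t)
    dec_t, upper = _first_passage_resampled(
        v_trial, params.a, z_trial * params.a, dt, rng, t_max)
    return pd.DataFrame({
        "subj_idx": subj_idx,
        "rt": dec_t + t_trial,
        "response": upper.astype(int),
    })


def _first_passage_resampled(v, a, x0, dt, rng, t_max):
    """First-passage walk with censored trials resampled (logged)."""
    dec_t, upper, n_cens = _first_passage(v, a, x0, dt, rng, t_max)
    tries = 0
    while n_cens and tries < 10:
        miss = np.isnan(dec_t)
        logger.info("resampling %d censored trials (no crossing before "
                    "%.1f s)", int(miss.sum()), t_max)
        d2, u2, n_cens = _first_passage(v[miss], a, x0[miss], dt, rng, t_max)
        dec_t[miss], upper[miss] = d2, u2
        tries += 1
    if np.isnan(dec_t).any():
        raise RuntimeError("trials failed to terminate within the time cap "
                           "after repeated resampling")
    return dec_t, upper


def _simulate_per_trial_drift(v_trial, a, z, t, sv, dt, rng, t_max=20.0):
    """Simulate one trial per entry of ``v_trial`` (covariate design)."""
    n = len(v_trial)
    v_eff = np.asarray(v_trial, dtype=float)
    if sv > 0:
        v_eff = v_eff + sv * rng.standard_normal(n)
    dec_t, upper = _first_passage_resampled(
        v_eff, a, np.full(n, z * a), dt, rng, t_max)
    return dec_t + t, upper.astype(int)


# ---------------------------------------------------------------------------
# multi-subject experiment generators
# ---------------------------------------------------------------------------

def _draw_group(design: ExperimentDesign, rng) -> dict[str, float]:
    return {p: rng.uniform(*design.group_ranges[p]) for p in ("v", "a", "t", "sv")}


def _draw_subject(group: dict[str, float], design: ExperimentDesign, rng):
    """Subject parameters = group + zero-centered normal noise; invalid draws
    (e.g. a <= 0 or t < 0) are redrawn."""
    sd = design.subject_sd
    n_redraw = 0
    for _ in range(1000):
        eps_v = rng.normal(0.0, sd["v"])
        a = group["a"] + rng.normal(0.0, sd["a"])
        t = group["t"] + rng.normal(0.0, sd["t"])
        sv = abs(group["sv"] + rng.normal(0.0, sd["sv"]))
        if a > 0 and t >= 0:
            if n_redraw:
                logger.info("redrew subject parameters %d time(s)", n_redraw)
            return eps_v, a, t, sv
        n_redraw += 1
    raise RuntimeError("could not draw valid subject parameters")


def sample_group_dataset(design: ExperimentDesign):
    """Generate one multi-subject dataset for the drift-difference designs.

    Group parameters are drawn uniformly from ``design.group_ranges``; each
    subject adds zero-centered normal noise to v1, a, t and sv (sz and st
    are zero).  Under ``drift_rule="double"`` the group drift of condition
    ``c1`` is twice that of ``c0`` and the subject noise on both drifts is
    the same draw; under ``"null"`` both conditions share the same drift.

    Returns ``(data, truth)``: the trial table (columns subj_idx, rt,
    response, and ``cond`` when two conditions exist) and a per-subject
    ground-truth parameter table for recovery scoring.
    """
    rng = np.random.default_rng(design.seed)
    group = _draw_group(design, rng)
    rows, truth_rows = [], []
    for i in range(design.n_subjects):
        eps_v, a_i, t_i, sv_i = _draw_subject(group, design, rng)
        v1_i = group["v"] + eps_v
        if design.drift_rule == "double":
            v2_i = 2.0 * group["v"] + eps_v  # identical noise on both drifts
        elif design.drift_rule == "null":
            v2_i = v1_i
        else:
            v2_i = None
        conds = [("c0", v1_i)] if v2_i is None else [("c0", v1_i), ("c1", v2_i)]
        for cond, v_i in conds:
            p = DDMParams(v=v_i, a=a_i, z=0.5, t=t_i, sv=sv_i)
            df = simulate_trials(p, design.n_trials, dt=design.dt, seed=rng,
                                 t_max=design.t_max, subj_idx=i)
            if v2_i is not None:
                df["cond"] = cond
            rows.append(df)
        truth_rows.append({
            "subj_idx": i, "v1": v1_i,
            **({"v2": v2_i} if v2_i is not None else {}),
            "a": a_i, "t": t_i, "sv": sv_i,
        })
    data = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    for k, val in group.items():
        truth.attrs[f"group_{k}"] = val
    return data, truth


def generate_covariate_dataset(design: ExperimentDesign):
    """Generate a dataset with a trial-by-trial drift covariate.

    Per subject i an auxiliary drift mean ``alpha_i`` is drawn around the
    group drift with the usual subject noise; the drift on trial j is
    ``alpha_i + beta * x_ij`` with ``x_ij ~ N(0, 1)`` stored in column
    ``x``.  Remaining parameters are sampled as in the drift-difference
    designs.  Returns ``(data, truth)``.
    """
    beta = design.effect_size
    if beta is None:
        raise ValueError("design.effect_size (beta) must be set for the "
                         "covariate design")
    rng = np.random.default_rng(design.seed)
    group = _draw_group(design, rng)
    rows, truth_rows = [], []
    for i in range(design.n_subjects):
        eps_v, a_i, t_i, sv_i = _draw_subject(group, design, rng)
        alpha_i = group["v"] + eps_v
        x = rng.standard_normal(design.n_trials)
        v_trial = alpha_i + beta * x
        rt, resp = _simulate_per_trial_drift(
            v_trial, a_i, 0.5, t_i, sv_i, design.dt, rng, design.t_max)
        rows.append(pd.DataFrame({
            "subj_idx": i, "rt": rt, "response": resp, "x": x,
        }))
        truth_rows.append({"subj_idx": i, "alpha": alpha_i, "beta": beta,
                           "a": a_i, "t": t_i, "sv": sv_i})
    data = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    for k, val in group.items():
        truth.attrs[f"group_{k}"] = val
    return data, truth
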