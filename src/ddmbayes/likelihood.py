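"""Wiener first-passage-time likelihood for the drift-diffusion model.

The DDM describes two-choice decisions as a noisy accumulation of evidence
between two absorbing boundaries separated by ``a``, starting at relative
position ``z`` (absolute start ``z*a``), with mean drift ``v`` and unit
within-trial noise.  The first-passage-time density at the lower boundary
admits a series representation; two expansions exist (one that converges
quickly at large times, one at small times) and this module switches between
them per evaluation point so that the truncation error stays below a
configurable bound.

The "full" DDM adds inter-trial variability: normally distributed drift
(``sv``, integrated analytically), and uniformly distributed non-decision
time (``st``) and start point (``sz``), both integrated numerically with
Simpson's rule.

All densities are in units 1/s; response times are in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DDMParams",
    "LikelihoodConfig",
    "wfpt_density",
    "full_density",
    "dataset_loglik",
    "choice_prob_upper",
    "wiener_logpdf",
]


@dataclass(frozen=True)
class DDMParams:
    """One subject/condition parameter set of the (full) DDM.

    Parameters
    ----------
    v : drift rate (evidence units per second).
    a : boundary separation (> 0).
    z : relative starting point in (0, 1); absolute start is ``z * a``.
    t : non-decision time in seconds (>= 0).
    sv : inter-trial standard deviation of the drift (>= 0).
    st : inter-trial range of the non-decision time (uniform width, >= 0).
    sz : inter-trial range of the relative start point (uniform width, >= 0).
    """

    v: float
    a: float
    z: float = 0.5
    t: float = 0.0
    sv: float = 0.0
    st: float = 0.0
    sz: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.v, self.a, self.z, self.t]).all():
            raise ValueError("DDM parameters must be finite")
        if self.a <= 0:
            raise ValueError(f"boundary separation a must be > 0, got {self.a}")
        if not 0 < self.z < 1:
            raise ValueError(f"relative start z must lie in (0, 1), got {self.z}")
        if self.t < 0:
            raise ValueError(f"non-decision time t must be >= 0, got {self.t}")
        if self.sv < 0 or self.st < 0 or self.sz < 0:
            raise ValueError("inter-trial variabilities sv, st, sz must be >= 0")
        if self.z - self.sz / 2 <= 0 or self.z + self.sz / 2 >= 1:
            raise ValueError("start-point range z +- sz/2 must stay inside (0, 1)")
        if self.t - self.st / 2 < 0:
            raise ValueError("non-decision-time range t - st/2 must be >= 0")


@dataclass(frozen=True)
class LikelihoodConfig:
    """Numerical settings for likelihood evaluation.

    ``series_tolerance`` bounds the truncation error of the infinite sum.
    ``n_quad_st`` / ``n_quad_sz`` are Simpson grid sizes (odd, >= 3 used in
    practice) for the uniform inter-trial integrals.  ``p_outlier`` mixes the
    DDM density with a uniform outlier density over (0, ``max_rt``] that puts
    equal mass on both responses.
    """

    series_tolerance: float = 1e-8
    n_quad_st: int = 11
    n_quad_sz: int = 11
    p_outlier: float = 0.0
    max_rt: float = 20.0

    def __post_init__(self) -> None:
        if self.series_tolerance <= 0:
            raise ValueError("series_tolerance must be > 0")
        if self.n_quad_st < 2 or self.n_quad_sz < 2:
            raise ValueError("quadrature grid sizes must be >= 2")
        if not 0 <= self.p_outlier <= 1:
            raise ValueError("p_outlier must lie in [0, 1]")
        if self.max_rt <= 0:
            raise ValueError("max_rt must be > 0")


DEFAULT_CONFIG = LikelihoodConfig()


# ---------------------------------------------------------------------------
# series kernel on the normalized scale
# ---------------------------------------------------------------------------

def _fpt_kernel(tt: np.ndarray, w: np.ndarray, err: float) -> np.ndarray:
    """Density of first passage through 0 for unit-boundary, zero-drift
    diffusion started at relative position ``w``, at normalized time ``tt``.

    Chooses per element between the large-time (sine) expansion and the
    small-time (image/reflection) expansion, whichever needs fewer terms to
    reach absolute truncation error <= ``err``.
    """
    tt = np.asarray(tt, dtype=float)
    w = np.broadcast_to(np.asarray(w, dtype=float), tt.shape)
    out = np.zeros_like(tt)
    pos = tt > 0
    if not pos.any():
        return out
    ttp = tt[pos]
    wp = w[pos]

    # required number of terms for each expansion (per element)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg_l = np.pi * ttp * err
        kl = np.where(
            arg_l < 1,
            np.sqrt(np.maximum(-2.0 * np.log(np.maximum(arg_l, 1e-300)), 0.0)
                    / (np.pi**2 * ttp)),
            0.0,
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(ttp)))

        arg_s = 2.0 * np.sqrt(2.0 * np.pi * ttp) * err
        ks = np.where(
            arg_s < 1,
            2.0 + np.sqrt(np.maximum(-2.0 * ttp
                                     * np.log(np.maximum(arg_s, 1e-300)), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(ttp) + 1.0)

    small = ks < kl
    res = np.empty_like(ttp)

    if small.any():
        ts, ws = ttp[small], wp[small]
        K = int(np.ceil(ks[small].max()))
        # terms k = -floor((K-1)/2) .. ceil((K-1)/2), image expansion
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        kk = np.arange(lo, hi + 1, dtype=float)
        y = ws[:, None] + 2.0 * kk[None, :]
        s = np.sum(y * np.exp(-(y**2) / (2.0 * ts[:, None])), axis=1)
        res[small] = s / np.sqrt(2.0 * np.pi * ts**3)

    large = ~small
    if large.any():
        tl, wl = ttp[large], wp[large]
        K = int(np.ceil(kl[large].max()))
        kk = np.arange(1, K + 1, dtype=float)
        s = np.sum(
            kk[None, :]
            * np.exp(-(kk[None, :] ** 2) * np.pi**2 * tl[:, None] / 2.0)
            * np.sin(kk[None, :] * np.pi * wl[:, None]),
            axis=1,
        )
        res[large] = np.pi * s

    out[pos] = np.maximum(res, 0.0)
    return out


def _wfpt_pdf_lower(rt, v, a, z, t, sv=0.0, err=1e-8):
    """Density of hitting the *lower* boundary at time ``rt`` (array-capable).

    ``v``, ``z``, ``t`` may be scalars or arrays broadcastable with ``rt``.
    Drift variability ``sv`` is integrated analytically (Gaussian drift).
    Returns exactly 0 where ``rt <= t``.
    """
    rt = np.asarray(rt, dtype=float)
    v, a, z, t, sv = (np.asarray(x, dtype=float) for x in (v, a, z, t, sv))
    tau = rt - t  # decision time
    tau, v, a, z, sv = np.broadcast_arrays(tau, v, a, z, sv)
    dens = np.zeros(tau.shape)
    ok = tau > 0
    if not ok.any():
        return dens
    tauo, vo, ao, zo, svo = tau[ok], v[ok], a[ok], z[ok], sv[ok]
    tt = tauo / ao**2
    kern = _fpt_kernel(tt, zo, err)
    s2t = svo**2 * tauo + 1.0
    logfac = (((ao * zo * svo) ** 2 - 2.0 * ao * vo * zo - vo**2 * tauo)
              / (2.0 * s2t)) - 0.5 * np.log(s2t)
    dens[ok] = kern / ao**2 * np.exp(logfac)
    return dens


def wiener_logpdf(rt, response, v, a, z, t, sv=0.0, err=1e-8,
                  p_outlier=0.0, max_rt=20.0):
    """Per-trial log density of (rt, response) under the DDM, vectorized.

    ``response`` is 1 for the upper boundary, 0 for the lower.  ``v``, ``z``,
    ``t``, ``sv`` may be per-trial arrays (used for trial-varying regression
    parameters); ``a`` must be scalar-like per call unless broadcast with the
    rest.  The upper-boundary density is evaluated through the mirror map
    (v, z) -> (-v, 1-z).  Optional uniform outlier mixture as in
    :func:`dataset_loglik`.
    """
    rt = np.asarray(rt, dtype=float)
    response = np.asarray(response)
    upper = response.astype(bool)
    v = np.broadcast_to(np.asarray(v, dtype=float), rt.shape).copy()
    z = np.broadcast_to(np.asarray(z, dtype=float), rt.shape).copy()
    t = np.broadcast_to(np.asarray(t, dtype=float), rt.shape)
    sv = np.broadcast_to(np.asarray(sv, dtype=float), rt.shape)
    # mirror upper-boundary trials onto the lower-boundary kernel
    v[upper] = -v[upper]
    z[upper] = 1.0 - z[upper]
    dens = _wfpt_pdf_lower(rt, v, a, z, t, sv=sv, err=err)
    if p_outlier > 0:
        dens = (1.0 - p_outlier) * dens + p_outlier / (2.0 * max_rt) * (
            (rt > 0) & (rt <= max_rt)
        )
    with np.errstate(divide="ignore"):
        return np.log(dens)


def wfpt_density(rt, choice, params: DDMParams,
                 config: LikelihoodConfig = DEFAULT_CONFIG):
    """First-passage density of the simple DDM (sv = st = sz = 0).

    Parameters
    ----------
    rt : response time(s) in seconds (> 0).
    choice : ``"upper"`` or ``"lower"`` — which boundary was hit.
    params : DDM parameters; the inter-trial fields must be zero.

    Returns the density of hitting ``choice`` at ``rt`` (0 for rt <= t).
    """
    if params.sv != 0 or params.st != 0 or params.sz != 0:
        raise ValueError("wfpt_density is the sv=st=sz=0 kernel; "
                         "use full_density for inter-trial variability")
    return full_density(rt, choice, params, config)


def full_density(rt, choice, params: DDMParams,
                 config: LikelihoodConfig = DEFAULT_CONFIG):
    """First-passage density of the full DDM at one boundary.

    Drift variability is integrated in closed form; ``st`` and ``sz`` by
    Simpson quadrature over their uniform intervals.  Reduces exactly to the
    simple kernel when sv = st = sz = 0.
    """
    if choice not in ("upper", "lower"):
        raise ValueError(f"choice must be 'upper' or 'lower', got {choice!r}")
    scalar = np.isscalar(rt)
    rt = np.atleast_1d(np.asarray(rt, dtype=float))
    v, z = params.v, params.z
    if choice == "upper":
        v, z = -v, 1.0 - z
    err = config.series_tolerance

    if params.st == 0 and params.sz == 0:
        dens = _wfpt_pdf_lower(rt, v, params.a, z, params.t,
                               sv=params.sv, err=err)
    else:
        t_nodes, t_w = _simpson_nodes(params.t, params.st, config.n_quad_st)
        z_nodes, z_w = _simpson_nodes(z, params.sz, config.n_quad_sz)
        dens = np.zeros_like(rt)
        for tn, twt in zip(t_nodes, t_w):
            for zn, zwt in zip(z_nodes, z_w):
                dens += twt * zwt * _wfpt_pdf_lower(
                    rt, v, params.a, zn, tn, sv=params.sv, err=err)
    return float(dens[0]) if scalar else dens


def _simpson_nodes(center: float, width: float, n: int):
    """Nodes and normalized Simpson weights for averaging over a uniform
    interval [center - width/2, center + width/2]; degenerate when width=0."""
    if width == 0:
        return np.array([center]), np.array([1.0])
    if n % 2 == 0:
        n += 1  # Simpson needs an odd number of nodes
    x = np.linspace(center - width / 2, center + width / 2, n)
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w /= w.sum()
    return x, w


def dataset_loglik(trials, params: DDMParams,
                   config: LikelihoodConfig = DEFAULT_CONFIG) -> float:
    """Log-likelihood (nats) of a set of trials under one parameter set.

    ``trials`` is a DataFrame-like with columns ``rt`` (seconds, > 0) and
    ``response`` (1 = upper, 0 = lower).  Each trial contributes
    ``log[(1 - p_outlier) * f_DDM + p_outlier * u]`` where ``u`` is the
    uniform outlier density ``1 / (2 * max_rt)`` over (0, max_rt] split
    equally across the two responses.  Returns ``-inf`` when any trial has
    zero mixture density.
    """
    if isinstance(trials, pd.DataFrame):
        rt = trials["rt"].to_numpy(dtype=float)
        resp = trials["response"].to_numpy()
    else:
        rt = np.asarray(trials[0], dtype=float)
        resp = np.asarray(trials[1])
    if rt.size == 0:
        raise ValueError("empty dataset")
    if (rt <= 0).any():
        raise ValueError("all response times must be > 0")

    dens_up = full_density(rt, "upper", params, config)
    dens_lo = full_density(rt, "lower", params, config)
    dens = np.where(resp.astype(bool), dens_up, dens_lo)
    if config.p_outlier > 0:
        u = (1.0 / (2.0 * config.max_rt)) * ((rt > 0) & (rt <= config.max_rt))
        dens = (1.0 - config.p_outlier) * dens + config.p_outlier * u
    if (dens <= 0).any():
        return -np.inf
    return float(np.log(dens).sum())


def choice_prob_upper(v: float, a: float, z: float) -> float:
    """Exact probability of absorbing at the upper boundary.

    For unit within-trial noise this is the classical hitting probability of
    Brownian motion with drift: (1 - exp(-2 v z a)) / (1 - exp(-2 v a)),
    which tends to ``z`` as v -> 0.
    """
    if a <= 0:
        raise ValueError("a must be > 0")
    if not 0 < z < 1:
        raise ValueError("z must lie in (0, 1)")
    if v == 0:
        return float(z)
    if v < 0:
        return 1.0 - choice_prob_upper(-v, a, 1.0 - z)
    # v > 0: both expm1 arguments are negative, no overflow
    num = -np.expm1(-2.0 * v * z * a)
    den = -np.expm1(-2.0 * v * a)
    return float(num / den)
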