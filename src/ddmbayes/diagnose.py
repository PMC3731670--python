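"""Posterior summaries, convergence diagnostics and model comparison.

``summarize`` mirrors the usual print_stats layout (mean, std and the
2.5/25/50/75/97.5 posterior percentiles per node).  ``gelman_rubin``
implements the classical potential-scale-reduction statistic from
between- and within-chain variances (no rank normalization, no chain
splitting; a split-chain variant is available behind a flag); values above
1.02 indicate convergence problems.  ``dic`` computes the deviance
information criterion DIC = D-bar + pD with pD = D-bar - D(theta-bar),
where theta-bar is the posterior mean taken by default on the
unconstrained sampling scale.  ``prob_greater`` is the posterior
hypothesis test: the fraction of paired draws in which one node exceeds
another (ties count as not greater).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .infer import PosteriorTrace

__all__ = ["summarize", "gelman_rubin", "dic", "prob_greater"]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["mean", "std", "2.5q", "25q", "50q", "75q", "97.5q"]

#: convergence flag threshold for the Gelman-Rubin statistic
RHAT_THRESHOLD = 1.02


def _as_sample_dict(trace) -> dict[str, np.ndarray]:
    if isinstance(trace, PosteriorTrace):
        return trace.samples
    if isinstance(trace, pd.DataFrame):
        return {c: trace[c].to_numpy() for c in trace.columns}
    return {k: np.asarray(v) for k, v in dict(trace).items()}


def summarize(trace, acf_lags: int = 0) -> pd.DataFrame:
    """Summary-statistics table of each node's posterior.

    One row per node with columns mean, std, 2.5q, 25q, 50q, 75q, 97.5q
    (quantiles by linear interpolation between order statistics; std with
    one delta degree of freedom).  With ``acf_lags > 0``, autocorrelation
    columns ``acf.1`` .. ``acf.L`` of the stored (post-thinning) chain are
    appended.
    """
    samples = _as_sample_dict(trace)
    if not samples or any(len(s) == 0 for s in samples.values()):
        raise ValueError("empty trace")
    rows = {}
    for name, s in samples.items():
        s = np.asarray(s, dtype=float)
        q = np.quantile(s, [0.025, 0.25, 0.5, 0.75, 0.975])
        row = [s.mean(), s.std(ddof=1) if len(s) > 1 else 0.0, *q]
        if acf_lags:
            row += list(_acf(s, acf_lags))
        rows[name] = row
    cols = list(SUMMARY_COLUMNS)
    if acf_lags:
        cols += [f"acf.{k}" for k in range(1, acf_lags + 1)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def _acf(x: np.ndarray, lags: int) -> np.ndarray:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return np.zeros(lags)
    return np.array([x[:-k] @ x[k:] / denom if k < len(x) else 0.0
                     for k in range(1, lags + 1)])


def gelman_rubin(traces, split: bool = False) -> dict[str, float]:
    """Potential scale reduction R-hat per node from >= 2 chains.

    With chains of length n and between/within-chain variances B and W,
    R-hat = sqrt(((n-1)/n * W + B/n) / W).  ``split=True`` halves each
    chain first (detects within-chain drift).  Nodes with R-hat above
    1.02 are logged as convergence problems.
    """
    dicts = [_as_sample_dict(t) for t in traces]
    if len(dicts) < 2:
        raise ValueError("gelman_rubin needs at least 2 chains")
    names = list(dicts[0])
    lengths = {len(d[n]) for d in dicts for n in names}
    if len(lengths) != 1:
        raise ValueError("all chains must have equal stored lengths")
    out = {}
    for name in names:
        chains = [np.asarray(d[name], dtype=float) for d in dicts]
        if split:
            half = len(chains[0]) // 2
            chains = [c[:half] for c in chains] + [c[-half:] for c in chains]
        c = np.vstack(chains)
        n = c.shape[1]
        means = c.mean(axis=1)
        W = float(c.var(axis=1, ddof=1).mean())
        B_over_n = float(means.var(ddof=1))
        if W == 0:
            if B_over_n == 0:
                raise ValueError(f"degenerate chains for node {name!r}: "
                                 "zero within- and between-chain variance")
            out[name] = np.inf
            continue
        var_hat = (n - 1) / n * W + B_over_n
        out[name] = float(np.sqrt(var_hat / W))
        if out[name] > RHAT_THRESHOLD:
            logger.warning("R-hat for %s is %.4f (> %.2f): convergence "
                           "suspect", name, out[name], RHAT_THRESHOLD)
    return out


def dic(model, trace: PosteriorTrace, scale: str = "sampling") -> float:
    """Deviance information criterion: DIC = D-bar + pD, lower is better.

    D-bar is the posterior mean deviance (-2 log-likelihood of the
    observations, taken from the trace's stored deviance or recomputed);
    pD = D-bar - D(theta-bar) with theta-bar the per-node posterior mean,
    computed on the unconstrained sampling scale (``scale="sampling"``,
    the default) or on the natural scale (``scale="natural"``).
    The model is left at theta-bar on return.
    """
    if scale not in ("sampling", "natural"):
        raise ValueError("scale must be 'sampling' or 'natural'")
    missing = [n for n in model.free_names if n not in trace.samples]
    if missing:
        raise ValueError(f"trace does not cover free node(s): {missing}")
    if trace.deviance is not None:
        d_bar = float(np.mean(trace.deviance))
    else:
        devs = []
        n_draws = len(trace)
        for i in range(n_draws):
            model.set_state({n: trace.samples[n][i]
                             for n in model.free_names})
            devs.append(-2.0 * model.loglik())
        d_bar = float(np.mean(devs))

    theta_bar = {}
    name_to_block = {n: b for b in model.blocks for n in b.names}
    for n in model.free_names:
        s = np.asarray(trace.samples[n], dtype=float)
        if scale == "sampling":
            tr = name_to_block[n].transform
            theta_bar[n] = float(tr.inverse(np.mean(tr.forward(s))))
        else:
            theta_bar[n] = float(np.mean(s))
    model.set_state(theta_bar)
    d_hat = -2.0 * model.loglik()
    if not np.isfinite(d_hat):
        ld = model._trial_logdens()
        bad = int(np.flatnonzero(~np.isfinite(ld))[0])
        raise ValueError(f"deviance at the posterior mean is not finite "
                         f"(first offending observation index {bad})")
    p_d = d_bar - d_hat
    return d_bar + p_d


def prob_greater(samples_a, samples_b) -> float:
    """Proportion of paired posterior draws with a > b (strict; ties count
    as not greater)."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty sample arrays")
    return float(np.mean(a > b))
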