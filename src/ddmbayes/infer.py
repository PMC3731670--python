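"""MAP initialization and MCMC sampling over a model graph.

Sampling uses component-wise slice sampling (stepping-out plus shrinkage)
on unconstrained coordinates: positive parameters are updated on a log
scale and interval parameters on a logit scale, with the Jacobian added to
the target.  Nodes that are conditionally independent given the rest of
the graph — the subject nodes of one parameter — are updated in a single
vectorized sweep, which is what makes hierarchical fits with many subjects
affordable; all other nodes are updated one at a time.  Slice sampling
needs no step-size tuning and every update leaves the joint posterior
invariant, so short burn-in from a MAP start is usually sufficient.

MAP starting values come from coordinate ascent: repeated scalar
maximization of each node's full conditional (Brent's method on the
sampling scale), which only ever accepts improvements of the joint
log-posterior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = ["PosteriorTrace", "find_starting_values", "sample"]


@dataclass
class PosteriorTrace:
    """Per-node posterior samples from one chain.

    ``samples[name]`` has length ``(n_samples - burn + thin - 1) // thin``;
    ``deviance`` stores -2 x data log-likelihood at each stored draw.
    """

    samples: dict[str, np.ndarray]
    n_samples: int
    burn: int
    thin: int = 1
    chain_id: int = 0
    seed: int | None = None
    deviance: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(next(iter(self.samples.values())))

    def __getitem__(self, name):
        return self.samples[name]

    @property
    def node_names(self):
        return list(self.samples)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples)
        if self.deviance is not None:
            df["deviance"] = self.deviance
        return df

    def to_csv(self, path) -> None:
        """Write the trace as plain CSV plus a JSON sidecar of run
        metadata (<path>.meta.json)."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        meta = {"n_samples": self.n_samples, "burn": self.burn,
                "thin": self.thin, "chain_id": self.chain_id,
                "seed": self.seed, **self.meta}
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path) -> "PosteriorTrace":
        path = Path(path)
        df = pd.read_csv(path)
        dev = None
        if "deviance" in df.columns:
            dev = df.pop("deviance").to_numpy()
        meta_path = Path(str(path) + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(samples={c: df[c].to_numpy() for c in df.columns},
                   n_samples=meta.get("n_samples", len(df)),
                   burn=meta.get("burn", 0), thin=meta.get("thin", 1),
                   chain_id=meta.get("chain_id", 0),
                   seed=meta.get("seed"), deviance=dev)


# ---------------------------------------------------------------------------
# MAP
# ---------------------------------------------------------------------------

def find_starting_values(model, n_passes: int = 4, xtol: float = 1e-8):
    """Coordinate-ascent MAP estimate used to initialize sampling.

    Each node's full conditional is maximized in turn with Brent's method
    on the node's unconstrained sampling scale; passes repeat until the
    joint log-posterior stops improving (at most ``n_passes`` sweeps).
    Returns the node -> value mapping and leaves the model at the optimum.

    Raises if no feasible starting point exists (typically a non-decision
    time at or above the smallest response time).
    """
    if not np.isfinite(model.logp()):
        raise RuntimeError(
            "log-posterior is -inf at the initial point; check that every "
            "response time exceeds the non-decision time (try reducing t)")
    from .model import _GroupStdBlock, _SubjectBlock

    last = -np.inf
    for _ in range(n_passes):
        for block in model.blocks:
            if isinstance(block, _GroupStdBlock):
                # the joint mode is degenerate in the group spreads
                # (spread -> 0 with all subjects equal); hold them fixed
                # during coordinate ascent and set them empirically below
                continue
            tr = block.transform
            for i in range(len(block.values)):
                x = block.values.copy()

                def neg(y, i=i, x=x, block=block, tr=tr):
                    xi = float(tr.inverse(np.asarray(y)))
                    x[i] = xi
                    lp = block.conditional_logp(x)[i] \
                        + float(tr.logjac(np.asarray(y)))
                    return -lp if np.isfinite(lp) else 1e300

                y0 = float(tr.forward(np.asarray(block.values[i])))
                res = minimize_scalar(
                    neg, bounds=(y0 - 5.0, y0 + 5.0), method="bounded",
                    options={"xatol": xtol})
                ynew = float(res.x)
                if neg(ynew) <= neg(y0):
                    block.values[i] = float(tr.inverse(np.asarray(ynew)))
            block.on_commit()
        cur = model.logp()
        if cur - last < 1e-6:
            break
        last = cur

    # data-driven group spreads: empirical SD of the subject-level optima
    # (floored away from the funnel), kept only if they do not hurt
    before = model.logp()
    saved = model.get_state()
    for block in model.blocks:
        if isinstance(block, _GroupStdBlock):
            fam, ix = block.fam, block.level_ix
            sblock = next(b for b in model.blocks
                          if isinstance(b, _SubjectBlock)
                          and b.fam is fam and b.level_ix == ix)
            vals = sblock.values
            if fam.base_param == "z":  # z scatters on the logit scale
                vals = sblock.transform.forward(vals)
            emp = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.1
            block.values[0] = max(emp, 0.05)
            block.on_commit()
    if model.logp() < before:
        model.set_state(saved)
    return model.get_state()


# ---------------------------------------------------------------------------
# slice sampling
# ---------------------------------------------------------------------------

def _slice_update(block, rng, max_stepout: int = 16, max_shrink: int = 64):
    """One vectorized slice-sampling update of all components of a block.

    Components are conditionally independent, so each gets its own slice
    level, stepping-out interval and shrinkage loop; the per-component
    conditional is evaluated for all components at once.
    """
    tr = block.transform
    y = tr.forward(block.values)
    y = np.atleast_1d(np.asarray(y, dtype=float)).copy()
    m = y.size

    def logp_y(yv):
        xv = tr.inverse(yv)
        return block.conditional_logp(np.atleast_1d(xv)) + tr.logjac(yv)

    lp0 = logp_y(y)
    # slice level; guard against a -inf current point (should not happen)
    logu = lp0 + np.log(rng.uniform(low=1e-300, size=m))

    w = block.width
    L = y - w * rng.uniform(size=m)
    R = L + w
    # stepping out with a random budget split (Neal 2003)
    j = np.floor(max_stepout * rng.uniform(size=m)).astype(int)
    k = (max_stepout - 1) - j
    grow = logp_y(L) > logu
    while grow.any() and (j > 0).any():
        idx = grow & (j > 0)
        L[idx] -= w
        j[idx] -= 1
        grow = np.zeros(m, dtype=bool)
        grow[idx] = logp_y(L)[idx] > logu[idx]
    grow = logp_y(R) > logu
    while grow.any() and (k > 0).any():
        idx = grow & (k > 0)
        R[idx] += w
        k[idx] -= 1
        grow = np.zeros(m, dtype=bool)
        grow[idx] = logp_y(R)[idx] > logu[idx]

    # shrinkage
    ynew = y.copy()
    todo = np.ones(m, dtype=bool)
    for _ in range(max_shrink):
        prop = L + (R - L) * rng.uniform(size=m)
        lp = logp_y(np.where(todo, prop, ynew))
        ok = todo & (lp >= logu)
        ynew[ok] = prop[ok]
        todo &= ~ok
        if not todo.any():
            break
        shrink_l = todo & (prop < y)
        shrink_r = todo & ~shrink_l
        L[shrink_l] = prop[shrink_l]
        R[shrink_r] = prop[shrink_r]
    block.values = np.atleast_1d(np.asarray(tr.inverse(ynew), dtype=float))
    block.on_commit()


def sample(model, n_samples: int = 2000, burn: int = 20, thin: int = 1,
           seed: int | None = None, n_chains: int = 1,
           find_start: bool = False, progress: bool = False):
    """Draw posterior samples with component-wise slice sampling.

    Returns one :class:`PosteriorTrace` (``n_chains == 1``) or a list of
    traces, one per chain; chain c uses seed ``seed + c``.  ``burn``
    initial iterations are discarded and every ``thin``-th of the rest is
    stored; deterministic under a fixed seed.  With ``find_start`` the
    chain starts from the coordinate-ascent MAP.
    """
    if not (n_samples > burn >= 0):
        raise ValueError("need n_samples > burn >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if n_chains > 1:
        start = find_starting_values(model) if find_start else \
            model.get_state()
        traces = []
        for c in range(n_chains):
            model.set_state(start)
            traces.append(sample(model, n_samples, burn, thin,
                                 seed=None if seed is None else seed + c,
                                 n_chains=1, find_start=False,
                                 progress=progress))
            traces[-1].chain_id = c
        return traces

    if find_start:
        find_starting_values(model)
    if not np.isfinite(model.logp()):
        bad = _first_invalid_block(model)
        raise RuntimeError(f"log-posterior is not finite at the start of "
                           f"sampling (node block {bad})")
    rng = np.random.default_rng(seed)
    names = model.free_names
    has_loglik = hasattr(model, "loglik")
    stored = {n: [] for n in names}
    dev = []
    n_keep = max((n_samples - burn) // thin, 1)
    n_stored = 0
    for it in range(n_samples):
        for block in model.blocks:
            _slice_update(block, rng)
        if it >= burn and (it - burn) % thin == 0 and n_stored < n_keep:
            n_stored += 1
            state = model.get_state()
            for n in names:
                stored[n].append(state[n])
            if has_loglik:
                dev.append(-2.0 * model.loglik())
        if progress and (it + 1) % 200 == 0:
            print(f"  iteration {it + 1}/{n_samples}")
    return PosteriorTrace(
        samples={n: np.asarray(vals) for n, vals in stored.items()},
        n_samples=n_samples, burn=burn, thin=thin, seed=seed,
        deviance=np.asarray(dev) if dev else None)


def _first_invalid_block(model):
    for b in model.blocks:
        if not np.isfinite(b.conditional_logp(b.values)).all():
            return b.names
    return "<unknown>"
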