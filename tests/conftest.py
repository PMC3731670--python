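"""Shared fixtures: tiny analytically tractable graphs for sampler checks."""

import numpy as np
import pytest

from ddmbayes.model import Block, Transform

IDENTITY = Transform()


class ConjugateNormalModel:
    """y_i ~ N(theta, sigma^2) with theta ~ N(mu0, tau0^2): the posterior of
    theta is N(mu_star, tau_star^2) in closed form, which makes this the
    reference target for MAP and sampler calibration."""

    def __init__(self, y, sigma=1.0, mu0=0.0, tau0=10.0):
        self.y = np.asarray(y, dtype=float)
        self.sigma, self.mu0, self.tau0 = sigma, mu0, tau0
        outer = self

        class _ThetaBlock(Block):
            def conditional_logp(self, x):
                x = np.atleast_1d(x)
                prior = -0.5 * ((x - outer.mu0) / outer.tau0) ** 2
                lik = np.array([
                    -0.5 * np.sum(((outer.y - xi) / outer.sigma) ** 2)
                    for xi in x])
                return prior + lik

        self.blocks = [_ThetaBlock(["theta"], [0.0], IDENTITY)]

    @property
    def free_names(self):
        return ["theta"]

    def get_state(self):
        return {"theta": float(self.blocks[0].values[0])}

    def set_state(self, state):
        self.blocks[0].values[0] = state["theta"]

    def logp(self):
        return float(self.blocks[0].conditional_logp(
            self.blocks[0].values)[0])

    def loglik(self):
        th = self.blocks[0].values[0]
        n = len(self.y)
        return float(-0.5 * np.sum(((self.y - th) / self.sigma) ** 2)
                     - n * np.log(self.sigma)
                     - 0.5 * n * np.log(2 * np.pi))

    # closed-form posterior
    @property
    def posterior(self):
        prec = len(self.y) / self.sigma**2 + 1.0 / self.tau0**2
        mean = (self.y.sum() / self.sigma**2
                + self.mu0 / self.tau0**2) / prec
        return mean, np.sqrt(1.0 / prec)


class StandardNormalModel:
    """A bare standard-normal target (no data term) for kernel smoke
    tests; deliberately lacks ``loglik`` so no deviance is tracked."""

    def __init__(self):
        class _B(Block):
            def conditional_logp(self, x):
                return -0.5 * np.atleast_1d(x) ** 2

        self.blocks = [_B(["x"], [0.0], IDENTITY)]

    @property
    def free_names(self):
        return ["x"]

    def get_state(self):
        return {"x": float(self.blocks[0].values[0])}

    def set_state(self, state):
        self.blocks[0].values[0] = state["x"]

    def logp(self):
        return float(-0.5 * self.blocks[0].values[0] ** 2)


@pytest.fixture
def conjugate_model():
    rng = np.random.default_rng(123)
    y = rng.normal(1.5, 1.0, size=40)
    return ConjugateNormalModel(y, sigma=1.0, mu0=0.0, tau0=5.0)


@pytest.fixture
def standard_normal_model():
    return StandardNormalModel()
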