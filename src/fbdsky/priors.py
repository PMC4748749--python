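"""Prior distributions for FBD model parameters.

Small closed-form log-density objects (cheap enough to call every MCMC
iteration).  The exponential distribution uses the *rate* parameterization
throughout, and Gamma(shape, rate) likewise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln

__all__ = ["Exponential", "Beta", "Gamma", "Uniform", "OffsetExponential",
           "LogNormal", "PriorSpec"]


@dataclass(frozen=True)
class Exponential:
    rate: float

    def logpdf(self, x):
        if x < 0:
            return -np.inf
        return np.log(self.rate) - self.rate * x

    @property
    def mean(self):
        return 1.0 / self.rate


@dataclass(frozen=True)
class Beta:
    a: float
    b: float

    def logpdf(self, x):
        if not 0.0 < x < 1.0:
            return -np.inf
        return ((self.a - 1.0) * np.log(x) + (self.b - 1.0) * np.log1p(-x)
                - betaln(self.a, self.b))

    @property
    def mean(self):
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class Gamma:
    shape: float
    rate: float

    def logpdf(self, x):
        if x <= 0:
            return -np.inf
        return (self.shape * np.log(self.rate) - gammaln(self.shape)
                + (self.shape - 1.0) * np.log(x) - self.rate * x)

    @property
    def mean(self):
        return self.shape / self.rate


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def logpdf(self, x):
        if not self.low <= x <= self.high:
            return -np.inf
        return -np.log(self.high - self.low)

    @property
    def mean(self):
        return 0.5 * (self.low + self.high)


@dataclass(frozen=True)
class OffsetExponential:
    """Exponential shifted to start at ``offset`` with the given ``mean``."""

    offset: float
    mean_value: float

    def logpdf(self, x):
        scale = self.mean_value - self.offset
        if x < self.offset or scale <= 0:
            return -np.inf
        return -np.log(scale) - (x - self.offset) / scale

    @property
    def mean(self):
        return self.mean_value


@dataclass(frozen=True)
class LogNormal:
    mu: float
    sigma: float

    def logpdf(self, x):
        if x <= 0:
            return -np.inf
        z = (np.log(x) - self.mu) / self.sigma
        return -np.log(x * self.sigma * np.sqrt(2.0 * np.pi)) - 0.5 * z * z

    @property
    def mean(self):
        return np.exp(self.mu + 0.5 * self.sigma ** 2)


@dataclass
class PriorSpec:
    """Hyperpriors for the FBD sampler.

    ``d``, ``r`` and ``s`` apply i.i.d. to every rate class.  ``root_age`` or
    ``clock`` set to None means the corresponding quantity is held fixed.
    """

    d: Exponential = Exponential(10.0)
    r: Beta = Beta(1.0, 1.0)
    s: Beta = Beta(1.0, 1.0)
    clock: object = None
    root_age: object = None

    def params_logpdf(self, params) -> float:
        total = 0.0
        for di, ri, si in zip(params.d, params.r, params.s):
            total += self.d.logpdf(di) + self.r.logpdf(ri) + self.s.logpdf(si)
        return float(total)
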