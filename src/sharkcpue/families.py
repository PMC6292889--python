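"""Count likelihood families on the log-link scale.

Both families expose the sum log-likelihood, its gradient, and its (exact)
negative second derivative with respect to the linear predictor
``eta = log(mu)``; the blocked sampler uses the latter two to build
Taylor-expanded Gaussian proposals.

The negative binomial is in mean--size form: mean ``mu``, size ``theta``,
variance ``mu + mu^2 / theta``, and ``P(0) = (theta / (theta + mu))^theta``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .errors import DataError


def nb_logpmf(y, mu, theta):
    """Log pmf of the mean--size negative binomial.

    Supports scalars or arrays (broadcast). ``y`` must be a non-negative
    integer, ``mu`` and ``theta`` strictly positive.
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise DataError("nb_logpmf requires mu > 0 and theta > 0")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise DataError("nb_logpmf requires non-negative integer counts")
    out = (
        gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
        + theta * (np.log(theta) - np.log(theta + mu))
        + y * (np.log(mu) - np.log(theta + mu))
    )
    return out if out.ndim else float(out)


def nb_zero_probability(mu, theta):
    """P(Y = 0) = (theta / (theta + mu))^theta, vectorized."""
    mu = np.asarray(mu, dtype=float)
    return np.exp(theta * (np.log(theta) - np.log(theta + mu)))


class NegativeBinomial:
    """NB family with fixed size ``theta`` for use inside the sampler."""

    def __init__(self, theta: float):
        if theta <= 0:
            raise DataError("theta must be > 0")
        self.theta = float(theta)

    def loglik_pointwise(self, y, eta):
        return nb_logpmf(y, np.exp(eta), self.theta)

    def loglik(self, y, eta):
        return float(np.sum(self.loglik_pointwise(y, eta)))

    def loglik_eta(self, y, eta):
        """Sum log-likelihood dropping terms constant in eta (MH ratios)."""
        mu = np.exp(eta)
        return float(np.sum(y * eta - (y + self.theta)
                            * np.log(mu + self.theta)))

    def grad(self, y, eta):
        mu = np.exp(eta)
        return y - (y + self.theta) * mu / (mu + self.theta)

    def curvature(self, y, eta):
        mu = np.exp(eta)
        return (y + self.theta) * self.theta * mu / (mu + self.theta) ** 2


class Poisson:
    """Poisson family on the log link."""

    def loglik_pointwise(self, y, eta):
        return y * eta - np.exp(eta) - gammaln(np.asarray(y) + 1)

    def loglik(self, y, eta):
        return float(np.sum(self.loglik_pointwise(y, eta)))

    def loglik_eta(self, y, eta):
        return float(np.sum(y * eta - np.exp(eta)))

    def grad(self, y, eta):
        return y - np.exp(eta)

    def curvature(self, y, eta):
        return np.exp(eta)
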