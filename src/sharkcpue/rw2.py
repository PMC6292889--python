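"""Order-2 random-walk (RW2) structure and the penalized-complexity prior.

The RW2 is the intrinsic Gaussian prior that penalizes second differences of
a time series — the count-model analogue of a cubic smoothing spline. Its
log-density is improper: the structure matrix ``Q = D'D`` (``D`` the second-
difference operator) has rank ``n - 2`` with null space spanned by constant
and linear functions of time, so the density is defined up to any linear
trend; the likelihood identifies that direction and a sum-to-zero constraint
separates the level from the intercept.

The penalized-complexity (PC) prior used for the RW2 standard deviation is
an exponential distribution on sigma calibrated by a tail statement
``P(sigma > u) = alpha``, shrinking toward the flat-trend base model.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError


def second_difference_matrix(n: int) -> np.ndarray:
    """The (n-2) x n operator D with (Df)_t = f_{t+2} - 2 f_{t+1} + f_t."""
    if n < 3:
        raise ConfigError("RW2 needs at least 3 time points")
    D = np.zeros((n - 2, n))
    idx = np.arange(n - 2)
    D[idx, idx] = 1.0
    D[idx, idx + 1] = -2.0
    D[idx, idx + 2] = 1.0
    return D


def structure_matrix(n: int) -> np.ndarray:
    """RW2 structure matrix Q = D'D (rank n - 2)."""
    D = second_difference_matrix(n)
    return D.T @ D


def rw2_quadform(f: np.ndarray) -> float:
    """Sum of squared second differences of ``f``."""
    f = np.asarray(f, dtype=float)
    if f.size < 3:
        raise ConfigError("RW2 needs at least 3 time points")
    d2 = np.diff(f, n=2)
    return float(d2 @ d2)


def rw2_logdensity(f: np.ndarray, tau: float) -> float:
    """Improper RW2 log-density up to an additive constant.

    ``(n-2)/2 * log(tau) - tau/2 * sum_t (f_{t+1} - 2 f_t + f_{t-1})^2``.
    """
    if tau <= 0:
        raise ConfigError("tau must be > 0")
    f = np.asarray(f, dtype=float)
    n = f.size
    return 0.5 * (n - 2) * np.log(tau) - 0.5 * tau * rw2_quadform(f)


def sumzero_basis(n: int) -> np.ndarray:
    """Orthonormal basis B (n x (n-1)) of the sum-to-zero subspace.

    Columns span the orthogonal complement of the constant vector, so
    ``f = B g`` satisfies ``sum(f) = 0`` for any ``g``. Built from the
    Helmert contrast matrix, hence deterministic.
    """
    if n < 2:
        raise ConfigError("need n >= 2")
    B = np.zeros((n, n - 1))
    for j in range(1, n):
        B[:j, j - 1] = 1.0
        B[j, j - 1] = -j
        B[:, j - 1] /= np.sqrt(j * (j + 1))
    return B


def pc_prior_rate(u: float, alpha: float) -> float:
    """Exponential rate lambda with P(sigma > u) = alpha."""
    if u <= 0 or not (0.0 < alpha < 1.0):
        raise ConfigError("PC prior requires u > 0 and 0 < alpha < 1")
    return -np.log(alpha) / u


def pc_prior_logdensity(sigma: float, u: float, alpha: float) -> float:
    """Log density of the PC (exponential) prior on a standard deviation."""
    lam = pc_prior_rate(u, alpha)
    if np.any(np.asarray(sigma) < 0):
        raise ConfigError("sigma must be >= 0")
    return np.log(lam) - lam * sigma
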