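"""Conjugate exponential families for change-point inference.

Each family tracks a single generative parameter (a Bernoulli rate, a Gaussian
mean with known observation noise, or a Gaussian scale with known mean) through
a pair of conjugate sufficient statistics:

* ``chi`` -- the accumulated sufficient statistic ``sum u(x)`` with the prior
  contribution folded in, and
* ``nu``  -- the pseudo-count (prior pseudo-count plus number of observations).

With this parameterization the posterior mean of the sufficient statistic is
always ``chi / nu`` and one observation updates it by a Delta rule with
learning rate ``1 / nu``; this is the property the reduced (fixed-learning-rate)
model exploits.

All predictive densities are computed in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy import special, stats

__all__ = [
    "ConjugateState",
    "ExponentialFamily",
    "Bernoulli",
    "GaussianMean",
    "GaussianScale",
    "get_family",
]


@dataclass(frozen=True)
class ConjugateState:
    """Conjugate posterior hyperparameters (chi, nu).

    ``chi`` has the same dimension as the sufficient statistic ``u(x)`` (scalar
    for all families implemented here); ``nu`` is a non-negative pseudo-count.
    """

    chi: float
    nu: float

    def __post_init__(self) -> None:
        if self.nu < 0:
            raise ValueError(f"pseudo-count nu must be >= 0, got {self.nu}")

    @property
    def stat_mean(self) -> float:
        """Posterior mean of the sufficient statistic, chi / nu."""
        if self.nu == 0:
            raise ValueError("stat_mean undefined for nu = 0")
        return self.chi / self.nu


class FamilyError(ValueError):
    """Raised for family / prior / data mismatches."""


class ExponentialFamily:
    """Base class: a conjugate exponential family with one tracked parameter."""

    family_id: str = ""

    # -- core conjugate operations -------------------------------------------------
    def sufficient_stat(self, x):
        """The transform u(x) accumulated by the conjugate update."""
        raise NotImplementedError

    def check_support(self, x) -> None:
        """Raise FamilyError if any observation lies outside the support."""

    def validate_prior(self, chi0: float, nu0: float) -> None:
        if nu0 <= 0:
            raise FamilyError(f"{self.family_id}: prior pseudo-count nu0 must be > 0")

    def update(self, state: ConjugateState, x: float) -> ConjugateState:
        """One-observation conjugate update: chi += u(x), nu += 1."""
        self.check_support(np.asarray(x))
        return ConjugateState(state.chi + float(self.sufficient_stat(x)), state.nu + 1.0)

    def log_predictive(self, chi, nu, x):
        """Log posterior-predictive density/mass of x given (chi, nu).

        Accepts arrays for chi/nu/x with numpy broadcasting.
        """
        raise NotImplementedError

    def predictive(self, state: ConjugateState, x) -> float:
        return float(np.exp(self.log_predictive(state.chi, state.nu, x)))

    # -- parameter-level quantities ------------------------------------------------
    def param_estimate(self, stat_mean):
        """Point estimate of the tracked parameter from the mean statistic chi/nu."""
        return stat_mean

    def mean(self, state: ConjugateState) -> float:
        """Posterior point estimate of the tracked parameter."""
        if state.nu <= 0:
            raise FamilyError("posterior mean undefined for nu = 0")
        return float(self.param_estimate(state.chi / state.nu))

    def param_prior_var(self, chi0: float, nu0: float) -> float:
        """Variance of the tracked parameter under the prior.

        This equals the mean squared error of an estimator that always reports
        the prior-mean parameter, so it is the natural normalizer for relative
        error (relative error 1 <=> zero-learning limit).
        """
        raise NotImplementedError

    # -- sampling (used by the generative module) ----------------------------------
    def sample_param(self, chi0: float, nu0: float, rng: np.random.Generator, size=None):
        """Draw the tracked parameter from the conjugate prior (chi0, nu0)."""
        raise NotImplementedError

    def sample_obs(self, theta, rng: np.random.Generator):
        """Draw one observation per element of theta."""
        raise NotImplementedError


class Bernoulli(ExponentialFamily):
    """Bernoulli observations with a Beta prior on the rate.

    Convention: chi = a, nu = a + b for Beta(a, b), so a uniform Beta(1, 1)
    prior is (chi0, nu0) = (1, 2) and the posterior rate estimate is chi / nu.
    """

    family_id = "bernoulli"

    def sufficient_stat(self, x):
        return np.asarray(x, dtype=float)

    def check_support(self, x) -> None:
        x = np.asarray(x)
        if not np.all((x == 0) | (x == 1)):
            raise FamilyError("bernoulli observations must be 0 or 1")

    def validate_prior(self, chi0: float, nu0: float) -> None:
        super().validate_prior(chi0, nu0)
        if not (0 < chi0 < nu0):
            raise FamilyError("bernoulli prior requires 0 < chi0 < nu0 (Beta(chi0, nu0-chi0))")

    def log_predictive(self, chi, nu, x):
        chi, nu, x = np.broadcast_arrays(chi, nu, x)
        p1 = np.asarray(chi, dtype=float) / np.asarray(nu, dtype=float)
        return np.where(np.asarray(x) == 1, np.log(p1), np.log1p(-p1))

    def param_prior_var(self, chi0: float, nu0: float) -> float:
        a, b = chi0, nu0 - chi0
        return a * b / ((a + b) ** 2 * (a + b + 1.0))

    def sample_param(self, chi0, nu0, rng, size=None):
        return rng.beta(chi0, nu0 - chi0, size=size)

    def sample_obs(self, theta, rng):
        theta = np.asarray(theta, dtype=float)
        return (rng.random(theta.shape) < theta).astype(float)


class GaussianMean(ExponentialFamily):
    """Gaussian observations with known noise sd ``sigma`` and unknown mean.

    A Gaussian prior N(mu_p, sigma_p^2) on the mean maps to
    ``nu0 = sigma^2 / sigma_p^2`` and ``chi0 = nu0 * mu_p``; with this mapping
    the posterior mean is chi / nu and sequential updates follow the
    decaying-learning-rate Delta rule with rate 1 / nu.
    """

    family_id = "gaussian_mean"

    def __init__(self, sigma: float = 5.0):
        if sigma <= 0:
            raise FamilyError("gaussian_mean requires sigma > 0")
        self.sigma = float(sigma)

    @classmethod
    def from_mean_prior(cls, sigma: float, mu_p: float, sigma_p: float):
        """Build the family and the (chi0, nu0) equivalent of N(mu_p, sigma_p^2)."""
        fam = cls(sigma)
        nu0 = sigma**2 / sigma_p**2
        return fam, nu0 * mu_p, nu0

    def to_mean_prior(self, chi0: float, nu0: float) -> tuple[float, float]:
        """Inverse of :meth:`from_mean_prior`: returns (mu_p, sigma_p)."""
        return chi0 / nu0, self.sigma / np.sqrt(nu0)

    def sufficient_stat(self, x):
        return np.asarray(x, dtype=float)

    def log_predictive(self, chi, nu, x):
        chi = np.asarray(chi, dtype=float)
        nu = np.asarray(nu, dtype=float)
        var = self.sigma**2 * (1.0 + 1.0 / nu)
        z = np.asarray(x, dtype=float) - chi / nu
        return -0.5 * (np.log(2.0 * np.pi * var) + z**2 / var)

    def param_prior_var(self, chi0: float, nu0: float) -> float:
        return self.sigma**2 / nu0

    def sample_param(self, chi0, nu0, rng, size=None):
        return rng.normal(chi0 / nu0, self.sigma / np.sqrt(nu0), size=size)

    def sample_obs(self, theta, rng):
        theta = np.asarray(theta, dtype=float)
        return rng.normal(theta, self.sigma)


class GaussianScale(ExponentialFamily):
    """Gaussian observations with known mean ``mu`` and unknown scale.

    The precision carries a Gamma(nu/2, chi/2) prior (shape-rate), i.e.
    u(x) = (x - mu)^2 accumulates into chi while nu counts observations.  The
    posterior predictive is a scaled Student-t with nu degrees of freedom and
    scale sqrt(chi / nu); the tracked parameter is the sd, estimated as
    sqrt(chi / nu).
    """

    family_id = "gaussian_scale"

    def __init__(self, mu: float = 0.0):
        self.mu = float(mu)

    def sufficient_stat(self, x):
        return (np.asarray(x, dtype=float) - self.mu) ** 2

    def validate_prior(self, chi0: float, nu0: float) -> None:
        super().validate_prior(chi0, nu0)
        if chi0 <= 0:
            raise FamilyError("gaussian_scale prior requires chi0 > 0")

    def log_predictive(self, chi, nu, x):
        chi = np.asarray(chi, dtype=float)
        nu = np.asarray(nu, dtype=float)
        scale = np.sqrt(chi / nu)
        z = (np.asarray(x, dtype=float) - self.mu) / scale
        return (
            special.gammaln((nu + 1.0) / 2.0)
            - special.gammaln(nu / 2.0)
            - 0.5 * np.log(np.pi * nu)
            - np.log(scale)
            - (nu + 1.0) / 2.0 * np.log1p(z**2 / nu)
        )

    def param_estimate(self, stat_mean):
        return np.sqrt(stat_mean)

    def _prior_sd_mean(self, chi0: float, nu0: float) -> float:
        # E[sigma] with lambda ~ Gamma(nu0/2, chi0/2): sqrt(chi0/2)*G((nu0-1)/2)/G(nu0/2)
        return float(
            np.sqrt(chi0 / 2.0)
            * np.exp(special.gammaln((nu0 - 1.0) / 2.0) - special.gammaln(nu0 / 2.0))
        )

    def param_prior_var(self, chi0: float, nu0: float) -> float:
        if nu0 <= 2:
            raise FamilyError("prior variance of sigma requires nu0 > 2")
        e_var = chi0 / (nu0 - 2.0)
        return e_var - self._prior_sd_mean(chi0, nu0) ** 2

    def sample_param(self, chi0, nu0, rng, size=None):
        lam = rng.gamma(shape=nu0 / 2.0, scale=2.0 / chi0, size=size)
        return 1.0 / np.sqrt(lam)

    def sample_obs(self, theta, rng):
        theta = np.asarray(theta, dtype=float)
        return rng.normal(self.mu, theta)


_FAMILIES = {
    "bernoulli": Bernoulli,
    "gaussian_mean": GaussianMean,
    "gaussian_scale": GaussianScale,
}


def get_family(family_id: str, **fixed: Any) -> ExponentialFamily:
    """Construct a family by id, e.g. ``get_family('gaussian_mean', sigma=5)``."""
    try:
        cls = _FAMILIES[family_id]
    except KeyError:
        raise FamilyError(
            f"unknown family {family_id!r}; choose from {sorted(_FAMILIES)}"
        ) from None
    return cls(**fixed)
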