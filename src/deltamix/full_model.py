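"""Exact (truncated) Bayesian run-length filtering.

The filter maintains a posterior over the run-length r (time steps since the
last change-point) together with, for every run-length, the conjugate
sufficient statistics of the data seen in that run.  One observation costs
O(R_max): each node passes a 'growth' message to r+1 (no change, probability
1-h) and a 'change' message to r=0 (probability h), each scaled by the node's
predictive likelihood of the observation.

After a step the weight vector is already propagated through the change-point
prior for the upcoming interval (the r=0 node, holding prior statistics, has
weight exactly h), so the predictive distribution for the next observation is
the plain node-weighted mixture computed by :meth:`FullModel.predict`.

All weight arithmetic is in log space; sufficient statistics are stored as
per-node means ``mu[r] = chi[r] / nu[r]`` with ``nu[r] = nu0 + r`` fixed, which
is algebraically identical to accumulating ``chi`` and keeps the truncation
merge at R_max a simple convex combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .families import ExponentialFamily

__all__ = ["FullModelState", "FullModel", "NumericalError"]


class NumericalError(RuntimeError):
    """Raised when an update is non-normalizable (all likelihoods zero)."""


@dataclass
class FullModelState:
    """Run-length posterior (log weights) and per-run-length statistic means.

    Arrays have shape ``(..., R_max + 1)``; leading axes are batch axes.
    ``mu[..., r]`` is the posterior mean of the sufficient statistic for a run
    of length r, i.e. ``chi_r / (nu0 + r)``.
    """

    log_w: np.ndarray
    mu: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_w)


class FullModel:
    """Truncated Bayesian run-length filter for one conjugate family."""

    def __init__(
        self,
        family: ExponentialFamily,
        chi0: float,
        nu0: float,
        h: float,
        r_max: int,
    ):
        if not 0.0 <= h <= 1.0:
            raise ValueError("hazard must lie in [0, 1]")
        if r_max < 1:
            raise ValueError("r_max must be >= 1")
        family.validate_prior(chi0, nu0)
        self.family = family
        self.chi0 = float(chi0)
        self.nu0 = float(nu0)
        self.h = float(h)
        self.r_max = int(r_max)
        self.nu = nu0 + np.arange(r_max + 1, dtype=float)
        with np.errstate(divide="ignore"):
            self._log_h = np.log(h)
            self._log_1mh = np.log1p(-h)

    # ------------------------------------------------------------------
    def init_state(self, batch_shape: tuple[int, ...] = ()) -> FullModelState:
        """All posterior mass on r = 0 with prior hyperparameters."""
        R = self.r_max
        log_w = np.full(batch_shape + (R + 1,), -np.inf)
        log_w[..., 0] = 0.0
        mu = np.full(batch_shape + (R + 1,), self.chi0 / self.nu0)
        return FullModelState(log_w=log_w, mu=mu)

    def step(self, state: FullModelState, x) -> FullModelState:
        """Assimilate one observation (scalar, or one per batch element)."""
        R = self.r_max
        x = np.asarray(x, dtype=float)
        self.family.check_support(x)
        logpred = self.family.log_predictive(
            state.mu * self.nu, self.nu, x[..., None]
        )
        # joint (unnormalized) log p(r, x): weight times predictive
        lg = state.log_w + logpred
        evidence = logsumexp(lg, axis=-1)
        if np.any(np.isneginf(evidence)) or np.any(np.isnan(evidence)):
            raise NumericalError(
                "all run-length likelihoods vanished; observation "
                f"{x!r} is inconsistent with every represented run"
            )

        new_log_w = np.empty_like(state.log_w)
        new_log_w[..., 0] = self._log_h + evidence
        new_log_w[..., 1:] = self._log_1mh + lg[..., :-1]
        # truncated prior: growth mass from R_max-1 and R_max both land at R_max
        new_log_w[..., R] = self._log_1mh + np.logaddexp(lg[..., R - 1], lg[..., R])
        new_log_w -= logsumexp(new_log_w, axis=-1, keepdims=True)

        u = np.asarray(self.family.sufficient_stat(x), dtype=float)
        new_mu = np.empty_like(state.mu)
        new_mu[..., 0] = self.chi0 / self.nu0
        new_mu[..., 1:] = state.mu[..., :-1] + (
            u[..., None] - state.mu[..., :-1]
        ) / self.nu[1:]
        # moment-matched merge at the truncation boundary, weighted by the two
        # incoming growth messages; keeps nu[R] = nu0 + R
        grown = new_mu[..., R]
        saturated = state.mu[..., R] + (u - state.mu[..., R]) / self.nu[R]
        with np.errstate(invalid="ignore", over="ignore"):
            frac = 1.0 / (1.0 + np.exp(lg[..., R] - lg[..., R - 1]))
        frac = np.where(np.isnan(frac), 1.0, frac)
        new_mu[..., R] = frac * grown + (1.0 - frac) * saturated
        return FullModelState(log_w=new_log_w, mu=new_mu)

    # ------------------------------------------------------------------
    def predict_mean(self, state: FullModelState) -> np.ndarray:
        """Predictive point estimate of the tracked parameter (node mixture)."""
        est = self.family.param_estimate(state.mu)
        return np.sum(state.weights * est, axis=-1)

    def predict(self, state: FullModelState):
        """Return ``(mean, log_density)`` for the next observation.

        ``log_density(x)`` evaluates the log predictive mixture density/mass.
        """
        mean = self.predict_mean(state)

        def log_density(x):
            lp = self.family.log_predictive(
                state.mu * self.nu, self.nu, np.asarray(x, dtype=float)[..., None]
            )
            return logsumexp(state.log_w + lp, axis=-1)

        return mean, log_density

    # ------------------------------------------------------------------
    def run(self, x: np.ndarray, return_weights: bool = False):
        """Filter a sequence (or batch of sequences, shape ``(..., T)``).

        Returns ``preds`` with ``preds[..., t]`` the prediction for ``x[..., t]``
        made *before* observing it (``preds[..., 0]`` is the prior estimate).
        With ``return_weights=True`` also returns the post-step run-length
        distributions, shape ``(..., T, R_max + 1)``.
        """
        x = np.asarray(x, dtype=float)
        T = x.shape[-1]
        batch_shape = x.shape[:-1]
        state = self.init_state(batch_shape)
        preds = np.empty(x.shape)
        weights = np.empty(batch_shape + (T, self.r_max + 1)) if return_weights else None
        for t in range(T):
            preds[..., t] = self.predict_mean(state)
            state = self.step(state, x[..., t])
            if return_weights:
                weights[..., t, :] = state.weights
        if return_weights:
            return preds, state, weights
        return preds, state
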