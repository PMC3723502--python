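"""Mixture-of-Delta-rules approximation to run-length filtering.

The reduced model keeps N 'nodes', each standing in for a run-length l_i
(possibly non-integer).  Node i tracks the mean of the sufficient statistic
with an independent Delta rule at the fixed learning rate

    alpha_i = 1 / (l_i + nu0)        (capped at 1),

which folds the prior pseudo-count nu0 into the node so that a single node
reduces exactly to a plain Delta rule.  Node weights approximate the
run-length distribution and are updated by message passing: each node sends a
change-point message to the shortest node (mass h), and its no-change mass
(1-h) is split between an 'increase' message to the next node and a 'self'
message, with the advance probability chosen so the expected run-length growth
per no-change step is 1 wherever node spacing allows it.

Per-step cost is O(N); the state is only (mu_i, w_i) -- no history buffer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .families import ExponentialFamily
from .full_model import NumericalError

__all__ = [
    "NodeSet",
    "TransitionPrior",
    "ReducedModelState",
    "ReducedModel",
    "build_transition_prior",
    "log_spaced_nodes",
    "effective_learning_rate",
]


def log_spaced_nodes(n: int, l_min: float = 1.0, l_max: float = 100.0) -> np.ndarray:
    """Logarithmically spaced node run-lengths (default 18 nodes in [1, 100])."""
    if n == 1:
        return np.array([l_min], dtype=float)
    return np.geomspace(l_min, l_max, n)


@dataclass(frozen=True)
class NodeSet:
    """Strictly increasing positive node run-lengths plus the shared prior."""

    run_lengths: np.ndarray
    chi0: float
    nu0: float

    def __post_init__(self) -> None:
        l = np.asarray(self.run_lengths, dtype=float)
        object.__setattr__(self, "run_lengths", l)
        if l.ndim != 1 or len(l) < 1:
            raise ValueError("need at least one node run-length")
        if np.any(l <= 0):
            raise ValueError("node run-lengths must be positive")
        if np.any(np.diff(l) <= 0):
            raise ValueError("node run-lengths must be strictly increasing")
        if self.nu0 <= 0:
            raise ValueError("prior pseudo-count nu0 must be > 0")

    @property
    def n_nodes(self) -> int:
        return len(self.run_lengths)

    @property
    def learning_rates(self) -> np.ndarray:
        """Fixed per-node Delta-rule rates alpha_i = 1/(l_i + nu0), capped at 1."""
        return np.minimum(1.0 / (self.run_lengths + self.nu0), 1.0)


@dataclass(frozen=True)
class TransitionPrior:
    """Adjusted change-point prior on nodes.

    ``matrix[i, j]`` is P(next node = j | node = i).  A change-point (mass h)
    always routes to node 0 (the shortest run-length); otherwise node i < N-1
    advances with probability ``advance[i]`` and stays put with the remainder,
    and the last node self-transitions.
    """

    matrix: np.ndarray
    advance: np.ndarray
    h: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if np.any(m < -1e-15):
            raise ValueError("transition probabilities must be non-negative")


def build_transition_prior(nodes: NodeSet, h: float) -> TransitionPrior:
    """Build the adjusted change-point prior for a node set.

    For spacing s_i = l_{i+1} - l_i >= 1 the advance probability 1/s_i makes
    the expected no-change run-length increase exactly 1; for s_i < 1 the
    advance probability is capped at 1 (the expected increase is then
    under-matched, the closest achievable).
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError("hazard must lie in [0, 1]")
    l = nodes.run_lengths
    n = len(l)
    spacing = np.diff(l)
    advance = np.minimum(1.0 / spacing, 1.0) if n > 1 else np.empty(0)
    g = np.zeros((n, n))
    for i in range(n - 1):
        g[i, i + 1] = advance[i]
        g[i, i] = 1.0 - advance[i]
    g[n - 1, n - 1] = 1.0
    m = (1.0 - h) * g
    m[:, 0] += h
    return TransitionPrior(matrix=m, advance=advance, h=h)


@dataclass
class ReducedModelState:
    """Per-node Delta-rule statistic means and node weights.

    Arrays have shape ``(..., N)``; leading axes are batch axes.
    """

    mu: np.ndarray
    w: np.ndarray


class ReducedModel:
    """N-node mixture of fixed-learning-rate Delta rules."""

    def __init__(
        self,
        family: ExponentialFamily,
        nodes: NodeSet,
        h: float,
    ):
        family.validate_prior(nodes.chi0, nodes.nu0)
        self.family = family
        self.nodes = nodes
        self.h = float(h)
        self.prior = build_transition_prior(nodes, h)
        self.alpha = nodes.learning_rates
        self.nu_eff = nodes.run_lengths + nodes.nu0  # effective counts for likelihoods

    # ------------------------------------------------------------------
    def init_state(self, batch_shape: tuple[int, ...] = ()) -> ReducedModelState:
        """Node means at the prior mean; all weight on the shortest node."""
        n = self.nodes.n_nodes
        mu = np.full(batch_shape + (n,), self.nodes.chi0 / self.nodes.nu0)
        w = np.zeros(batch_shape + (n,))
        w[..., 0] = 1.0
        return ReducedModelState(mu=mu, w=w)

    def node_log_likelihood(self, state: ReducedModelState, x) -> np.ndarray:
        """Per-node predictive log likelihood of x (conjugate predictive with
        effective count nu0 + l_i and statistic implied by mu_i)."""
        x = np.asarray(x, dtype=float)
        return self.family.log_predictive(
            state.mu * self.nu_eff, self.nu_eff, x[..., None]
        )

    def step(self, state: ReducedModelState, x) -> ReducedModelState:
        """One observation: Bayes-reweight, propagate, Delta-rule-update."""
        x = np.asarray(x, dtype=float)
        self.family.check_support(x)
        logpred = self.node_log_likelihood(state, x)
        shift = np.max(logpred, axis=-1, keepdims=True)
        v = state.w * np.exp(logpred - shift)
        tot = v.sum(axis=-1)
        if np.any(tot == 0.0) or np.any(~np.isfinite(tot)):
            raise NumericalError(
                f"all node likelihoods vanished for observation {x!r}"
            )
        w_new = v @ self.prior.matrix
        w_new /= w_new.sum(axis=-1, keepdims=True)
        u = np.asarray(self.family.sufficient_stat(x), dtype=float)
        mu_new = state.mu + self.alpha * (u[..., None] - state.mu)
        return ReducedModelState(mu=mu_new, w=w_new)

    # ------------------------------------------------------------------
    def predict_mean(self, state: ReducedModelState) -> np.ndarray:
        """Weighted-node point estimate of the tracked parameter."""
        est = self.family.param_estimate(state.mu)
        return np.sum(state.w * est, axis=-1)

    def run(self, x: np.ndarray, return_weights: bool = False):
        """Filter a sequence (or batch, shape ``(..., T)``).

        ``preds[..., t]`` is the prediction for ``x[..., t]`` made before
        observing it; ``preds[..., 0]`` is the prior estimate.
        """
        x = np.asarray(x, dtype=float)
        T = x.shape[-1]
        batch_shape = x.shape[:-1]
        state = self.init_state(batch_shape)
        preds = np.empty(x.shape)
        n = self.nodes.n_nodes
        weights = np.empty(batch_shape + (T, n)) if return_weights else None
        for t in range(T):
            preds[..., t] = self.predict_mean(state)
            state = self.step(state, x[..., t])
            if return_weights:
                weights[..., t, :] = state.w
        if return_weights:
            return preds, state, weights
        return preds, state


def effective_learning_rate(
    predictions: np.ndarray, x: np.ndarray, atol: float = 1e-8
) -> np.ndarray:
    """Trial-by-trial learning rates implied by a prediction sequence.

    With ``predictions[t]`` the prediction for ``x[t]`` (made before observing
    it), inverts the Delta rule:

        alpha_t = (predictions[t+1] - predictions[t]) / (x[t] - predictions[t])

    Entries where the prediction error magnitude is below ``atol`` are NaN
    (the learning rate is undefined without a prediction error).
    """
    p = np.asarray(predictions, dtype=float)
    x = np.asarray(x, dtype=float)
    if p.shape != x.shape:
        raise ValueError("predictions and observations must be aligned")
    err = x[..., :-1] - p[..., :-1]
    num = p[..., 1:] - p[..., :-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = num / err
    return np.where(np.abs(err) < atol, np.nan, alpha)
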