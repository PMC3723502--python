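"""Monte-Carlo error analysis and node-placement optimization.

Quantifies how well the reduced model tracks the generative parameter: the
error is the mean, over simulated time series and time, of the squared
difference between the model's one-step-ahead estimate and the generative
parameter of the predicted trial.  The relative error divides by the prior
variance of the tracked parameter -- the error of an observer who always
reports the prior mean -- so a value of 1 marks the zero-learning limit.

Node placements (equivalently learning rates) are optimized by multi-start
local search on a common-random-numbers objective: the simulated sequences are
fixed by the seed, so the objective is a deterministic, smooth function of the
learning rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .families import ExponentialFamily
from .generative import sample_dataset_batch
from .reduced_model import NodeSet, ReducedModel

__all__ = [
    "ErrorEstimate",
    "NodeOptimum",
    "estimate_error",
    "optimize_nodes",
    "alpha_to_run_length",
    "run_length_to_alpha",
]


@dataclass(frozen=True)
class ErrorEstimate:
    """Monte-Carlo mean squared error of the reduced model vs ground truth."""

    E: float
    E_rel: float
    mc_se: float
    mc_se_rel: float
    n_reps: int
    T: int

    def __post_init__(self) -> None:
        if self.E < 0 or self.E_rel < 0 or self.mc_se < 0:
            raise ValueError("error estimates must be non-negative")


@dataclass(frozen=True)
class NodeOptimum:
    """Result of node-placement optimization."""

    run_lengths: np.ndarray       # ascending
    learning_rates: np.ndarray    # descending, alpha_i = 1/(l_i + nu0)
    estimate: ErrorEstimate
    converged: bool


def alpha_to_run_length(alpha, nu0: float):
    """Invert alpha = 1/(l + nu0); requires alpha < 1/nu0."""
    alpha = np.asarray(alpha, dtype=float)
    return 1.0 / alpha - nu0


def run_length_to_alpha(l, nu0: float):
    return 1.0 / (np.asarray(l, dtype=float) + nu0)


def _separate(l: np.ndarray) -> np.ndarray:
    """Force strict ordering of run-lengths with negligible bumps."""
    l = np.sort(np.asarray(l, dtype=float))
    for i in range(1, len(l)):
        if l[i] <= l[i - 1]:
            l[i] = l[i - 1] * (1.0 + 1e-9) + 1e-9
    return l


def _mse_on_data(
    run_lengths: np.ndarray,
    family: ExponentialFamily,
    prior: tuple[float, float],
    h: float,
    x: np.ndarray,
    theta: np.ndarray,
    burn_in: int,
) -> np.ndarray:
    """Per-replicate mean squared error of the reduced model on fixed data."""
    chi0, nu0 = prior
    model = ReducedModel(family, NodeSet(run_lengths, chi0, nu0), h)
    preds, _ = model.run(x)
    lo = max(1, burn_in)  # preds[:, 0] is data-free (prior estimate)
    err = (preds[:, lo:] - theta[:, lo:]) ** 2
    return err.mean(axis=1)


def estimate_error(
    nodes,
    family: ExponentialFamily,
    prior: tuple[float, float],
    h: float,
    T: int = 1000,
    n_reps: int = 20,
    seed=0,
    burn_in: int = 0,
) -> ErrorEstimate:
    """Monte-Carlo estimate of the reduced model's (relative) squared error.

    ``nodes`` may be a :class:`NodeSet` or an array of run-lengths.  ``burn_in``
    drops the first steps of each replicate from the average (useful when
    comparing with stationary closed forms).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    chi0, nu0 = prior
    if isinstance(nodes, NodeSet):
        run_lengths = nodes.run_lengths
    else:
        run_lengths = np.atleast_1d(np.asarray(nodes, dtype=float))
    x, theta, _ = sample_dataset_batch(family, prior, h, T, n_reps, seed)
    rep_means = _mse_on_data(run_lengths, family, prior, h, x, theta, burn_in)
    E = float(rep_means.mean())
    mc_se = float(rep_means.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    var_p = family.param_prior_var(chi0, nu0)
    return ErrorEstimate(
        E=E, E_rel=E / var_p, mc_se=mc_se, mc_se_rel=mc_se / var_p,
        n_reps=n_reps, T=T,
    )


def optimize_nodes(
    n_nodes: int,
    family: ExponentialFamily,
    prior: tuple[float, float],
    h: float,
    bounds: tuple[float, float] = (1e-3, 1.0),
    seed=0,
    T: int = 1000,
    n_reps: int = 20,
    n_starts: int = 8,
    burn_in: int = 0,
) -> NodeOptimum:
    """Optimize node run-lengths by minimizing the Monte-Carlo relative error.

    Search is over learning rates alpha in ``bounds`` (intersected with the
    feasible range alpha < 1/nu0 implied by positive run-lengths), with a
    common-random-numbers objective and ``n_starts`` local searches.
    """
    if n_nodes not in (1, 2, 3):
        raise ValueError("n_nodes must be 1, 2 or 3")
    chi0, nu0 = prior
    var_p = family.param_prior_var(chi0, nu0)
    lo = max(bounds[0], 1e-4)
    hi = min(bounds[1], 1.0, (1.0 / nu0) * (1.0 - 1e-6))
    if not lo < hi:
        raise ValueError("empty learning-rate search interval")
    x, theta, _ = sample_dataset_batch(family, prior, h, T, n_reps, seed)

    min_gap = 1e-4

    def objective(alphas: np.ndarray) -> float:
        a = np.sort(np.asarray(alphas, dtype=float))[::-1]
        penalty = 0.0
        a_cl = np.clip(a, lo, hi)
        penalty += 1e3 * float(np.sum((a - a_cl) ** 2))
        for i in range(len(a_cl) - 1):
            if a_cl[i] - a_cl[i + 1] < min_gap:
                gap = a_cl[i] - a_cl[i + 1]
                penalty += 10.0 * (min_gap - gap)
                a_cl[i + 1] = max(lo, a_cl[i] - min_gap)
        l = _separate(alpha_to_run_length(a_cl, nu0))
        rep = _mse_on_data(l, family, prior, h, x, theta, burn_in)
        return float(rep.mean()) / var_p + penalty

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 17]))
    log_lo, log_hi = np.log(lo), np.log(hi)
    starts = [np.exp(rng.uniform(log_lo, log_hi, size=n_nodes)) for _ in range(n_starts)]
    # one deterministic, well-spread start
    starts[0] = np.exp(np.linspace(log_hi - 0.2, log_lo + 0.2, n_nodes))

    best_val, best_a, converged = np.inf, None, False
    for s in starts:
        res = optimize.minimize(
            objective,
            np.sort(s)[::-1],
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
        )
        if res.fun < best_val:
            best_val, best_a = res.fun, np.sort(np.clip(res.x, lo, hi))[::-1]
            converged = bool(res.success)

    for i in range(len(best_a) - 1):
        if best_a[i] - best_a[i + 1] < min_gap:
            best_a[i + 1] = max(lo, best_a[i] - min_gap)
    l_opt = _separate(alpha_to_run_length(best_a, nu0))
    rep = _mse_on_data(l_opt, family, prior, h, x, theta, burn_in)
    E = float(rep.mean())
    mc_se = float(rep.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    est = ErrorEstimate(
        E=E, E_rel=E / var_p, mc_se=mc_se, mc_se_rel=mc_se / var_p,
        n_reps=n_reps, T=T,
    )
    return NodeOptimum(
        run_lengths=l_opt,
        learning_rates=np.sort(run_length_to_alpha(l_opt, nu0))[::-1],
        estimate=est,
        converged=converged,
    )
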