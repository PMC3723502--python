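"""Fitting candidate models to subject predictions and comparing them.

Subjects (here always synthetic) observe the prediction-task number sequence
and report a prediction before every trial.  Reports are modelled as the
candidate model's prediction plus Gaussian decision noise sigma_n.  For each
candidate, maximum-likelihood parameters are found with sigma_n profiled out
in closed form (its MLE is the residual RMS), model evidence is approximated
by BIC, and models are compared at the group level with random-effects
Bayesian model selection (variational Dirichlet-multinomial estimation of
model frequencies plus Monte-Carlo exceedance probabilities).

The model set is {full, reduced-1, reduced-2, reduced-3}; free parameters are
hazard + noise for the full model, one rate + noise for the 1-node model, and
hazard + N rates + noise for N >= 2 nodes.  Model predictions entering the
likelihood depend only on the observed number sequence, never on the
subject's own reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .families import GaussianMean
from .full_model import FullModel
from .generative import ChangePointDataset, TaskConfig, generate_task
from .reduced_model import NodeSet, ReducedModel

__all__ = [
    "MODEL_IDS",
    "SubjectData",
    "FitResult",
    "BMSResult",
    "model_predictions",
    "simulate_subject",
    "loglik",
    "fit",
    "group_bms",
    "confusion_matrices",
    "draw_params",
]

MODEL_IDS = ("full", "reduced-1", "reduced-2", "reduced-3")

# Gaussian stand-in for the task's uniform-[40, 260] prior on the mean:
# matched mean and variance (sd of U[a, b] is (b - a)/sqrt(12)).
TASK_PRIOR_MEAN = 150.0
TASK_PRIOR_SD = 220.0 / np.sqrt(12.0)
DEFAULT_R_MAX = 120


@dataclass
class SubjectData:
    """Observed numbers, reported predictions, and per-trial task noise sd."""

    x: np.ndarray
    predictions: np.ndarray
    noise_sd: np.ndarray
    bounds: tuple[float, float] = (0.0, 300.0)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.predictions = np.asarray(self.predictions, dtype=float)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if not (len(self.x) == len(self.predictions) == len(self.noise_sd)):
            raise ValueError("x, predictions and noise_sd must have equal length")
        lo, hi = self.bounds
        if np.any(self.predictions < lo) or np.any(self.predictions > hi):
            raise ValueError("reported predictions must lie within task bounds")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one model to one subject."""

    model_id: str
    params: dict
    log_lik: float
    bic: float
    k: int
    n_obs: int
    converged: bool = True

    @property
    def log_evidence(self) -> float:
        """BIC approximation to the log model evidence, -BIC/2."""
        return -0.5 * self.bic


@dataclass(frozen=True)
class BMSResult:
    """Group-level random-effects model comparison."""

    model_probability: np.ndarray
    exceedance_probability: np.ndarray
    dirichlet_alpha: np.ndarray
    subject_posteriors: np.ndarray  # subjects x models


def n_free_params(model_id: str) -> int:
    """Free parameters including decision noise."""
    return {"full": 2, "reduced-1": 2, "reduced-2": 4, "reduced-3": 5}[model_id]


def _model_n_nodes(model_id: str) -> int:
    return int(model_id.split("-")[1])


def _block_slices(noise_sd: np.ndarray):
    """Contiguous runs of constant noise sd (the task's blocks)."""
    noise_sd = np.asarray(noise_sd, dtype=float)
    edges = np.flatnonzero(np.diff(noise_sd) != 0) + 1
    starts = np.concatenate(([0], edges))
    stops = np.concatenate((edges, [len(noise_sd)]))
    return list(zip(starts, stops))


def _reduced_gauss_block(
    x: np.ndarray, sigma: float, h: float, alphas_desc: np.ndarray,
    chi0: float, nu0: float,
) -> np.ndarray:
    """Tight scalar loop for the reduced model on one Gaussian task block.

    Identical to ``ReducedModel.run`` (asserted in the test suite) but avoids
    per-step array bookkeeping; the inner loop of every likelihood evaluation
    during fitting runs through here.
    """
    from math import exp, log, pi

    a = [float(v) for v in alphas_desc]
    n = len(a)
    l = sorted(1.0 / ai - nu0 for ai in a)
    # effective count nu0 + l_i equals 1/alpha_i by construction
    var = [sigma**2 * (1.0 + ai) for ai in sorted(a, reverse=True)]
    c = [-0.5 * log(2.0 * pi * v) for v in var]
    inv2 = [0.5 / v for v in var]
    alpha = sorted(a, reverse=True)  # node 0 = shortest run-length = largest rate
    if n > 1:
        adv = [
            1.0 if (s := l[i + 1] - l[i]) <= 1.0 else 1.0 / s for i in range(n - 1)
        ]
    else:
        adv = []
    mu = [chi0 / nu0] * n
    w = [1.0] + [0.0] * (n - 1)
    T = len(x)
    preds = np.empty(T)
    for t in range(T):
        preds[t] = sum(wi * mi for wi, mi in zip(w, mu))
        xt = float(x[t])
        d = [xt - mi for mi in mu]
        lp = [ci - di * di * iv for ci, di, iv in zip(c, d, inv2)]
        m = max(lp)
        v = [wi * exp(li - m) for wi, li in zip(w, lp)]
        if n > 1:
            new = [0.0] * n
            for i in range(n):
                new[0] += h * v[i]
                stay = (1.0 - h) * v[i]
                if i < n - 1:
                    new[i + 1] += stay * adv[i]
                    new[i] += stay * (1.0 - adv[i])
                else:
                    new[i] += stay
            s = sum(new)
            w = [wi / s for wi in new]
        mu = [mi + ai * di for mi, ai, di in zip(mu, alpha, d)]
    return preds


def model_predictions(
    model_id: str,
    params: dict,
    x: np.ndarray,
    noise_sd: np.ndarray,
    r_max: int = DEFAULT_R_MAX,
) -> np.ndarray:
    """Deterministic per-trial predictions of a candidate model.

    ``preds[t]`` is the model's prediction of ``x[t]`` from ``x[:t]``; the
    model state is reset at every block boundary.  ``params`` holds ``h``
    (hazard, absent for reduced-1) and/or ``alphas`` (descending learning
    rates for reduced models).
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}")
    x = np.asarray(x, dtype=float)
    preds = np.empty_like(x)
    for start, stop in _block_slices(noise_sd):
        sigma = float(noise_sd[start])
        family, chi0, nu0 = GaussianMean.from_mean_prior(
            sigma, TASK_PRIOR_MEAN, TASK_PRIOR_SD
        )
        if model_id == "full":
            model = FullModel(family, chi0, nu0, h=float(params["h"]), r_max=r_max)
            preds[start:stop], _ = model.run(x[start:stop])
        else:
            n = _model_n_nodes(model_id)
            alphas = np.sort(np.asarray(params["alphas"], dtype=float))[::-1]
            if len(alphas) != n:
                raise ValueError(f"{model_id} needs {n} learning rates")
            h = 0.0 if n == 1 else float(params["h"])
            preds[start:stop] = _reduced_gauss_block(
                x[start:stop], sigma, h, alphas, chi0, nu0
            )
    return preds


def simulate_subject(
    model_id: str,
    params: dict,
    task: ChangePointDataset,
    sigma_n: float,
    seed,
    r_max: int = DEFAULT_R_MAX,
) -> SubjectData:
    """Simulate a subject: model predictions plus truncated Gaussian report noise."""
    if task.noise_sd is None:
        raise ValueError("task dataset must carry per-trial noise_sd")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    preds = model_predictions(model_id, params, task.x, task.noise_sd, r_max=r_max)
    reports = preds + rng.normal(0.0, sigma_n, size=len(preds))
    reports = np.clip(reports, 0.0, 300.0)
    return SubjectData(x=task.x, predictions=reports, noise_sd=task.noise_sd)


def loglik(
    model_id: str,
    params: dict,
    subject: SubjectData,
    r_max: int = DEFAULT_R_MAX,
) -> float:
    """Gaussian log likelihood of the subject's reports under a model.

    ``params`` must include ``sigma_n``.  The noise is an untruncated Gaussian
    even though simulated reports are clipped to the task bounds (the bias is
    negligible away from the bounds).
    """
    sigma_n = float(params["sigma_n"])
    if sigma_n <= 0:
        raise ValueError("sigma_n must be > 0")
    if "h" in params and not 0.0 <= params["h"] <= 1.0:
        raise ValueError("hazard must lie in [0, 1]")
    if "alphas" in params and not np.all(
        (np.asarray(params["alphas"]) > 0) & (np.asarray(params["alphas"]) <= 1)
    ):
        raise ValueError("learning rates must lie in (0, 1]")
    preds = model_predictions(model_id, params, subject.x, subject.noise_sd, r_max=r_max)
    resid = subject.predictions - preds
    n = len(resid)
    return float(
        -0.5 * n * np.log(2.0 * np.pi * sigma_n**2)
        - 0.5 * np.sum(resid**2) / sigma_n**2
    )


# ----------------------------------------------------------------------
# maximum-likelihood fitting with sigma_n profiled out
# ----------------------------------------------------------------------

_H_BOUNDS = (0.005, 0.95)
_ALPHA_BOUNDS = (0.02, 1.0)
_MIN_ALPHA_GAP = 1e-3


def _profiled_nll(model_id: str, theta: np.ndarray, subject: SubjectData, r_max: int):
    """Negative log likelihood with sigma_n at its closed-form optimum."""
    params = _theta_to_params(model_id, theta)
    preds = model_predictions(model_id, params, subject.x, subject.noise_sd, r_max=r_max)
    resid = subject.predictions - preds
    n = len(resid)
    sigma = max(float(np.sqrt(np.mean(resid**2))), 1e-6)
    nll = 0.5 * n * (np.log(2.0 * np.pi * sigma**2) + 1.0)
    return nll, sigma


def _theta_to_params(model_id: str, theta: np.ndarray) -> dict:
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if model_id == "full":
        return {"h": float(theta[0])}
    if model_id == "reduced-1":
        return {"alphas": np.array([float(theta[0])])}
    return {"h": float(theta[0]), "alphas": np.sort(theta[1:])[::-1]}


def _penalized(model_id: str, theta: np.ndarray, subject: SubjectData, r_max: int) -> float:
    """Objective for the unconstrained optimizer: clip + quadratic penalty."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    penalty = 0.0
    clipped = theta.copy()
    if model_id == "full":
        clipped[0] = np.clip(theta[0], *_H_BOUNDS)
    elif model_id == "reduced-1":
        clipped[0] = np.clip(theta[0], *_ALPHA_BOUNDS)
    else:
        clipped[0] = np.clip(theta[0], *_H_BOUNDS)
        clipped[1:] = np.clip(theta[1:], *_ALPHA_BOUNDS)
        a = np.sort(clipped[1:])[::-1]
        for i in range(len(a) - 1):
            if a[i] - a[i + 1] < _MIN_ALPHA_GAP:
                penalty += 50.0 * (_MIN_ALPHA_GAP - (a[i] - a[i + 1]))
                a[i + 1] = max(_ALPHA_BOUNDS[0], a[i] - _MIN_ALPHA_GAP)
        clipped[1:] = a
    penalty += 1e4 * float(np.sum((theta - clipped) ** 2))
    nll, _ = _profiled_nll(model_id, clipped, subject, r_max)
    return nll + penalty


def _fit_1d(model_id, subject, bounds, r_max, n_grid=14):
    """Deterministic grid scan plus bounded local polish for 1-parameter models."""
    grid = np.geomspace(bounds[0], bounds[1], n_grid)
    vals = [_profiled_nll(model_id, np.array([g]), subject, r_max)[0] for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda g: _profiled_nll(model_id, np.array([g]), subject, r_max)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-4},
    )
    best = res.x if res.fun <= vals[i] else grid[i]
    return np.array([best]), True


def _fit_multi(model_id, subject, r_max, n_starts, seed):
    """Multi-start Nelder-Mead for (h, alphas) models; deterministic restart seeds."""
    n = _model_n_nodes(model_id)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 101]))
    heuristics = {
        2: [np.array([0.25, 0.95, 0.5]), np.array([0.1, 0.8, 0.3])],
        3: [np.array([0.15, 0.95, 0.8, 0.5]), np.array([0.3, 0.9, 0.5, 0.2])],
    }[n]
    starts = list(heuristics)
    while len(starts) < n_starts:
        h0 = rng.uniform(0.02, 0.6)
        a0 = np.sort(rng.uniform(0.05, 1.0, size=n))[::-1]
        starts.append(np.concatenate(([h0], a0)))
    best_val, best_theta, ok = np.inf, None, False
    for s in starts[:n_starts]:
        res = optimize.minimize(
            lambda th: _penalized(model_id, th, subject, r_max),
            s,
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-3, "maxiter": 300},
        )
        if res.fun < best_val:
            best_val, best_theta, ok = res.fun, res.x, bool(res.success)
    theta = np.atleast_1d(best_theta)
    theta[0] = np.clip(theta[0], *_H_BOUNDS)
    theta[1:] = np.clip(theta[1:], *_ALPHA_BOUNDS)
    a = np.sort(theta[1:])[::-1]
    for i in range(len(a) - 1):
        if a[i] - a[i + 1] < _MIN_ALPHA_GAP:
            a[i + 1] = max(_ALPHA_BOUNDS[0], a[i] - _MIN_ALPHA_GAP)
    theta[1:] = a
    return theta, ok


def fit(
    model_id: str,
    subject: SubjectData,
    n_starts: int = 8,
    seed: int = 0,
    r_max: int = DEFAULT_R_MAX,
) -> FitResult:
    """Maximum-likelihood fit of one model to one subject, with BIC."""
    k = n_free_params(model_id)
    n = len(subject)
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} trials to fit {model_id}")
    if model_id == "full":
        theta, ok = _fit_1d("full", subject, _H_BOUNDS, r_max)
    elif model_id == "reduced-1":
        theta, ok = _fit_1d("reduced-1", subject, _ALPHA_BOUNDS, r_max)
    else:
        theta, ok = _fit_multi(model_id, subject, r_max, n_starts, seed)
    nll, sigma = _profiled_nll(model_id, theta, subject, r_max)
    params = _theta_to_params(model_id, theta)
    params["sigma_n"] = sigma
    log_lik = -nll
    bic = -2.0 * log_lik + k * np.log(n)
    return FitResult(
        model_id=model_id, params=params, log_lik=log_lik, bic=float(bic),
        k=k, n_obs=n, converged=ok,
    )


# ----------------------------------------------------------------------
# group-level random-effects model selection
# ----------------------------------------------------------------------

def group_bms(
    log_evidence: np.ndarray,
    alpha0: float = 1.0,
    n_samples: int = 100_000,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> BMSResult:
    """Random-effects model selection from a subjects-by-models evidence matrix.

    Variational Dirichlet-multinomial estimation of model frequencies; the
    exceedance probability (chance each model is the most frequent in the
    population) is computed from Dirichlet posterior samples.
    """
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[0] < 2 or L.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 models")
    S, M = L.shape
    alpha = np.full(M, float(alpha0))
    u = np.zeros((S, M))
    from scipy.special import digamma

    for _ in range(max_iter):
        ln_u = L + digamma(alpha) - digamma(alpha.sum())
        ln_u -= ln_u.max(axis=1, keepdims=True)
        u = np.exp(ln_u)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    r = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=M) / n_samples
    return BMSResult(
        model_probability=r,
        exceedance_probability=xp,
        dirichlet_alpha=alpha,
        subject_posteriors=u,
    )


# ----------------------------------------------------------------------
# model-recovery confusion matrices
# ----------------------------------------------------------------------

# Group-mean parameter values typical of human subjects on this task, used as
# the centres of the generating-parameter pools for recovery simulations.
# Spreads are half the between-subject sd, and clips keep draws
# out of degenerate corners (a 2-node subject with both rates near each other
# or a rate pinned at 1 is behaviourally a 1-node subject, so drawing such
# parameters would make the recovery question ill-posed rather than hard).
_TABLE_POOLS = {
    "full": {"h": (0.04, 0.027, 0.01, 0.3), "sigma_n": (20.22, 1.45, 10.0, 28.0)},
    "reduced-1": {"alphas": [(0.88, 0.03, 0.5, 0.98)],
                  "sigma_n": (8.7, 2.0, 4.0, 12.0)},
    "reduced-2": {"h": (0.27, 0.11, 0.05, 0.45),
                  "alphas": [(0.94, 0.03, 0.8, 0.98), (0.53, 0.08, 0.3, 0.68)],
                  "sigma_n": (7.26, 1.8, 4.0, 11.0)},
    "reduced-3": {"h": (0.12, 0.08, 0.05, 0.45),
                  "alphas": [(0.96, 0.03, 0.85, 0.98), (0.82, 0.08, 0.6, 0.9),
                             (0.52, 0.08, 0.25, 0.65)],
                  "sigma_n": (6.97, 1.8, 4.0, 11.0)},
}


def draw_params(model_id: str, rng: np.random.Generator) -> tuple[dict, float]:
    """Draw generating parameters (params dict, sigma_n) from the fitted pools."""
    pool = _TABLE_POOLS[model_id]
    params: dict = {}

    def tnorm(m, sd, lo, hi):
        return float(np.clip(rng.normal(m, sd), lo, hi))

    if "h" in pool:
        params["h"] = tnorm(*pool["h"])
    if "alphas" in pool:
        a = np.array([tnorm(*spec) for spec in pool["alphas"]])
        a = np.sort(a)[::-1]
        for i in range(len(a) - 1):
            if a[i] - a[i + 1] < 0.1:
                a[i + 1] = max(0.05, a[i] - 0.1)
        params["alphas"] = a
    sigma_n = tnorm(*pool["sigma_n"])
    return params, sigma_n


def confusion_matrices(
    model_ids=MODEL_IDS,
    n_subjects: int = 8,
    task_cfg: TaskConfig | None = None,
    n_blocks: int = 2,
    seed: int = 0,
    fit_starts: int = 4,
    r_max: int = DEFAULT_R_MAX,
) -> tuple[np.ndarray, np.ndarray]:
    """Model-recovery confusion matrices (model probability, exceedance).

    For each generating model, simulate ``n_subjects`` subjects with
    parameters drawn from the fitted pools, refit every candidate, and
    aggregate with group BMS.  Rows = generating model, columns = fitted.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects per generating model")
    cfg = task_cfg or TaskConfig()
    model_ids = list(model_ids)
    M = len(model_ids)
    mp = np.zeros((M, M))
    ep = np.zeros((M, M))
    for gi, gen in enumerate(model_ids):
        evidence = []
        for s in range(n_subjects):
            child = np.random.SeedSequence([seed, gi, s])
            rng = np.random.default_rng(child)
            task = generate_task(cfg, n_blocks, rng)
            params, sigma_n = draw_params(gen, rng)
            subject = simulate_subject(gen, params, task, sigma_n, rng, r_max=r_max)
            row = []
            for fm in model_ids:
                try:
                    res = fit(fm, subject, n_starts=fit_starts, seed=seed + s, r_max=r_max)
                    row.append(res.log_evidence)
                except Exception as exc:  # pragma: no cover - defensive
                    warnings.warn(f"fit of {fm} to a {gen} subject failed: {exc}")
                    row.append(np.nan)
            if np.all(np.isfinite(row)):
                evidence.append(row)
        bms = group_bms(np.asarray(evidence), seed=seed + 7 * gi)
        mp[gi] = bms.model_probability
        ep[gi] = bms.exceedance_probability
    return mp, ep
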