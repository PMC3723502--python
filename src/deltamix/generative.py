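"""Simulation of change-point processes and the behavioral prediction task.

A change-point process alternates 'epochs' within which the generative
parameter is constant; epoch boundaries are drawn from a Bernoulli hazard,
optionally with a refractory period that forbids changes for a fixed number of
steps after each change.  The behavioral task generator reproduces the
predictive-inference task structure: numbers in [0, 300] drawn around means
that are resampled (uniformly in [40, 260]) at change-points with hazard 0.1
and a 3-trial refractory period, with block-wise constant noise sd of 5 or 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .families import ExponentialFamily, FamilyError, GaussianMean, get_family

__all__ = [
    "HazardSpec",
    "ChangePointDataset",
    "TaskConfig",
    "sample_changepoints",
    "sample_dataset",
    "sample_dataset_batch",
    "generate_task",
    "benchmarks",
]

_RESAMPLE_CAP = 10_000


@dataclass(frozen=True)
class HazardSpec:
    """Per-step change probability ``h`` with an optional refractory period.

    During the ``refractory`` steps following a change-point (including the
    start of the sequence) the effective hazard is zero.
    """

    h: float
    refractory: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"hazard rate must lie in [0, 1], got {self.h}")
        if self.refractory < 0:
            raise ValueError(f"refractory must be >= 0, got {self.refractory}")


@dataclass
class ChangePointDataset:
    """Observations with their generative parameters and change-point marks."""

    x: np.ndarray
    theta_true: np.ndarray
    cp: np.ndarray
    family_id: str
    noise_sd: np.ndarray | None = None  # per-trial observation sd (task data only)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.theta_true = np.asarray(self.theta_true, dtype=float)
        self.cp = np.asarray(self.cp, dtype=bool)
        if not (len(self.x) == len(self.theta_true) == len(self.cp)):
            raise ValueError("x, theta_true and cp must have equal length")
        if self.noise_sd is not None:
            self.noise_sd = np.asarray(self.noise_sd, dtype=float)
            if len(self.noise_sd) != len(self.x):
                raise ValueError("noise_sd must match x in length")

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t": np.arange(len(self.x)),
                "x": self.x,
                "theta_true": self.theta_true,
                "cp": self.cp.astype(int),
            }
        )
        if self.noise_sd is not None:
            df["noise_sd"] = self.noise_sd
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, family_id: str) -> "ChangePointDataset":
        noise = df["noise_sd"].to_numpy() if "noise_sd" in df.columns else None
        return cls(
            x=df["x"].to_numpy(),
            theta_true=df["theta_true"].to_numpy(),
            cp=df["cp"].to_numpy().astype(bool),
            family_id=family_id,
            noise_sd=noise,
        )


@dataclass(frozen=True)
class TaskConfig:
    """Configuration of the behavioral prediction task."""

    n_trials: int = 200
    noise_sd: tuple[float, ...] = (5.0, 10.0)
    mean_range: tuple[float, float] = (40.0, 260.0)
    sample_bounds: tuple[float, float] = (0.0, 300.0)
    hazard: HazardSpec = field(default_factory=lambda: HazardSpec(0.1, refractory=3))

    def __post_init__(self) -> None:
        lo, hi = self.mean_range
        blo, bhi = self.sample_bounds
        if not (blo <= lo < hi <= bhi):
            raise ValueError("mean_range must be contained in sample_bounds")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_changepoints(T: int, hz: HazardSpec, seed) -> np.ndarray:
    """Boolean change-point indicators of length T.

    Position 0 is always an epoch start.  For t >= 1 a change occurs with
    probability ``hz.h`` unless fewer than ``hz.refractory`` steps have passed
    since the previous change-point.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = _as_rng(seed)
    cp = np.zeros(T, dtype=bool)
    cp[0] = True
    u = rng.random(T)
    last = 0
    for t in range(1, T):
        if t - last <= hz.refractory:
            continue
        if u[t] < hz.h:
            cp[t] = True
            last = t
    return cp


def sample_dataset(
    family: ExponentialFamily,
    prior: tuple[float, float],
    hz: HazardSpec,
    T: int,
    seed,
    cp: np.ndarray | None = None,
) -> ChangePointDataset:
    """Simulate one change-point sequence from a family and its conjugate prior.

    The parameter is drawn from the prior at position 0 and redrawn at every
    change-point (``cp`` may be supplied to force change-point locations).
    """
    chi0, nu0 = prior
    family.validate_prior(chi0, nu0)
    rng = _as_rng(seed)
    if cp is None:
        cp = sample_changepoints(T, hz, rng)
    else:
        cp = np.asarray(cp, dtype=bool).copy()
        if len(cp) != T:
            raise ValueError("forced cp must have length T")
        cp[0] = True
    theta = np.empty(T)
    cur = np.nan
    for t in range(T):
        if cp[t]:
            cur = float(family.sample_param(chi0, nu0, rng))
        theta[t] = cur
    x = family.sample_obs(theta, rng)
    return ChangePointDataset(x=x, theta_true=theta, cp=cp, family_id=family.family_id)


def sample_dataset_batch(
    family: ExponentialFamily,
    prior: tuple[float, float],
    h: float,
    T: int,
    n_reps: int,
    seed,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized batch of change-point sequences (refractory 0).

    Returns ``(x, theta, cp)`` arrays of shape (n_reps, T).  Used by the
    Monte-Carlo error estimator where many replicates are needed.
    """
    chi0, nu0 = prior
    family.validate_prior(chi0, nu0)
    rng = _as_rng(seed)
    cp = rng.random((n_reps, T)) < h
    cp[:, 0] = True
    draws = np.asarray(family.sample_param(chi0, nu0, rng, size=(n_reps, T)))
    # index of the most recent change-point at or before t, per replicate
    idx = np.where(cp, np.arange(T)[None, :], 0)
    idx = np.maximum.accumulate(idx, axis=1)
    theta = np.take_along_axis(draws, idx, axis=1)
    x = family.sample_obs(theta, rng)
    return x, theta, cp


def generate_task(cfg: TaskConfig, n_blocks: int, seed) -> ChangePointDataset:
    """Generate a multi-block run of the behavioral prediction task.

    Blocks cycle through ``cfg.noise_sd``; within a block the noise sd is
    constant, means are uniform on ``cfg.mean_range`` and samples outside
    ``cfg.sample_bounds`` are redrawn until they fall inside.
    """
    rng = _as_rng(seed)
    lo, hi = cfg.mean_range
    blo, bhi = cfg.sample_bounds
    xs, thetas, cps, sds = [], [], [], []
    for b in range(n_blocks):
        sd = float(cfg.noise_sd[b % len(cfg.noise_sd)])
        cp = sample_changepoints(cfg.n_trials, cfg.hazard, rng)
        theta = np.empty(cfg.n_trials)
        cur = np.nan
        for t in range(cfg.n_trials):
            if cp[t]:
                cur = float(rng.uniform(lo, hi))
            theta[t] = cur
        x = rng.normal(theta, sd)
        out = (x < blo) | (x > bhi)
        tries = 0
        while np.any(out):
            tries += 1
            if tries > _RESAMPLE_CAP:
                raise RuntimeError("exceeded resampling cap for out-of-bounds samples")
            x[out] = rng.normal(theta[out], sd)
            out = (x < blo) | (x > bhi)
        xs.append(x)
        thetas.append(theta)
        cps.append(cp)
        sds.append(np.full(cfg.n_trials, sd))
    return ChangePointDataset(
        x=np.concatenate(xs),
        theta_true=np.concatenate(thetas),
        cp=np.concatenate(cps),
        family_id="gaussian_mean",
        noise_sd=np.concatenate(sds),
    )


def benchmarks(x: np.ndarray, theta_true: np.ndarray) -> tuple[float, float]:
    """Task benchmarks (LB, HB).

    LB is the mean absolute difference between successive outcomes; HB is the
    mean absolute difference between each outcome and the previous trial's
    generative mean (the error floor of an observer who knows the mean).
    """
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta_true, dtype=float)
    if len(x) < 2 or len(theta) != len(x):
        raise ValueError("need aligned sequences of length >= 2")
    lb = float(np.mean(np.abs(np.diff(x))))
    hb = float(np.mean(np.abs(theta[:-1] - x[1:])))
    return lb, hb
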