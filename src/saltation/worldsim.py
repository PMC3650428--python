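"""Generative world simulation: the biased percept is the calibrated estimator.

The simulation draws many two-tap trials from the world the observer's
prior assumes: the first tap position is uniform, the second is Gaussian
about the first with sd t*sigma_v (a zero-mean velocity draw), and each
position is measured with independent Gaussian noise of sd sigma_s. The
measured length l_m = x2m - x1m is an *unbiased* estimator of the true
length l (its conditional mean given l is l), yet it is miscalibrated:
the true lengths that produce a given l_m average to something smaller.
The observer's percept l* — the contracted l_m — is biased given l but
perfectly calibrated: trials on which the observer perceives 3 cm have
true lengths averaging 3 cm, with smaller spread than the measurement's.

Closed-form conditional variances (validated against the simulation):

    Var(l_m | l)  = 2 sigma_s^2
    Var(l | l_m)  = 2 sigma_s^2 (sigma_v t)^2 / (2 sigma_s^2 + (sigma_v t)^2)

and Var(l | l*) = Var(l | l_m) because l* is a deterministic function of l_m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observer import contract_length
from .params import ObserverParams

__all__ = [
    "WorldGenParams",
    "TrialBatch",
    "ConditionalStats",
    "sample_world",
    "conditional_stats",
    "theoretical_variances",
]


@dataclass(frozen=True)
class WorldGenParams:
    """Settings of the generative simulation.

    Defaults reproduce the standard forearm condition: sigma_s = 1 cm,
    sigma_v = 10 cm/s, inter-tap interval 0.15 s (so true lengths have sd
    t*sigma_v = 1.5 cm), one million trials.
    """

    n_trials: int = 1_000_000
    t: float = 0.15
    sigma_v: float = 10.0
    sigma_s: float = 1.0
    x1_range: tuple[float, float] = (0.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (self.t > 0 and self.sigma_v > 0 and self.sigma_s > 0):
            raise ValueError("t, sigma_v, sigma_s must be positive")
        if not self.x1_range[1] > self.x1_range[0]:
            raise ValueError("x1_range must be non-degenerate")


@dataclass(frozen=True)
class TrialBatch:
    """Per-trial true length l, measured length l_m, perceived length l_star (cm)."""

    l: np.ndarray
    l_m: np.ndarray
    l_star: np.ndarray
    params: WorldGenParams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.l.size),
                "l": self.l,
                "l_m": self.l_m,
                "l_star": self.l_star,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ConditionalStats:
    mean: float
    var: float
    n: int


def sample_world(p: WorldGenParams) -> TrialBatch:
    """Draw a reproducible batch of trials from the generative model.

    Positions are generated explicitly (x1 uniform; x2 Gaussian about x1
    with sd t*sigma_v; measurements with independent sd-sigma_s noise), so
    l_m = l + eps with eps ~ Normal(0, 2 sigma_s^2). The percept is the
    deterministic contraction of l_m.
    """
    rng = np.random.default_rng(p.seed)
    x1 = rng.uniform(*p.x1_range, size=p.n_trials)
    x2 = x1 + rng.normal(0.0, p.t * p.sigma_v, size=p.n_trials)
    x1m = x1 + rng.normal(0.0, p.sigma_s, size=p.n_trials)
    x2m = x2 + rng.normal(0.0, p.sigma_s, size=p.n_trials)
    l = x2 - x1
    l_m = x2m - x1m
    obs = ObserverParams(sigma_v=p.sigma_v, sigma_s_default=p.sigma_s)
    l_star = contract_length(l_m, p.t, obs)
    return TrialBatch(l=l, l_m=l_m, l_star=l_star, params=p)


_VARIABLES = ("l", "l_m", "l_star")


def conditional_stats(
    b: TrialBatch,
    condition_on: str,
    center: float,
    halfwidth: float = 0.05,
    report: str = "l",
    min_trials: int = 100,
) -> ConditionalStats:
    """Sample mean and variance of one variable conditioned on a window of another.

    Selects trials whose ``condition_on`` variable lies within
    ``center +/- halfwidth`` and reports the mean and variance of the
    ``report`` variable over them. Raises if fewer than ``min_trials``
    trials fall in the window.
    """
    for name in (condition_on, report):
        if name not in _VARIABLES:
            raise ValueError(f"unknown variable {name!r}; choose from {_VARIABLES}")
    cond = getattr(b, condition_on)
    mask = np.abs(cond - center) <= halfwidth
    n = int(mask.sum())
    if n < min_trials:
        raise ValueError(
            f"only {n} trials have {condition_on} in "
            f"[{center - halfwidth}, {center + halfwidth}]; need {min_trials}"
        )
    vals = getattr(b, report)[mask]
    return ConditionalStats(mean=float(vals.mean()), var=float(vals.var(ddof=1)), n=n)


def theoretical_variances(
    t: float, sigma_v: float, sigma_s: float
) -> tuple[float, float]:
    """Closed-form conditional variances (cm^2).

    Returns ``(Var(l_m | l), Var(l | l_m))``. The second also equals
    Var(l | l*) since the percept is a deterministic function of l_m, and
    is always the smaller of the two: the percept beats the measurement
    in mean-squared error.
    """
    if not (t > 0 and sigma_v > 0 and sigma_s > 0):
        raise ValueError("t, sigma_v, sigma_s must be positive")
    meas = 2.0 * sigma_s**2
    s = (sigma_v * t) ** 2
    post = meas * s / (meas + s)
    return meas, post
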