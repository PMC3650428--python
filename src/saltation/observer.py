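"""Two-tap Bayesian observer: closed-form percepts and the joint posterior.

Two taps at skin positions measured as (x1m, x2m), separated by an interval
t, are interpreted as a candidate trajectory (x1, x2). The observer combines
a Gaussian likelihood centered on the measurements with a zero-mean Gaussian
prior over the trajectory speed (x2 - x1)/t. Because both are Gaussian (and
the prior over absolute position is improper-uniform), the posterior over
(x1, x2) is a two-dimensional Gaussian whose mode has closed form.

The perceived length l* = x2* - x1* contracts relative to the measured
length l_m = x2m - x1m:

    l* = l_m / (1 + 2 (tau/t)^2)            equal spatial uncertainty
    l* = l_m / (1 + (s1^2 + s2^2)/(sigma_v t)^2)   unequal (attention)

where tau = sigma_s / sigma_v. Unequal per-tap uncertainty additionally
shifts the perceived midpoint toward the better-localized (attended) tap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ObserverParams

__all__ = [
    "TwoTapMeasurement",
    "JointPosterior2",
    "contract_length",
    "contract_length_general",
    "midpoint_shift",
    "two_tap_posterior",
    "equality_ratio",
]


def _check_interval(t: float) -> None:
    if not t > 0:
        raise ValueError(
            f"inter-stimulus interval must be positive (coincident or "
            f"out-of-order taps), got t={t}"
        )


@dataclass(frozen=True)
class TwoTapMeasurement:
    """Noisy position measurements of a two-tap sequence.

    ``x1m``/``x2m`` are the measured positions (cm) of the first and second
    tap on one skin axis, ``t`` the interval between them (s), and
    ``sigma_s1``/``sigma_s2`` the per-tap spatial uncertainties (cm).
    The measured length may be negative: sign encodes direction.
    """

    x1m: float
    x2m: float
    t: float
    sigma_s1: float
    sigma_s2: float

    def __post_init__(self) -> None:
        _check_interval(self.t)
        if not (self.sigma_s1 > 0 and self.sigma_s2 > 0):
            raise ValueError("per-tap sigma_s values must be positive")

    @property
    def l_m(self) -> float:
        """Measured trajectory length x2m - x1m, cm (signed)."""
        return self.x2m - self.x1m

    @classmethod
    def symmetric(
        cls, x1m: float, x2m: float, t: float, sigma_s: float
    ) -> "TwoTapMeasurement":
        return cls(x1m=x1m, x2m=x2m, t=t, sigma_s1=sigma_s, sigma_s2=sigma_s)


@dataclass(frozen=True)
class JointPosterior2:
    """Bivariate Gaussian posterior over the two tap positions.

    ``mean`` is the (x1*, x2*) percept (mode == mean for a Gaussian);
    ``cov`` its 2x2 covariance, cm^2.
    """

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if mean.shape != (2,) or cov.shape != (2, 2):
            raise ValueError("mean must be length 2, cov 2x2")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("covariance must be positive-definite")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)

    @property
    def perceived_length(self) -> float:
        """Perceived trajectory length l* = x2* - x1*, cm."""
        return float(self.mean[1] - self.mean[0])

    @property
    def midpoint(self) -> float:
        return float(0.5 * (self.mean[0] + self.mean[1]))

    def marginal(self, i: int) -> tuple[float, float]:
        """Mean and sd of the marginal posterior over tap ``i`` (0 or 1)."""
        return float(self.mean[i]), float(math.sqrt(self.cov[i, i]))


def contract_length(l_m: float, t: float, params: ObserverParams) -> float:
    """Perceived length of a two-tap trajectory, cm.

    l* = l_m / (1 + 2 (tau/t)^2). The percept approaches the measurement
    as t grows (l* -> l_m), and contracts to l_m/3 at t = tau.
    """
    _check_interval(t)
    return l_m / (1.0 + 2.0 * (params.tau / t) ** 2)


def contract_length_general(m: TwoTapMeasurement, sigma_v: float) -> float:
    """Perceived length with per-tap spatial uncertainties, cm.

    l* = l_m / (1 + (sigma_s1^2 + sigma_s2^2) / (sigma_v t)^2); reduces to
    :func:`contract_length` when sigma_s1 == sigma_s2.
    """
    s = (sigma_v * m.t) ** 2
    return m.l_m / (1.0 + (m.sigma_s1**2 + m.sigma_s2**2) / s)


def midpoint_shift(m: TwoTapMeasurement, sigma_v: float) -> float:
    """Shift of the perceived midpoint from the measured midpoint, cm.

    Delta = (l_m/2) (sigma_s1^2 - sigma_s2^2)
            / ((sigma_v t)^2 + sigma_s1^2 + sigma_s2^2).

    The midpoint moves toward the tap with the smaller sigma_s: the
    better-localized (attended) tap migrates less, so the percept as a
    whole drifts toward it.
    """
    s = (sigma_v * m.t) ** 2
    return (
        0.5
        * m.l_m
        * (m.sigma_s1**2 - m.sigma_s2**2)
        / (s + m.sigma_s1**2 + m.sigma_s2**2)
    )


def two_tap_posterior(m: TwoTapMeasurement, sigma_v: float) -> JointPosterior2:
    """Joint Gaussian posterior over the two tap positions.

    The MAP percept minimizes

        (x1 - x1m)^2 / (2 s1^2) + (x2 - x2m)^2 / (2 s2^2)
        + (x2 - x1)^2 / (2 (sigma_v t)^2)

    whose precision matrix is [[1/s1^2 + 1/s, -1/s], [-1/s, 1/s2^2 + 1/s]]
    with s = (sigma_v t)^2. No absolute-position term appears: only the
    speed is penalized, so the percept is translation-equivariant.
    """
    s = (sigma_v * m.t) ** 2
    precision = np.array(
        [
            [1.0 / m.sigma_s1**2 + 1.0 / s, -1.0 / s],
            [-1.0 / s, 1.0 / m.sigma_s2**2 + 1.0 / s],
        ]
    )
    rhs = np.array([m.x1m / m.sigma_s1**2, m.x2m / m.sigma_s2**2])
    mean = np.linalg.solve(precision, rhs)
    cov = np.linalg.inv(precision)
    cov = 0.5 * (cov + cov.T)
    return JointPosterior2(mean=mean, cov=cov)


def equality_ratio(t1: float, t2: float, tau: float) -> float:
    """Length ratio l2/l1 at which two tap pairs are perceived as equal.

    Two pairs presented at intervals t1 and t2 are perceived as equally
    spaced when l1* == l2*, i.e. when

        l2/l1 = (1 + 2 (tau/t2)^2) / (1 + 2 (tau/t1)^2).

    The pair with the shorter interval must be physically longer to be
    perceived as equal (ratio > 1 when t2 < t1).
    """
    _check_interval(t1)
    _check_interval(t2)
    return (1.0 + 2.0 * (tau / t2) ** 2) / (1.0 + 2.0 * (tau / t1) ** 2)
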