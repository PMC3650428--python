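"""MAP trajectory inference for n-tap sequences.

Low-speed observer
------------------
Each inter-tap movement is penalized independently by the zero-mean Gaussian
speed prior, giving the quadratic cost

    C(x) = sum_i (x_i - x_im)^2 / (2 sigma_si^2)
         + sum_{i<n} (x_{i+1} - x_i)^2 / (2 (sigma_v t_i)^2)

Its minimizer solves a symmetric positive-definite tridiagonal system, and
is identical to the posterior-mean output of a Kalman smoother for a
random-walk state with process variance (sigma_v t_i)^2 per step, a diffuse
initial state, and measurement variance sigma_si^2 (Rauch-Tung-Striebel
backward pass). Both routes are provided and cross-checked.

Low-acceleration observer
-------------------------
A rival expectation: only the first segment's speed is penalized; thereafter
the *change* in segment velocity is penalized, with the same scale sigma_v:

    v_1^2 / (2 sigma_v^2) + sum_{i>=2} (v_i - v_{i-1})^2 / (2 sigma_v^2),
    v_i = (x_{i+1} - x_i) / t_i

Still quadratic in x (banded, pentadiagonal). This observer extrapolates
rapid jumps at nearly constant velocity and so overshoots trajectory
endpoints — a signature that distinguishes it behaviorally from the
low-speed observer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solveh_banded
from scipy.optimize import brentq

from .observer import _check_interval, contract_length, equality_ratio
from .params import ObserverParams

__all__ = [
    "MeasurementSequence",
    "Percept",
    "map_percept_lowspeed",
    "rts_percept_lowspeed",
    "map_percept_lowaccel",
    "tau_effect_pse",
]


@dataclass(frozen=True)
class MeasurementSequence:
    """Ordered tap onset times (s), measured positions (cm), per-tap sigma_s (cm)."""

    times: np.ndarray
    x_m: np.ndarray
    sigma_s: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        x_m = np.asarray(self.x_m, dtype=float)
        sigma_s = np.asarray(self.sigma_s, dtype=float)
        if times.ndim != 1 or times.size < 1:
            raise ValueError("need at least one tap")
        if x_m.shape != times.shape or sigma_s.shape != times.shape:
            raise ValueError("times, x_m and sigma_s must have equal length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError(
                "tap times must be strictly increasing (coincident or "
                "out-of-order taps)"
            )
        if not np.all(sigma_s > 0):
            raise ValueError("all sigma_s must be positive")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(x_m))):
            raise ValueError("times and positions must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "x_m", x_m)
        object.__setattr__(self, "sigma_s", sigma_s)

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def intervals(self) -> np.ndarray:
        """Inter-tap intervals t_i = times[i+1] - times[i], s (length n-1)."""
        return np.diff(self.times)

    @classmethod
    def from_taps(
        cls,
        times: Sequence[float],
        x_m: Sequence[float],
        sigma_s: float | Sequence[float] = 1.0,
    ) -> "MeasurementSequence":
        times = np.asarray(times, dtype=float)
        sig = np.broadcast_to(np.asarray(sigma_s, dtype=float), times.shape).copy()
        return cls(times=times, x_m=np.asarray(x_m, dtype=float), sigma_s=sig)


@dataclass(frozen=True)
class Percept:
    """Perceived positions (posterior mode, cm) and per-tap posterior sd (cm)."""

    x_star: np.ndarray
    sd: np.ndarray
    cov: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x_star, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if x.shape != sd.shape:
            raise ValueError("x_star and sd must have equal length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(sd))):
            raise ValueError("percept must be finite")
        object.__setattr__(self, "x_star", x)
        object.__setattr__(self, "sd", sd)


def _lowspeed_precision(m: MeasurementSequence, sigma_v: float) -> np.ndarray:
    n = m.n
    s = (sigma_v * m.intervals) ** 2  # per-segment prior variance, cm^2
    P = np.zeros((n, n))
    P[np.arange(n), np.arange(n)] = 1.0 / m.sigma_s**2
    for i in range(n - 1):
        P[i, i] += 1.0 / s[i]
        P[i + 1, i + 1] += 1.0 / s[i]
        P[i, i + 1] -= 1.0 / s[i]
        P[i + 1, i] -= 1.0 / s[i]
    return P


def map_percept_lowspeed(m: MeasurementSequence, sigma_v: float) -> Percept:
    """MAP percept under the low-speed prior via the tridiagonal normal equations.

    Posterior sds come from the diagonal of the exact inverse precision
    matrix (n is small in every stimulus of interest).
    """
    if not sigma_v > 0:
        raise ValueError("sigma_v must be positive")
    n = m.n
    rhs = m.x_m / m.sigma_s**2
    if n == 1:
        return Percept(x_star=m.x_m.copy(), sd=m.sigma_s.copy())
    s = (sigma_v * m.intervals) ** 2
    # upper banded storage for solveh_banded: row 0 = superdiagonal, row 1 = diag
    ab = np.zeros((2, n))
    ab[1] = 1.0 / m.sigma_s**2
    ab[1, :-1] += 1.0 / s
    ab[1, 1:] += 1.0 / s
    ab[0, 1:] = -1.0 / s
    x_star = solveh_banded(ab, rhs)
    cov = np.linalg.inv(_lowspeed_precision(m, sigma_v))
    return Percept(x_star=x_star, sd=np.sqrt(np.diag(cov)), cov=cov)


def rts_percept_lowspeed(m: MeasurementSequence, sigma_v: float) -> Percept:
    """Same percept via a Kalman filter + Rauch-Tung-Striebel smoother.

    State: scalar position following a random walk with per-step process
    variance (sigma_v t_i)^2; diffuse initial state (the first update
    returns the first measurement exactly); measurement variance
    sigma_si^2. The smoothed means equal the tridiagonal MAP solution.
    """
    if not sigma_v > 0:
        raise ValueError("sigma_v must be positive")
    n = m.n
    q = (sigma_v * m.intervals) ** 2
    r = m.sigma_s**2

    f_mean = np.empty(n)
    f_var = np.empty(n)
    p_mean = np.empty(n)  # one-step predictions, p_*[k] valid for k >= 1
    p_var = np.empty(n)
    f_mean[0], f_var[0] = m.x_m[0], r[0]
    for k in range(1, n):
        p_mean[k] = f_mean[k - 1]
        p_var[k] = f_var[k - 1] + q[k - 1]
        gain = p_var[k] / (p_var[k] + r[k])
        f_mean[k] = p_mean[k] + gain * (m.x_m[k] - p_mean[k])
        f_var[k] = (1.0 - gain) * p_var[k]

    s_mean = np.empty(n)
    s_var = np.empty(n)
    s_mean[-1], s_var[-1] = f_mean[-1], f_var[-1]
    for k in range(n - 2, -1, -1):
        c = f_var[k] / p_var[k + 1]
        s_mean[k] = f_mean[k] + c * (s_mean[k + 1] - p_mean[k + 1])
        s_var[k] = f_var[k] + c**2 * (s_var[k + 1] - p_var[k + 1])
    return Percept(x_star=s_mean, sd=np.sqrt(s_var))


def map_percept_lowaccel(m: MeasurementSequence, sigma_v: float) -> Percept:
    """MAP percept under the low-acceleration prior (pentadiagonal system)."""
    if not sigma_v > 0:
        raise ValueError("sigma_v must be positive")
    n = m.n
    if n < 2:
        raise ValueError("low-acceleration observer needs at least 2 taps")
    t = m.intervals
    # rows of G map x to the penalized velocity functionals (units cm/s)
    G = np.zeros((n - 1, n))
    G[0, 0], G[0, 1] = -1.0 / t[0], 1.0 / t[0]  # v_1
    for i in range(1, n - 1):  # v_{i+1} - v_i
        G[i, i - 1] = 1.0 / t[i - 1]
        G[i, i] = -1.0 / t[i - 1] - 1.0 / t[i]
        G[i, i + 1] = 1.0 / t[i]
    P = np.diag(1.0 / m.sigma_s**2) + (G.T @ G) / sigma_v**2
    rhs = m.x_m / m.sigma_s**2
    x_star = np.linalg.solve(P, rhs)
    cov = np.linalg.inv(P)
    return Percept(x_star=x_star, sd=np.sqrt(np.diag(cov)), cov=cov)


def tau_effect_pse(
    l1: float,
    t1: float,
    t2: float,
    params: ObserverParams,
    mode: str = "pairwise",
    bracket: tuple[float, float] | None = None,
    xtol: float = 1e-6,
) -> float:
    """Tap-3 position at which the two intervals are perceived as equal.

    Three taps at positions 0, l1, x3 with temporal intervals t1 then t2
    define spatial intervals l1 and l2 = x3 - l1. Returns the x3 (cm) at
    which the observer's perceived second interval equals its perceived
    first interval (the point of subjective equality).

    ``mode='pairwise'`` applies the two-tap contraction formula to each
    interval independently and solves in closed form; ``mode='joint'``
    runs the full 3-tap low-speed inference (with measurements set equal
    to the actual positions) and finds the root of l2*(x3) - l1*(x3) by
    bracketed root-finding.
    """
    if not l1 > 0:
        raise ValueError("l1 must be positive")
    _check_interval(t1)
    _check_interval(t2)
    if mode == "pairwise":
        return l1 + l1 * equality_ratio(t1, t2, params.tau)
    if mode != "joint":
        raise ValueError(f"mode must be 'pairwise' or 'joint', got {mode!r}")

    x2 = l1
    times = np.array([0.0, t1, t1 + t2])

    def interval_diff(x3: float) -> float:
        m = MeasurementSequence.from_taps(
            times, [0.0, x2, x3], params.sigma_s_default
        )
        p = map_percept_lowspeed(m, params.sigma_v)
        l1_star = p.x_star[1] - p.x_star[0]
        l2_star = p.x_star[2] - p.x_star[1]
        return l2_star - l1_star

    lo, hi = bracket if bracket is not None else (x2 + 0.1, 10.0 * l1)
    f_lo, f_hi = interval_diff(lo), interval_diff(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no sign change of l2* - l1* in bracket [{lo}, {hi}]: "
            f"f({lo})={f_lo:.6g}, f({hi})={f_hi:.6g}"
        )
    return float(brentq(interval_diff, lo, hi, xtol=xtol))
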