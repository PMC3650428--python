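import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.optimize import minimize

from saltation import MeasurementSequence, TwoTapMeasurement

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def grid_mode_2tap(m: TwoTapMeasurement, sigma_v: float, res: float = 0.001):
    """Brute-force grid maximization of likelihood x prior for two taps.

    Two-stage grid (coarse then refined around the coarse argmax), both
    stages plain exhaustive evaluation of the log-posterior on a lattice.
    Returns the (x1, x2) grid argmax; accurate to ~res.
    """

    def neg_log_post(x1, x2):
        s = (sigma_v * m.t) ** 2
        return (
            (x1 - m.x1m) ** 2 / (2 * m.sigma_s1**2)
            + (x2 - m.x2m) ** 2 / (2 * m.sigma_s2**2)
            + (x2 - x1) ** 2 / (2 * s)
        )

    lo = min(m.x1m, m.x2m) - 3.0
    hi = max(m.x1m, m.x2m) + 3.0
    centre = None
    for r, half in ((0.05, None), (res, 0.08)):
        if half is None:
            g1 = np.arange(lo, hi, r)
            g2 = g1
        else:
            g1 = np.arange(centre[0] - half, centre[0] + half, r)
            g2 = np.arange(centre[1] - half, centre[1] + half, r)
        X1, X2 = np.meshgrid(g1, g2, indexing="ij")
        C = neg_log_post(X1, X2)
        i, j = np.unravel_index(np.argmin(C), C.shape)
        centre = (g1[i], g2[j])
    return centre


def lowspeed_cost(x, m: MeasurementSequence, sigma_v: float) -> float:
    s = (sigma_v * m.intervals) ** 2
    c = np.sum((x - m.x_m) ** 2 / (2 * m.sigma_s**2))
    c += np.sum(np.diff(x) ** 2 / (2 * s))
    return float(c)


def lowaccel_cost(x, m: MeasurementSequence, sigma_v: float) -> float:
    t = m.intervals
    v = np.diff(x) / t
    c = np.sum((x - m.x_m) ** 2 / (2 * m.sigma_s**2))
    c += v[0] ** 2 / (2 * sigma_v**2)
    c += np.sum(np.diff(v) ** 2 / (2 * sigma_v**2))
    return float(c)


def numeric_minimizer(cost, m: MeasurementSequence, sigma_v: float) -> np.ndarray:
    """Generic numeric minimizer (BFGS from the measurements) as oracle."""
    res = minimize(
        cost, m.x_m.copy(), args=(m, sigma_v), method="BFGS",
        options={"gtol": 1e-12, "maxiter": 10_000},
    )
    return res.x


def random_sequence(rng: np.random.Generator, n: int) -> MeasurementSequence:
    times = np.cumsum(rng.uniform(0.02, 0.5, size=n))
    x_m = rng.uniform(0.0, 10.0, size=n)
    sigma = rng.uniform(0.3, 2.0, size=n)
    return MeasurementSequence(times=times, x_m=x_m, sigma_s=sigma)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
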