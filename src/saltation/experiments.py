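"""Scenario runners and tau fitting.

This module packages the classic experimental paradigms as pure functions
of their stimulus parameters:

* ``fit_tau`` — least-squares estimation of the observer's time constant
  from (length, interval, perceived length) records, e.g. digitized
  psychophysical datasets supplied as CSV.
* ``make_fixture_dataset`` — synthetic stand-in datasets generated from
  the contraction formula plus Gaussian report noise, for parameter-
  recovery studies (no historical human data ships with the package).
* ``run_rabbit_scenario`` — the 15-tap reduced-rabbit protocol: five taps
  at each of three skin sites, run through either observer, optionally
  with a per-region spatial-attention profile.
* ``run_attention_pair`` — a two-tap trial with unequal proximal/distal
  spatial uncertainty, reporting the percept and the midpoint shift.

Deterministic scenario predictions feed the actual tap positions in as
the observer's measurements (the expected measurement), mirroring how the
contraction formula is fit to actual stimulus lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .multitap import (
    MeasurementSequence,
    map_percept_lowaccel,
    map_percept_lowspeed,
)
from .observer import TwoTapMeasurement, midpoint_shift, two_tap_posterior
from .params import ObserverParams, PriorKind

__all__ = [
    "ContractionDataset",
    "TauFit",
    "fit_tau",
    "make_fixture_dataset",
    "rabbit_preset",
    "run_rabbit_scenario",
    "run_attention_pair",
]

TAU_BOUNDS = (1e-4, 10.0)  # search interval for the time constant, s


@dataclass(frozen=True)
class ContractionDataset:
    """Records of (stimulus length cm, inter-stimulus time s, perceived length cm)."""

    length_cm: np.ndarray
    time_s: np.ndarray
    perceived_cm: np.ndarray
    paradigm: str = ""

    def __post_init__(self) -> None:
        l = np.asarray(self.length_cm, dtype=float)
        t = np.asarray(self.time_s, dtype=float)
        p = np.asarray(self.perceived_cm, dtype=float)
        if not (l.shape == t.shape == p.shape) or l.ndim != 1:
            raise ValueError("columns must be 1-D and of equal length")
        if not (np.all(np.isfinite(l)) and np.all(np.isfinite(p))):
            raise ValueError("lengths must be finite")
        if not np.all(t > 0):
            raise ValueError("all times must be positive")
        object.__setattr__(self, "length_cm", l)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "perceived_cm", p)

    @property
    def n(self) -> int:
        return self.length_cm.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "length_cm": self.length_cm,
                "time_s": self.time_s,
                "perceived_cm": self.perceived_cm,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, paradigm: str = "") -> "ContractionDataset":
        df = pd.read_csv(path)
        missing = {"length_cm", "time_s", "perceived_cm"} - set(df.columns)
        if missing:
            raise ValueError(f"dataset CSV missing columns: {sorted(missing)}")
        return cls(
            length_cm=df["length_cm"].to_numpy(float),
            time_s=df["time_s"].to_numpy(float),
            perceived_cm=df["perceived_cm"].to_numpy(float),
            paradigm=paradigm,
        )


@dataclass(frozen=True)
class TauFit:
    tau: float
    rss: float
    n: int


def _predict(l: np.ndarray, t: np.ndarray, tau: float) -> np.ndarray:
    return l / (1.0 + 2.0 * (tau / t) ** 2)


def fit_tau(d: ContractionDataset) -> TauFit:
    """Least-squares estimate of the time constant from a contraction dataset.

    Minimizes the sum of squared differences between observed perceived
    lengths and the contraction-formula prediction over tau in
    ``TAU_BOUNDS``. Requires at least two records and at least two
    distinct inter-stimulus times (with a single time, tau and length
    scale are confounded).
    """
    if d.n < 2:
        raise ValueError(f"need at least 2 records to fit tau, got {d.n}")
    if np.unique(d.time_s).size < 2:
        raise ValueError(
            "tau is not identifiable from a single inter-stimulus time; "
            "need records at >= 2 distinct times"
        )

    def sse(tau: float) -> float:
        r = d.perceived_cm - _predict(d.length_cm, d.time_s, tau)
        return float(r @ r)

    res = minimize_scalar(
        sse, bounds=TAU_BOUNDS, method="bounded", options={"xatol": 1e-10}
    )
    return TauFit(tau=float(res.x), rss=float(res.fun), n=d.n)


def make_fixture_dataset(
    tau_true: float,
    design: Sequence[tuple[float, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    paradigm: str = "synthetic",
) -> ContractionDataset:
    """Synthetic contraction dataset at known tau.

    ``design`` is a list of (stimulus length cm, inter-stimulus time s)
    conditions; perceived lengths are the contraction-formula prediction
    plus Normal(0, noise_sd^2) report noise, reproducible by seed.
    """
    design_arr = np.asarray(design, dtype=float)
    l, t = design_arr[:, 0], design_arr[:, 1]
    rng = np.random.default_rng(seed)
    perceived = _predict(l, t, tau_true)
    if noise_sd > 0:
        perceived = perceived + rng.normal(0.0, noise_sd, size=l.size)
    return ContractionDataset(
        length_cm=l, time_s=t, perceived_cm=perceived, paradigm=paradigm
    )


def rabbit_preset(
    isi: float,
    positions_cm: Sequence[float] = (0.0, 5.0, 10.0),
    taps_per_site: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Times and true positions of the 15-tap rabbit stimulus.

    ``taps_per_site`` consecutive taps at each listed position, uniform
    inter-stimulus interval. Default geometry: 5 taps at each of 0, 5 and
    10 cm along the arm.
    """
    if not isi > 0:
        raise ValueError("isi must be positive")
    x = np.repeat(np.asarray(positions_cm, dtype=float), taps_per_site)
    times = np.arange(x.size) * isi
    return times, x


def run_rabbit_scenario(
    isi: float,
    sigma_profile: float | Sequence[float],
    params: ObserverParams,
    positions_cm: Sequence[float] = (0.0, 5.0, 10.0),
    taps_per_site: int = 5,
) -> pd.DataFrame:
    """Run the multi-site rabbit stimulus through the configured observer.

    ``sigma_profile`` is either one sigma_s (cm) for the whole arm or one
    per site, applied block-wise to that site's taps (e.g. (1, 2, 0.5) for
    standard, reduced and heightened attention over the proximal, middle
    and distal regions). Measurements are set to the true positions.

    Returns a table with columns tap, time_s, true_cm, measured_cm,
    perceived_cm, posterior_sd_cm.
    """
    times, x_true = rabbit_preset(isi, positions_cm, taps_per_site)
    profile = np.asarray(sigma_profile, dtype=float)
    if profile.ndim == 0:
        sigma = np.full(x_true.size, float(profile))
    else:
        if profile.size != len(positions_cm):
            raise ValueError(
                f"sigma_profile must have one value per site "
                f"({len(positions_cm)}), got {profile.size}"
            )
        sigma = np.repeat(profile, taps_per_site)
    m = MeasurementSequence(times=times, x_m=x_true.copy(), sigma_s=sigma)
    if params.prior_kind is PriorKind.LOW_ACCEL:
        p = map_percept_lowaccel(m, params.sigma_v)
    else:
        p = map_percept_lowspeed(m, params.sigma_v)
    return pd.DataFrame(
        {
            "tap": np.arange(1, x_true.size + 1),
            "time_s": times,
            "true_cm": x_true,
            "measured_cm": m.x_m,
            "perceived_cm": p.x_star,
            "posterior_sd_cm": p.sd,
        }
    )


def run_attention_pair(
    x2m: float,
    x3m: float,
    t: float,
    sigma_sp: float,
    sigma_sd: float,
    sigma_v: float,
) -> dict:
    """Two-tap trial with unequal proximal/distal spatial uncertainty.

    ``sigma_sp`` applies to the proximal (first) tap, ``sigma_sd`` to the
    distal (second). Returns the perceived pair, their posterior sds, and
    the midpoint shift (negative = toward the proximal tap).
    """
    m = TwoTapMeasurement(
        x1m=x2m, x2m=x3m, t=t, sigma_s1=sigma_sp, sigma_s2=sigma_sd
    )
    post = two_tap_posterior(m, sigma_v)
    return {
        "perceived_proximal_cm": float(post.mean[0]),
        "perceived_distal_cm": float(post.mean[1]),
        "sd_proximal_cm": post.marginal(0)[1],
        "sd_distal_cm": post.marginal(1)[1],
        "perceived_length_cm": post.perceived_length,
        "midpoint_shift_cm": midpoint_shift(m, sigma_v),
    }
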