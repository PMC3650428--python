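"""Stimulus/percept file formats and run configuration.

All files use cm and s. A stimulus CSV has a header and columns
``time_s,position_cm`` plus an optional ``sigma_s_cm`` column; absent
per-tap uncertainties fall back to the observer default. Percept CSVs
carry one row per tap: ``tap,time_s,measured_cm,perceived_cm,
posterior_sd_cm``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .multitap import MeasurementSequence, Percept
from .params import ObserverParams, PriorKind

__all__ = [
    "read_stimulus",
    "write_percept",
    "read_percept",
    "RunConfig",
]

_REQUIRED = ("time_s", "position_cm")


def read_stimulus(path, default_sigma_s: float = 1.0) -> MeasurementSequence:
    """Read a stimulus CSV into a measurement sequence.

    Validates the header, numeric content, strictly increasing times and
    positive per-tap uncertainties; error messages name the offending row
    (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"stimulus file {path} missing columns: {missing}")
    if len(df) < 1:
        raise ValueError(f"stimulus file {path} has no taps")

    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(coerced.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if bad.size:
            raise ValueError(
                f"non-numeric value in column {col!r} at row {bad[0] + 1}"
            )
        df[col] = coerced

    times = df["time_s"].to_numpy(float)
    if np.any(~np.isfinite(times)) or np.any(~np.isfinite(df["position_cm"])):
        raise ValueError("times and positions must be finite")
    dec = np.nonzero(np.diff(times) <= 0)[0]
    if dec.size:
        raise ValueError(
            f"tap times must be strictly increasing; violated at row {dec[0] + 2}"
        )

    if "sigma_s_cm" in df.columns:
        sigma = df["sigma_s_cm"].to_numpy(float)
        sigma = np.where(np.isnan(sigma), default_sigma_s, sigma)
        nonpos = np.nonzero(~(sigma > 0))[0]
        if nonpos.size:
            raise ValueError(f"sigma_s_cm must be positive at row {nonpos[0] + 1}")
    else:
        sigma = np.full(len(df), default_sigma_s)

    return MeasurementSequence(
        times=times, x_m=df["position_cm"].to_numpy(float), sigma_s=sigma
    )


def write_percept(path, m: MeasurementSequence, p: Percept) -> None:
    """Write a percept CSV (one row per tap)."""
    pd.DataFrame(
        {
            "tap": np.arange(1, m.n + 1),
            "time_s": m.times,
            "measured_cm": m.x_m,
            "perceived_cm": p.x_star,
            "posterior_sd_cm": p.sd,
        }
    ).to_csv(path, index=False, float_format="%.9g")


def read_percept(path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass(frozen=True)
class RunConfig:
    """Observer configuration for batch runs.

    Exactly one of ``sigma_s``/``tau`` need be given (the other derives
    via tau = sigma_s / sigma_v); giving both is accepted only when they
    are mutually consistent.
    """

    sigma_v: float = 10.0
    sigma_s: float | None = None
    tau: float | None = None
    prior_kind: PriorKind = PriorKind.LOW_SPEED
    seed: int = 0
    output: str | None = None

    def resolve(self) -> ObserverParams:
        if self.sigma_s is None and self.tau is None:
            raise ValueError("one of sigma_s or tau must be given")
        if self.sigma_s is not None and self.tau is not None:
            if abs(self.sigma_s / self.sigma_v - self.tau) > 1e-9:
                raise ValueError(
                    f"inconsistent parameters: sigma_s/sigma_v = "
                    f"{self.sigma_s / self.sigma_v:g} s but tau = {self.tau:g} s"
                )
        sigma_s = (
            self.sigma_s if self.sigma_s is not None else self.tau * self.sigma_v
        )
        return ObserverParams(
            sigma_v=self.sigma_v,
            sigma_s_default=sigma_s,
            prior_kind=self.prior_kind,
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "prior_kind" in raw:
            raw["prior_kind"] = PriorKind(raw["prior_kind"])
        return cls(**raw)
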