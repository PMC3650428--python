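"""Observer parameters.

The model of tactile space-time perception used throughout this package has
two physical parameters: ``sigma_v`` (cm/s), the standard deviation of the
observer's zero-mean Gaussian expectation over stimulus speed (a "low-speed
prior"), and ``sigma_s`` (cm), the standard deviation of the Gaussian
measurement noise on each tap's perceived skin position. Only their ratio

    tau = sigma_s / sigma_v   (seconds)

matters for the amount of perceptual length contraction, so ``tau`` acts as
the model's single free time constant: percepts approach the measurements as
the inter-stimulus interval grows past a few tau.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class PriorKind(str, enum.Enum):
    """Which trajectory expectation the observer holds."""

    LOW_SPEED = "low_speed"
    LOW_ACCEL = "low_accel"


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the Bayesian observer.

    Parameters
    ----------
    sigma_v : float
        Standard deviation of the prior over trajectory speed, cm/s.
    sigma_s_default : float
        Default spatial measurement standard deviation, cm; per-tap values
        may override it in multi-tap sequences.
    prior_kind : PriorKind
        ``LOW_SPEED`` penalizes each segment's speed independently;
        ``LOW_ACCEL`` penalizes the first segment's speed and thereafter
        the change in velocity between consecutive segments.
    """

    sigma_v: float = 10.0
    sigma_s_default: float = 1.0
    prior_kind: PriorKind = PriorKind.LOW_SPEED

    def __post_init__(self) -> None:
        if not self.sigma_v > 0:
            raise ValueError(f"sigma_v must be positive, got {self.sigma_v}")
        if not self.sigma_s_default > 0:
            raise ValueError(
                f"sigma_s_default must be positive, got {self.sigma_s_default}"
            )

    @property
    def tau(self) -> float:
        """Time constant for space perception, s (= sigma_s / sigma_v)."""
        return self.sigma_s_default / self.sigma_v

    @classmethod
    def from_tau(
        cls,
        tau: float,
        sigma_s_default: float = 1.0,
        prior_kind: PriorKind = PriorKind.LOW_SPEED,
    ) -> "ObserverParams":
        """Build parameters from the time constant.

        Since only the ratio sigma_s/sigma_v is identified by two-tap
        percepts, ``sigma_s_default`` fixes the overall scale (1 cm is the
        conventional forearm value) and sigma_v is derived.
        """
        if not tau > 0:
            raise ValueError(f"tau must be positive, got {tau}")
        return cls(
            sigma_v=sigma_s_default / tau,
            sigma_s_default=sigma_s_default,
            prior_kind=prior_kind,
        )
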