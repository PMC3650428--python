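"""Predictive-postdictive reformulation of the two-tap observer.

The joint two-dimensional inference can be decomposed into one-dimensional
inferences about each tap separately. From the first tap's likelihood the
observer *predicts* a prior over the second tap's position (projected
forward in time under the low-speed expectation); from the second tap's
likelihood it *postdicts* a prior over the first tap's position (projected
backward). Each tap's posterior is then the precision-weighted product of
its own likelihood and the pre/postdicted prior:

    mu_pre  = x1m,  var_pre  = sigma_s1^2 + (sigma_v t)^2
    mu_post = x2m,  var_post = sigma_s2^2 + (sigma_v t)^2

These one-dimensional posteriors are exactly the marginals of the joint
bivariate posterior (verified by property test), so prediction and
postdiction are implicit in the joint formulation rather than extra
machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .observer import _check_interval

__all__ = ["GaussianBelief", "predicted_prior", "postdicted_prior", "fuse"]


@dataclass(frozen=True)
class GaussianBelief:
    """A Gaussian belief over one scalar skin position: mean and sd in cm.

    ``sd = math.inf`` encodes a flat (uninformative) belief; fusing with a
    flat belief is the identity.
    """

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"sd must be positive (inf allowed), got {self.sd}")

    @property
    def var(self) -> float:
        return self.sd**2

    @property
    def precision(self) -> float:
        return 0.0 if math.isinf(self.sd) else 1.0 / self.sd**2

    @property
    def is_flat(self) -> bool:
        return math.isinf(self.sd)

    @classmethod
    def flat(cls) -> "GaussianBelief":
        return cls(mean=0.0, sd=math.inf)


def _projected(belief: GaussianBelief, t: float, sigma_v: float) -> GaussianBelief:
    # Under the low-speed expectation the most probable displacement over an
    # interval t is zero, with variance (sigma_v t)^2 added to the belief's.
    _check_interval(t)
    if belief.is_flat:
        return GaussianBelief.flat()
    return GaussianBelief(
        mean=belief.mean, sd=math.sqrt(belief.var + (sigma_v * t) ** 2)
    )


def predicted_prior(
    likelihood1: GaussianBelief, t: float, sigma_v: float
) -> GaussianBelief:
    """Prior over tap 2's position, predicted forward from tap 1's likelihood."""
    return _projected(likelihood1, t, sigma_v)


def postdicted_prior(
    likelihood2: GaussianBelief, t: float, sigma_v: float
) -> GaussianBelief:
    """Prior over tap 1's position, postdicted backward from tap 2's likelihood."""
    return _projected(likelihood2, t, sigma_v)


def fuse(likelihood: GaussianBelief, prior: GaussianBelief) -> GaussianBelief:
    """Precision-weighted Gaussian product of a likelihood and a prior.

    Posterior precision is the sum of precisions; the posterior mean is the
    precision-weighted average of the means. Commutative and associative.
    Raises if both beliefs are flat (no information).
    """
    p1, p2 = likelihood.precision, prior.precision
    p = p1 + p2
    if p == 0.0:
        raise ValueError("cannot fuse two flat beliefs: no information")
    if p1 == 0.0:
        return GaussianBelief(mean=prior.mean, sd=prior.sd)
    if p2 == 0.0:
        return GaussianBelief(mean=likelihood.mean, sd=likelihood.sd)
    mean = (p1 * likelihood.mean + p2 * prior.mean) / p
    return GaussianBelief(mean=mean, sd=math.sqrt(1.0 / p))
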