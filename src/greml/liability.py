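"""Observed-scale to liability-scale conversion and sibling recurrence risk.

Case-control GREML estimates heritability on the observed 0/1 scale of an
ascertained sample.  Under the liability-threshold model (standard-normal
liability, affected iff liability > T = Phi^-1(1 - K)) the estimate maps to
the liability scale as

    h2_liab = h2_obs * K^2 (1 - K)^2 / (z^2 * P (1 - P)),

with K the population prevalence, P the sample case fraction and z = phi(T)
the normal density at the threshold.  The factor is linear, so the SE scales
identically.  The same model turns (h2_liab, K) into a sibling recurrence
risk via a bivariate-normal orthant probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal, norm

__all__ = [
    "LiabilityParams",
    "LiabilityEstimate",
    "observed_to_liability",
    "prevalence_sensitivity",
    "sibling_recurrence_risk",
]


@dataclass(frozen=True)
class LiabilityParams:
    """Prevalence K and sample case fraction P with derived threshold quantities."""

    K: float
    P: float

    def __post_init__(self) -> None:
        if not 0.0 < self.K < 1.0:
            raise ValueError(f"prevalence K must be in (0, 1), got {self.K}")
        if not 0.0 < self.P < 1.0:
            raise ValueError(f"case fraction P must be in (0, 1), got {self.P}")

    @property
    def T(self) -> float:
        """Liability threshold Phi^-1(1 - K)."""
        return float(norm.isf(self.K))

    @property
    def z(self) -> float:
        """Standard-normal density at the threshold."""
        return float(norm.pdf(self.T))

    @property
    def factor(self) -> float:
        """Multiplier taking observed-scale h2 to the liability scale."""
        K, P = self.K, self.P
        return (K * (1.0 - K)) ** 2 / (self.z**2 * P * (1.0 - P))


class LiabilityEstimate(NamedTuple):
    h2_liab: float
    se_liab: float
    factor: float


def observed_to_liability(h2_obs: float, se_obs: float,
                          params: LiabilityParams) -> LiabilityEstimate:
    """Transform an observed-scale estimate and its SE to the liability scale."""
    if h2_obs < 0:
        raise ValueError("h2_obs must be >= 0")
    f = params.factor
    return LiabilityEstimate(h2_obs * f, se_obs * f, f)


def prevalence_sensitivity(h2_obs: float, se_obs: float, P: float,
                           K_grid) -> pd.DataFrame:
    """Liability-scale estimates across a grid of assumed prevalences."""
    rows = []
    for K in K_grid:
        params = LiabilityParams(K=float(K), P=P)
        est = observed_to_liability(h2_obs, se_obs, params)
        rows.append(
            {
                "K": float(K),
                "T": params.T,
                "z": params.z,
                "factor": est.factor,
                "h2_liab": est.h2_liab,
                "se_liab": est.se_liab,
            }
        )
    return pd.DataFrame(rows)


def sibling_recurrence_risk(h2_liab: float, K: float,
                            relative_coefficient: float = 0.5) -> float:
    """Recurrence risk ratio lambda for a relative of an affected individual.

    The liability correlation between relatives is ``a * h2_liab`` with ``a``
    the additive relationship coefficient (0.5 for first-degree relatives).
    lambda = P(L2 > T | L1 > T) / K with (L1, L2) standard bivariate normal.
    """
    if not 0.0 <= h2_liab <= 1.0:
        raise ValueError("h2_liab must be in [0, 1]")
    if not 0.0 < relative_coefficient <= 1.0:
        raise ValueError("relative_coefficient must be in (0, 1]")
    rho = relative_coefficient * h2_liab
    T = float(norm.isf(K))
    if rho == 0.0:
        return 1.0
    # P(L1 > T, L2 > T) = P(L1 < -T, L2 < -T) by symmetry
    orthant = float(
        multivariate_normal(mean=[0.0, 0.0],
                            cov=[[1.0, rho], [rho, 1.0]],
                            allow_singular=True).cdf([-T, -T])
    )
    K_R = orthant / K
    return K_R / K
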