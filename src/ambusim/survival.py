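"""Exponential survival of a time-critical emergency as a function of
time-to-care: S(t) = exp(−λt), t in minutes.

λ is the per-minute hazard; its uncertainty is carried by a normal
distribution truncated to positive values by rejection (clipping would put
an atom at zero).  The applied default λ = 0.056/min reflects an elicited
survival of roughly 0.16 for severe postpartum haemorrhage at the longest
plausible transfer times; because the anchoring arithmetic is not uniquely
determined, λ is treated as a direct input (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class SurvivalParams:
    lambda_mean: float = 0.056
    lambda_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.lambda_mean <= 0:
            raise ValueError("lambda_mean must be positive")
        if self.lambda_sd < 0:
            raise ValueError("lambda_sd must be non-negative")
        # for a positive mean the negative mass is always < 50%, so warn once
        # truncation discards enough mass (>10%) to visibly distort the shape
        if self.lambda_sd > 0 and stats.norm.cdf(0, self.lambda_mean, self.lambda_sd) > 0.10:
            warnings.warn(
                "a large share of the normal mass for lambda is negative; "
                "rejection truncation will noticeably distort the distribution",
                stacklevel=2,
            )


def survival_prob(lam: float, t):
    """S(t) = exp(−λt) ∈ (0, 1]; t = +inf is allowed and gives 0."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr[~np.isnan(t_arr)] < 0):
        raise ValueError("time must be non-negative")
    with np.errstate(over="ignore"):
        out = np.exp(-lam * t_arr)
    return float(out) if out.ndim == 0 else out


def sample_lambda(params: SurvivalParams, rng: np.random.Generator) -> float:
    """One Normal(mean, sd) draw, rejection-resampled until positive."""
    if params.lambda_sd == 0:
        return params.lambda_mean
    while True:
        lam = rng.normal(params.lambda_mean, params.lambda_sd)
        if lam > 0:
            return float(lam)
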