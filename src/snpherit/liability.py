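"""Observed-scale to liability-scale conversion for ascertained case-control h2.

A binary trait is modeled through a latent standard-normal liability; an
individual is a case when liability exceeds the threshold t = Phi^-1(1 - K)
set by the population prevalence K.  Heritability estimated on the observed
0/1 scale from an ascertained sample with case proportion P is converted to
the liability scale with the ascertainment-corrected factor

    h2_liability = h2_observed * [K(1-K)/z^2] * [K(1-K) / (P(1-P))],

where z = phi(t) is the standard-normal density at the threshold.  Standard
errors transform by the same factor (delta method on a linear map).  When
P = K (no ascertainment) the factor reduces to K(1-K)/z^2.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm


@dataclass(frozen=True)
class LiabilityEstimate:
    h2_liability: float
    se_liability: float
    K: float          # population prevalence
    P: float          # sample case proportion
    t: float          # liability threshold Phi^-1(1-K)
    z: float          # standard normal density at t
    factor: float     # multiplicative observed -> liability conversion
    h2_observed: float
    se_observed: float


def liability_threshold(K: float) -> tuple[float, float]:
    """Threshold t = Phi^-1(1-K) and normal density z = phi(t) at prevalence K."""
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence K must lie in (0, 1), got {K}")
    t = norm.isf(K)
    return float(t), float(norm.pdf(t))


def conversion_factor(K: float, P: float | None = None) -> float:
    """Observed-to-liability multiplier at prevalence K and case proportion P.

    ``P=None`` (or P equal to K) gives the unascertained factor K(1-K)/z^2.
    """
    t, z = liability_threshold(K)
    factor = K * (1.0 - K) / z**2
    if P is not None:
        if not 0.0 < P < 1.0:
            raise ValueError(f"case proportion P must lie in (0, 1), got {P}")
        factor *= K * (1.0 - K) / (P * (1.0 - P))
    return factor


def observed_to_liability(h2_obs: float, se_obs: float, K: float,
                          P: float | None = None) -> LiabilityEstimate:
    """Convert an observed-scale h2 and its SE to the liability scale.

    ``P`` is the case proportion of the analyzed sample; omit it for the
    unascertained (P = K) transformation.
    """
    if h2_obs < 0:
        raise ValueError("observed-scale h2 must be non-negative")
    t, z = liability_threshold(K)
    factor = conversion_factor(K, P)
    P_eff = K if P is None else P
    return LiabilityEstimate(
        h2_liability=factor * h2_obs, se_liability=factor * se_obs,
        K=K, P=P_eff, t=t, z=z, factor=factor,
        h2_observed=h2_obs, se_observed=se_obs,
    )


def liability_to_observed(estimate: LiabilityEstimate) -> tuple[float, float]:
    """Inverse transformation (provided for round-trip testing)."""
    return (estimate.h2_liability / estimate.factor,
            estimate.se_liability / estimate.factor)
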