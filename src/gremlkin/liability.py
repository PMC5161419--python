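"""Observed-scale to liability-scale conversion for binary traits.

Under the liability-threshold model a 0/1 trait with population
prevalence K arises when a standard-normal latent liability exceeds
t = Phi^-1(1 - K).  A variance proportion estimated on the observed
(0/1) scale converts to the liability scale by

    h2_liab = h2_obs * K (1 - K) / z^2,        z = phi(t),

which applies uniformly to every component and, being linear, to its
standard error.  For case-control samples ascertained to a case
proportion P different from K, the corrected factor is
K^2 (1-K)^2 / (z^2 P (1-P)).
"""

from __future__ import annotations

from scipy import stats

__all__ = ["liability_factor", "observed_to_liability"]


def liability_factor(prevalence: float, sample_prevalence: float | None = None) -> float:
    """Multiplier taking an observed-scale proportion to the liability scale."""
    K = prevalence
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {K}")
    t = stats.norm.isf(K)
    z = stats.norm.pdf(t)
    base = K * (1 - K) / z**2
    if sample_prevalence is None:
        return base
    P = sample_prevalence
    if not 0.0 < P < 1.0:
        raise ValueError(f"sample prevalence must be in (0, 1), got {P}")
    return base * K * (1 - K) / (P * (1 - P))


def observed_to_liability(
    prop_obs: float,
    prevalence: float,
    se_obs: float | None = None,
    sample_prevalence: float | None = None,
):
    """Transform an observed-scale variance proportion (and optional SE).

    Returns the transformed proportion, or a ``(proportion, se)`` tuple
    when ``se_obs`` is given.  ``sample_prevalence`` activates the
    case-control ascertainment correction; the default (None) is the
    unascertained population/family-sample transform.
    """
    f = liability_factor(prevalence, sample_prevalence)
    if se_obs is None:
        return prop_obs * f
    return prop_obs * f, se_obs * f
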