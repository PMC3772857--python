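"""Winner's-curse adjustment for significance-selected effect estimates.

A per-allele log odds ratio reported by the same study that discovered the
variant is biased away from zero, because it is only reported when the test
statistic crossed the significance threshold.  Conditioning on that
selection event gives the likelihood

    L(beta) = phi((beta_hat - beta)/se) /
              [ Phi(-c + beta/se) + Phi(-c - beta/se) ],

where c is the upper-alpha/2 normal quantile of the discovery threshold.
The conditional MLE maximizes this in beta; it shrinks the naive estimate
toward zero and the correction vanishes as |beta_hat|/se grows.  Because
the conditional MLE tends to overcorrect, a weighted average of the naive
estimate and the conditional MLE is also reported (equal weights by
default; the weight is a parameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["DiscoveryEstimate", "conditional_mle", "adjust",
           "inflation_factor", "se_from_ci"]

_Z975 = 1.959963984540054


@dataclass(frozen=True)
class DiscoveryEstimate:
    """A genome-wide-significant effect estimate from a discovery scan."""

    beta_hat: float
    se: float
    alpha: float = 5e-8          # two-sided discovery threshold

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if abs(self.beta_hat) / self.se < self.c:
            raise ValueError(
                f"estimate is not significant at alpha={self.alpha:g} "
                f"(|z| = {abs(self.beta_hat) / self.se:.3f} < c = {self.c:.3f}); "
                "the selection-adjusted likelihood does not apply")

    @property
    def c(self) -> float:
        return float(stats.norm.isf(self.alpha / 2.0))


def _neg_log_cond_lik(beta: float, est: DiscoveryEstimate) -> float:
    z = (est.beta_hat - beta) / est.se
    sel = (stats.norm.cdf(-est.c + beta / est.se)
           + stats.norm.cdf(-est.c - beta / est.se))
    # selection probability is bounded below by ~alpha, so the log is safe
    return 0.5 * z * z + math.log(sel)


def conditional_mle(est: DiscoveryEstimate) -> float:
    """Maximize the selection-conditional likelihood in beta.

    One-dimensional bounded minimization of the negative log conditional
    likelihood over [-|beta_hat| - 5 se, |beta_hat| + 5 se], refined to
    high absolute tolerance.
    """
    span = abs(est.beta_hat) + 5.0 * est.se
    res = optimize.minimize_scalar(
        _neg_log_cond_lik, args=(est,), bounds=(-span, span),
        method="bounded", options={"xatol": 1e-12})
    if not res.success:
        raise RuntimeError(f"conditional-likelihood search failed: {res.message}")
    return float(res.x)


def adjust(est: DiscoveryEstimate, weight: float = 0.5
           ) -> dict[str, float]:
    """Naive, conditional-MLE and weighted-average estimates.

    ``weight`` is the mass placed on the naive estimate in the combined
    estimator (``weight * naive + (1 - weight) * conditional``).  The
    combined estimate (default: equal weights) is the one used downstream;
    the dict labels all three.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    cmle = conditional_mle(est)
    combined = weight * est.beta_hat + (1.0 - weight) * cmle
    return {"naive": est.beta_hat, "conditional_mle": cmle,
            "combined": combined, "weight_on_naive": weight}


def inflation_factor(beta_hat: float, beta_adjusted: float) -> float:
    """Percentage inflation of the naive estimate over the adjusted one:
    100 * (beta_hat - beta_adjusted) / beta_adjusted."""
    if beta_adjusted == 0:
        raise ValueError("adjusted estimate is zero; inflation undefined")
    if beta_hat * beta_adjusted < 0:
        raise ValueError("naive and adjusted estimates disagree in sign")
    return 100.0 * (beta_hat - beta_adjusted) / beta_adjusted


def se_from_ci(or_lower: float, or_upper: float) -> float:
    """Back-derive the log-OR standard error from a 95% CI on the OR scale."""
    if not 0 < or_lower < or_upper:
        raise ValueError("need 0 < lower < upper")
    return (math.log(or_upper) - math.log(or_lower)) / (2.0 * _Z975)
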