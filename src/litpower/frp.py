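"""False report probability under prestudy odds, power and reporting bias.

In long-run (Bayesian) terms, the false report probability (FRP) is the
probability that the null hypothesis is true given a statistically
significant finding; the true report probability is its complement. With
prestudy H0:H1 odds O, significance level alpha and power, and a bias
parameter u — the fraction of results that would be nonsignificant
without bias but get reported as significant —

    FRP = (O*alpha + u*O*(1 - alpha))
          / (O*alpha + u*O*(1 - alpha) + power + u*(1 - power))

which reduces to O*alpha / (O*alpha + power) at u = 0. The bias term acts
on nonsignificant outcomes under H0 and H1 alike, consistent with the
Ioannidis (2005) PPV model.

A variant treats significant-but-tiny effects as false reports by
splitting power into power to detect small (P_S) and large (P_L) effects
with mixing probabilities pr(S) + pr(L) = 1:

    FRP = (O*alpha + P_S*pr(S)) / (O*alpha + P_S*pr(S) + P_L*pr(L))

The literature-wide expectation E[FRP] weighs the record-level FRP (each
record contributing the power to detect its own published effect size) by
the empirical probability of that record's (df, D) combination — here the
records' empirical weights. Because published effects are inflated, the
resulting powers are overestimates and E[FRP] is a lower limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FRPSpec:
    """Scenario parameters for a false-report-probability computation."""

    odds_h0_h1: float
    alpha: float = 0.05
    bias: float = 0.0
    p_small: float | None = None
    p_large: float | None = None
    pr_small: float | None = None

    def __post_init__(self):
        if self.odds_h0_h1 < 0:
            raise ValueError("odds_h0_h1 must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.bias <= 1:
            raise ValueError("bias must be in [0, 1]")


@dataclass(frozen=True)
class FRPResult:
    frp: float
    trp: float


def _frp_value(odds, alpha, bias, power):
    """Vectorized FRP under odds/alpha/bias at the given power."""
    odds = np.asarray(odds, dtype=float)
    power = np.asarray(power, dtype=float)
    num = odds * alpha + bias * odds * (1.0 - alpha)
    den = num + power + bias * (1.0 - power)
    return num / den


def frp_point(spec: FRPSpec, power) -> FRPResult:
    """FRP/TRP for a single power value under the given scenario."""
    power = float(power)
    if not 0 <= power <= 1:
        raise ValueError("power must be in [0, 1]")
    frp = float(_frp_value(spec.odds_h0_h1, spec.alpha, spec.bias, power))
    return FRPResult(frp=frp, trp=1.0 - frp)


def frp_small_large(spec: FRPSpec) -> FRPResult:
    """FRP when significant small effects are counted as false reports."""
    if spec.p_small is None or spec.p_large is None or spec.pr_small is None:
        raise ValueError("p_small, p_large and pr_small must all be present")
    oa = spec.odds_h0_h1 * spec.alpha
    num = oa + spec.p_small * spec.pr_small
    den = num + spec.p_large * (1.0 - spec.pr_small)
    frp = num / den
    return FRPResult(frp=float(frp), trp=float(1.0 - frp))


def expected_frp(powers, spec: FRPSpec, weights=None) -> FRPResult:
    """Expected FRP over an empirical power distribution.

    ``powers`` holds each record's power to detect its own published
    effect size; ``weights`` default to 1/N. The result is the weighted
    mean of record-level FRPs.
    """
    powers = np.asarray(powers, dtype=float)
    if powers.size == 0:
        raise ValueError("powers must be nonempty")
    if weights is None:
        weights = np.full(powers.size, 1.0 / powers.size)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != powers.shape:
            raise ValueError("weights must match powers in shape")
        if not np.isclose(weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")
    frp = float(np.sum(_frp_value(spec.odds_h0_h1, spec.alpha, spec.bias, powers) * weights))
    return FRPResult(frp=frp, trp=1.0 - frp)


def frp_curves(powers, odds_grid, bias_grid, alpha: float = 0.05) -> pd.DataFrame:
    """E[FRP] on the Cartesian (bias, odds) grid, sorted by (u, O).

    Returns a DataFrame with columns ``odds``, ``bias``, ``frp``.
    """
    odds_grid = list(odds_grid)
    bias_grid = list(bias_grid)
    if not odds_grid or not bias_grid:
        raise ValueError("odds_grid and bias_grid must be nonempty")
    rows = []
    for u in sorted(bias_grid):
        for o in sorted(odds_grid):
            spec = FRPSpec(odds_h0_h1=o, alpha=alpha, bias=u)
            rows.append({"odds": o, "bias": u, "frp": expected_frp(powers, spec).frp})
    return pd.DataFrame(rows, columns=["odds", "bias", "frp"])
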