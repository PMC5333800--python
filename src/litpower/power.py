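"""Two-sided t-test power from the noncentral t distribution.

For a true standardized effect d, the t statistic follows a noncentral t
distribution with the record's df and noncentrality

    delta = d * sqrt(df + 1)            one-sample / matched
    delta = d * sqrt(N_subgroup / 2)    two-sample, equal groups,
                                        N_subgroup = ceil((df + 2) / 2)

and two-sided power at level alpha is P(|T'| > t_crit) with t_crit the
central-t critical value. Because the test type behind a published record
is unknown, record-level power uses the same one-sample/two-sample
mixture weights as the effect-size conversion (:mod:`litpower.effectsize`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .effectsize import DEFAULT_ALPHA, n_per_group, w_onesample

#: conventional benchmark effect sizes
D_SMALL, D_MEDIUM, D_LARGE = 0.2, 0.5, 0.8

ONE_SAMPLE = "one_sample"
TWO_SAMPLE = "two_sample"


@dataclass(frozen=True)
class PowerProfile:
    """Benchmark (and optionally published-effect) power at one df."""

    df: int
    alpha: float
    power_small: float
    power_medium: float
    power_large: float
    power_published: float | None = None


def noncentrality(d, df, test_type: str):
    """Noncentrality parameter delta for the given design."""
    d = np.asarray(d, dtype=float)
    df = np.asarray(df)
    if test_type == ONE_SAMPLE:
        return d * np.sqrt(df + 1.0)
    if test_type == TWO_SAMPLE:
        return d * np.sqrt(np.ceil((df + 2) / 2) / 2.0)
    raise ValueError(f"unknown test_type {test_type!r}")


def power_t(d, df, test_type: str, alpha: float = DEFAULT_ALPHA):
    """Exact two-sided power for a single test type (vectorized)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("d must be >= 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = np.asarray(df)
    if np.any(df < 1):
        raise ValueError("df must be >= 1")
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    delta = noncentrality(d, df, test_type)
    # d = 0 reduces to the central t: power equals alpha exactly, but
    # scipy's nct at nc=0 is slightly less accurate, so special-case it
    upper = stats.nct.sf(tcrit, df, delta)
    lower = stats.nct.cdf(-tcrit, df, delta)
    # the opposite-tail term underflows to nan at large noncentrality,
    # where it is numerically zero
    lower = np.where(np.isfinite(lower), lower, 0.0)
    power = np.clip(upper + lower, 0.0, 1.0)
    central = stats.t.sf(tcrit, df) + stats.t.cdf(-tcrit, df)
    power = np.where(delta == 0.0, central, power)
    return power if power.ndim else float(power)


def power_mixture(d, df, alpha: float = DEFAULT_ALPHA):
    """Power under the df-conditional one-/two-sample mixture."""
    w = w_onesample(df)
    return w * power_t(d, df, ONE_SAMPLE, alpha) + (1.0 - w) * power_t(
        d, df, TWO_SAMPLE, alpha
    )


def benchmark_powers(df: int, alpha: float = DEFAULT_ALPHA) -> PowerProfile:
    """Mixture power to detect small/medium/large benchmark effects."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return PowerProfile(
        df=int(df),
        alpha=alpha,
        power_small=float(power_mixture(D_SMALL, df, alpha)),
        power_medium=float(power_mixture(D_MEDIUM, df, alpha)),
        power_large=float(power_mixture(D_LARGE, df, alpha)),
    )


def power_frame(frame, alpha: float = DEFAULT_ALPHA):
    """Add benchmark and published-effect mixture power columns.

    Expects the output of :func:`litpower.effectsize.estimate_frame`
    (needs ``df`` and ``d_mixture``); adds ``power_small``,
    ``power_medium``, ``power_large`` and ``power_published``.
    """
    out = frame.copy()
    df = out["df"].to_numpy()
    out["power_small"] = power_mixture(D_SMALL, df, alpha)
    out["power_medium"] = power_mixture(D_MEDIUM, df, alpha)
    out["power_large"] = power_mixture(D_LARGE, df, alpha)
    out["power_published"] = power_mixture(out["d_mixture"].to_numpy(), df, alpha)
    return out
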