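"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library's analytic code paths: power comes
from simulating raw data and running the t-test; false report fractions
come from simulating the NHST publication process study by study; ECDF
distances come from direct counting.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

_CHUNK_CELLS = 4_000_000


def mc_power_onesample(d: float, df: int, alpha: float, reps: int, rng) -> float:
    """Raw-data one-sample t-test power (n = df + 1)."""
    n = df + 1
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    hits = 0
    done = 0
    step = max(1, _CHUNK_CELLS // n)
    while done < reps:
        m = min(step, reps - done)
        x = rng.standard_normal((m, n)) + d
        t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
        hits += int((np.abs(t) > tcrit).sum())
        done += m
    return hits / reps


def mc_power_twosample(d: float, df: int, alpha: float, reps: int, rng) -> float:
    """Raw-data two-sample t-test power with equal groups of
    N = ceil((df + 2) / 2), tested at its own degrees of freedom."""
    n = int(np.ceil((df + 2) / 2))
    tcrit = stats.t.ppf(1 - alpha / 2, 2 * n - 2)
    hits = 0
    done = 0
    step = max(1, _CHUNK_CELLS // (2 * n))
    while done < reps:
        m = min(step, reps - done)
        a = rng.standard_normal((m, n)) + d
        b = rng.standard_normal((m, n))
        sp2 = ((n - 1) * a.var(axis=1, ddof=1) + (n - 1) * b.var(axis=1, ddof=1)) / (2 * n - 2)
        t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(sp2 * 2 / n)
        hits += int((np.abs(t) > tcrit).sum())
        done += m
    return hits / reps


def mc_power_mixture(d: float, df: int, alpha: float, reps: int, rng) -> float:
    """Mixture power: draw the test type per replicate, then simulate it."""
    w = 0.93 if df <= 10 else 0.72
    k1 = rng.binomial(reps, w)
    p1 = mc_power_onesample(d, df, alpha, k1, rng) if k1 else 0.0
    p2 = mc_power_twosample(d, df, alpha, reps - k1, rng) if reps - k1 else 0.0
    return (k1 * p1 + (reps - k1) * p2) / reps


def mc_false_report_fraction(
    odds: float, alpha: float, bias: float, power: float, n_studies: int, rng
) -> tuple[float, int]:
    """Simulate the NHST reporting process at fixed power.

    Each study is H0 with probability O/(1+O); significance arrives with
    probability alpha under H0 and `power` under H1; a nonsignificant
    result flips to reported-significant with probability `bias`.
    Returns (false fraction among reported-significant, number significant).
    """
    h0 = rng.random(n_studies) < odds / (1 + odds)
    p_sig = np.where(h0, alpha, power)
    sig = rng.random(n_studies) < p_sig
    flip = (~sig) & (rng.random(n_studies) < bias)
    reported_sig = sig | flip
    n_sig = int(reported_sig.sum())
    false_frac = float(h0[reported_sig].mean()) if n_sig else np.nan
    return false_frac, n_sig


def ecdf_sup_distance(a, b) -> float:
    """Direct sup-distance between two empirical CDFs by counting."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / a.size
    fb = np.searchsorted(b, grid, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))
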