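"""Descriptive aggregation of record-level effects and power.

Summaries by subfield / journal / whole literature, split by recomputed
significance; cumulative distributions; the Pearson correlation between
journal-level median power and five-year impact factor with a BCa
bootstrap confidence interval; and a two-sample Kolmogorov-Smirnov
comparison used to validate extracted against manually collected df
distributions.

Quantiles use linear interpolation on the order statistics (type 7,
numpy's default); this convention is stated so that small mismatches
against other software can be attributed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records_io import JournalMeta

_QUANTILE_METHOD = "linear"

_POWER_COLS = ("power_small", "power_medium", "power_large")


def _group_stats(g: pd.DataFrame, group: str, significance: str) -> dict:
    q = lambda col, p: float(np.quantile(g[col].to_numpy(dtype=float), p, method=_QUANTILE_METHOD))
    row = {
        "group": group,
        "significance": significance,
        "n_records": int(len(g)),
        "n_papers": int(g["paper_id"].nunique()) if "paper_id" in g else 0,
        "median_d": q("d_mixture", 0.5),
        "q25_d": q("d_mixture", 0.25),
        "q75_d": q("d_mixture", 0.75),
        "median_df": q("df", 0.5),
        "q25_df": q("df", 0.25),
        "q75_df": q("df", 0.75),
    }
    for col in _POWER_COLS:
        if col in g:
            row[f"median_{col}"] = q(col, 0.5)
            row[f"mean_{col}"] = float(g[col].mean())
    return row


def summarize(
    records_power: pd.DataFrame,
    journals: Sequence[JournalMeta] | None = None,
    by: str = "all",
) -> pd.DataFrame:
    """Group-level medians/quartiles of D, df and benchmark power.

    ``by`` is one of ``all``, ``subfield``, ``journal``. Each group is
    reported three times: for significant, nonsignificant and all
    records. Groups with zero records are omitted.
    """
    frame = records_power
    if by not in ("all", "subfield", "journal"):
        raise ValueError(f"unknown grouping {by!r}")
    if by == "all":
        frame = frame.assign(_group="all")
    else:
        if journals is None:
            raise ValueError(f"grouping by {by!r} requires journal metadata")
        meta = {j.journal_id: j for j in journals}
        unresolved = sorted(
            set(frame["journal_id"].dropna()) - set(meta)
        )
        if unresolved or frame["journal_id"].isna().any():
            missing = unresolved + (["<missing>"] if frame["journal_id"].isna().any() else [])
            raise ValueError(f"unresolvable journal_id values: {missing}")
        if by == "journal":
            frame = frame.assign(_group=frame["journal_id"])
        else:
            frame = frame.assign(
                _group=frame["journal_id"].map(lambda j: meta[j].subfield)
            )
    rows = []
    for group, g in frame.groupby("_group", sort=True):
        splits = {
            "all": g,
            "significant": g[g["significant"]],
            "nonsignificant": g[~g["significant"]],
        }
        for label, sub in splits.items():
            if len(sub) == 0:
                continue
            rows.append(_group_stats(sub, str(group), label))
    return pd.DataFrame(rows)


def cumulative_distribution(values, grid) -> pd.DataFrame:
    """Fraction of values at or above each threshold of an ascending grid."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be nonempty")
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    frac = np.array([np.mean(values >= g) for g in grid])
    return pd.DataFrame({"threshold": grid, "fraction_at_least": frac})


def correlate_power_impact(
    median_powers,
    impact_factors,
    n_boot: int = 100_000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Pearson r between journal median power and impact factor, BCa CI.

    Bias correction comes from the bootstrap distribution and
    acceleration from the jackknife; deterministic for a given seed.
    """
    x = np.asarray(median_powers, dtype=float)
    y = np.asarray(impact_factors, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")

    def pearson(xs, ys, axis=-1):
        xs = xs - np.mean(xs, axis=axis, keepdims=True)
        ys = ys - np.mean(ys, axis=axis, keepdims=True)
        num = np.sum(xs * ys, axis=axis)
        den = np.sqrt(np.sum(xs**2, axis=axis) * np.sum(ys**2, axis=axis))
        return num / den

    r = float(pearson(x, y))
    rng = np.random.default_rng(seed)
    res = stats.bootstrap(
        (x, y),
        pearson,
        paired=True,
        vectorized=True,
        n_resamples=n_boot,
        confidence_level=level,
        method="BCa",
        rng=rng,
    )
    ci = (float(res.confidence_interval.low), float(res.confidence_interval.high))
    return r, ci


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
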