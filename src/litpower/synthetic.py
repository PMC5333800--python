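"""Generative simulator for a t-test literature with selection and bias.

Each simulated study draws, in order: whether the alternative hypothesis
is true (prestudy H0:H1 odds O give P(H0) = O/(1+O)); degrees of freedom
from a discretized lognormal (right-skewed, defaults tuned to median 20
with mode near 15, matching what large text-mined samples of this
literature show); a test type (one-sample/matched with the same
df-conditional probabilities the analysis assumes); a true effect |d|
(zero under H0, lognormal under H1); and a t statistic built from its
exact stochastic representation t = (Z + delta) / sqrt(chi2_df / df).

Reporting then distorts the record stream the way the publication process
does: nonsignificant results are published only with probability
``select_nonsig``; a fraction ``bias_u`` of would-be-nonsignificant
results is flipped to a significant-looking report (p drawn just under
alpha, t just above the critical value); reported t and p are rounded to
the precision journals print.

:func:`render_lines` turns published records into article-like plain text
in several reporting dialects, optionally garbling a fraction with a line
break inside the record, which is what defeats line-based extraction in
real PDFs. Together the two stages make every pipeline stage testable
end-to-end with known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effectsize import (
    ONE_SAMPLE_DF_CUT,
    W_ONESAMPLE_HIGH_DF,
    W_ONESAMPLE_LOW_DF,
    d_onesample,
    d_twosample,
)
from .power import ONE_SAMPLE, TWO_SAMPLE, noncentrality, power_t
from .records_io import JournalMeta, StatRecord

#: reporting templates; ``{d}`` clauses are used only when a d is reported
DEFAULT_DIALECTS = (
    "t({df}) = {t}, p {pcmp} {p}",
    "t({df})={t}; p {pcmp} {p}",
    "t({df}) = {t}, p {pcmp} {p}, d = {d}",
    "(t({df}) = {t}; p {pcmp} {p}; d = {d})",
)

_FILLER = (
    "Participants completed the task in a quiet room.",
    "Reaction times were trimmed before analysis.",
    "The interaction did not reach significance in the control group.",
    "Accuracy was high across conditions.",
    "Stimuli were counterbalanced across blocks.",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Simulator parameters; the defaults are the study conditions.

    ``df_median``/``df_sigma`` parameterize the discretized lognormal over
    df (the default sigma places the lognormal mode at 15 when the median
    is 20). ``effect_median``/``effect_sigma`` parameterize |d| under H1.
    ``report_d_rate`` is the fraction of records that also report a
    Cohen's d, matching the roughly 8% seen in mined corpora.
    """

    n_studies: int = 10_000
    odds_h0_h1: float = 1.0
    effect_median: float = 0.5
    effect_sigma: float = 0.5
    df_median: float = 20.0
    df_sigma: float = math.sqrt(math.log(20.0 / 15.0))
    alpha: float = 0.05
    select_nonsig: float = 0.2
    bias_u: float = 0.0
    report_d_rate: float = 0.08
    records_per_paper: float = 7.0
    n_journals: int = 18
    dialects: tuple[str, ...] = DEFAULT_DIALECTS
    malformed_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if self.odds_h0_h1 < 0:
            raise ValueError("odds_h0_h1 must be >= 0")
        for name in ("alpha", "select_nonsig", "bias_u", "report_d_rate", "malformed_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.effect_median <= 0 or self.effect_sigma < 0:
            raise ValueError("effect distribution parameters must be positive")
        if self.df_median < 1 or self.df_sigma < 0:
            raise ValueError("df distribution parameters must be positive")
        if not self.dialects:
            raise ValueError("dialect list must be nonempty")
        if self.records_per_paper < 1:
            raise ValueError("records_per_paper must be >= 1")


def _draw_df(rng: np.random.Generator, n: int, cfg: SyntheticConfig) -> np.ndarray:
    raw = rng.lognormal(mean=math.log(cfg.df_median), sigma=cfg.df_sigma, size=n)
    return np.maximum(1, np.round(raw)).astype(int)


def _onesample_share(df: np.ndarray) -> np.ndarray:
    return np.where(df <= ONE_SAMPLE_DF_CUT, W_ONESAMPLE_LOW_DF, W_ONESAMPLE_HIGH_DF)


def _draw_t(rng: np.random.Generator, df: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Exact t draw: (Z + delta) / sqrt(chi2_df / df), with a random sign
    convention carried by the sign of delta (delta >= 0 here, so negative
    observed t arises only through sampling noise)."""
    z = rng.standard_normal(df.size)
    denom = np.sqrt(rng.chisquare(df) / df)
    return (z + delta) / denom


def simulate_literature(
    config: SyntheticConfig,
) -> tuple[list[StatRecord], pd.DataFrame]:
    """Simulate a literature; returns published records plus full truth.

    The truth table has one row per simulated study (published or not);
    its ``published`` column marks the rows that appear, in the same
    order, in the returned record list. Reproducible bit-for-bit from
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_studies

    p_h0 = config.odds_h0_h1 / (1.0 + config.odds_h0_h1) if np.isfinite(config.odds_h0_h1) else 1.0
    h1_true = rng.random(n) >= p_h0
    df = _draw_df(rng, n, config)
    one_sample = rng.random(n) < _onesample_share(df)
    true_d = np.where(
        h1_true,
        rng.lognormal(mean=math.log(config.effect_median), sigma=config.effect_sigma, size=n),
        0.0,
    )

    delta = np.where(
        one_sample,
        noncentrality(true_d, df, ONE_SAMPLE),
        noncentrality(true_d, df, TWO_SAMPLE),
    )
    t_latent = _draw_t(rng, df, delta)
    p_latent = 2.0 * stats.t.sf(np.abs(t_latent), df)
    significant_latent = p_latent <= config.alpha

    flip = (~significant_latent) & (rng.random(n) < config.bias_u)
    publish_nonsig = rng.random(n) < config.select_nonsig
    published = significant_latent | flip | publish_nonsig

    # reported values at journal precision
    t_reported = np.round(t_latent, 2)
    p_exact = p_latent.copy()
    p_cmp = np.where(p_exact < 0.001, "<", "=")
    p_reported = np.where(p_exact < 0.001, 0.001, np.round(p_exact, 3))
    p_reported = np.maximum(p_reported, 0.001)

    # bias-flipped studies get a significant-looking report: p drawn just
    # below alpha and t regenerated just above the critical value
    if flip.any():
        idx = np.flatnonzero(flip)
        p_fake = np.round(rng.uniform(0.6 * config.alpha, 0.98 * config.alpha, idx.size), 3)
        p_fake = np.clip(p_fake, 0.001, None)
        t_fake = stats.t.ppf(1.0 - p_fake / 2.0, df[idx])
        t_fake = np.ceil(t_fake * 100) / 100  # round upward: stays significant
        sign = np.where(t_latent[idx] < 0, -1.0, 1.0)
        t_reported[idx] = sign * t_fake
        p_cmp[idx] = "="
        p_reported[idx] = p_fake

    report_d = rng.random(n) < config.report_d_rate
    d_rep = np.where(
        one_sample,
        d_onesample(t_reported, df),
        d_twosample(t_reported, df),
    )
    d_rep = np.round(d_rep, 2)

    true_power = np.where(
        one_sample,
        power_t(true_d, df, ONE_SAMPLE, config.alpha),
        power_t(true_d, df, TWO_SAMPLE, config.alpha),
    )

    # assign published records to papers and papers to journals
    pub_idx = np.flatnonzero(published)
    paper_ids = np.empty(n, dtype=object)
    journal_ids = np.empty(n, dtype=object)
    paper_no = 0
    i = 0
    journal_choices = rng.integers(0, config.n_journals, size=max(1, pub_idx.size))
    while i < pub_idx.size:
        size = 1 + rng.poisson(max(config.records_per_paper - 1, 0))
        chunk = pub_idx[i : i + size]
        pid = f"paper{paper_no:05d}"
        jid = f"J{journal_choices[paper_no % journal_choices.size] + 1:02d}"
        paper_ids[chunk] = pid
        journal_ids[chunk] = jid
        paper_no += 1
        i += size

    truth = pd.DataFrame(
        {
            "study_id": np.arange(n),
            "h1_true": h1_true,
            "true_d": true_d,
            "test_type": np.where(one_sample, ONE_SAMPLE, TWO_SAMPLE),
            "df": df,
            "t_latent": t_latent,
            "p_latent": p_latent,
            "significant_latent": significant_latent,
            "bias_flipped": flip,
            "published": published,
            "true_power": true_power,
            "t_reported": t_reported,
            "p_cmp": p_cmp,
            "p_reported": p_reported,
            "d_reported": np.where(report_d, d_rep, np.nan),
            "paper_id": paper_ids,
            "journal_id": journal_ids,
        }
    )

    records = [
        StatRecord(
            df=int(df[i]),
            t_value=float(t_reported[i]),
            paper_id=str(paper_ids[i]),
            journal_id=str(journal_ids[i]),
            p_cmp=str(p_cmp[i]),
            p_reported=float(p_reported[i]),
            d_reported=float(d_rep[i]) if report_d[i] else None,
        )
        for i in pub_idx
    ]
    return records, truth


def _fmt_num(x: float, decimals: int, strip_zero: bool) -> str:
    s = f"{x:.{decimals}f}"
    if strip_zero and s.startswith("0."):
        s = s[1:]
    elif strip_zero and s.startswith("-0."):
        s = "-" + s[2:]
    return s


@dataclass(frozen=True)
class RenderResult:
    """Rendered corpus plus per-record rendering bookkeeping."""

    corpus: dict[str, str]
    info: pd.DataFrame  # record_index, paper_id, dialect, malformed


def render_record(record: StatRecord, dialect: str, strip_zero: bool = True) -> str:
    """Render one record in one dialect template."""
    if "{d}" in dialect and record.d_reported is None:
        raise ValueError("dialect has a d clause but the record reports no d")
    return dialect.format(
        df=record.df,
        t=f"{record.t_value:.2f}",
        pcmp=record.p_cmp or "=",
        p=_fmt_num(record.p_reported if record.p_reported is not None else 1.0, 3, strip_zero),
        d="" if record.d_reported is None else f"{record.d_reported:.2f}",
    )


def render_lines(
    records: Sequence[StatRecord],
    dialects: Sequence[str] = DEFAULT_DIALECTS,
    malformed_rate: float = 0.0,
    seed: int = 0,
) -> RenderResult:
    """Render records into per-paper article-like text bodies.

    Every record is printed on its own line embedded in filler prose; a
    record chosen as malformed (probability ``malformed_rate``) is broken
    across a line just before its p clause, which makes it unparseable by
    line-based extraction — by construction, never a false positive.
    """
    if not dialects:
        raise ValueError("dialect list must be nonempty")
    rng = np.random.default_rng(seed)
    plain = [d for d in dialects if "{d}" not in d]
    with_d = [d for d in dialects if "{d}" in d]
    if not plain:
        raise ValueError("need at least one dialect without a d clause")

    bodies: dict[str, list[str]] = {}
    info_rows = []
    for i, rec in enumerate(records):
        pid = rec.paper_id or "paper00000"
        lines = bodies.setdefault(pid, [str(_FILLER[len(bodies) % len(_FILLER)])])
        # rendering must be lossless for well-formed lines: a record with a
        # reported d keeps its d clause
        pool = (with_d or plain) if rec.d_reported is not None else plain
        dialect = pool[rng.integers(0, len(pool))]
        rendered = render_record(rec, dialect, strip_zero=bool(rng.integers(0, 2)))
        malformed = bool(rng.random() < malformed_rate)
        if malformed:
            # break the record just before the p clause
            cut = rendered.lower().find("p", 1)
            rendered = rendered[:cut].rstrip() + "\n" + rendered[cut:]
        prefix = _FILLER[int(rng.integers(0, len(_FILLER)))]
        lines.append(f"{prefix} The test was reliable, {rendered}.")
        info_rows.append(
            {"record_index": i, "paper_id": pid, "dialect": dialect, "malformed": malformed}
        )
    corpus = {pid: "\n".join(lines) + "\n" for pid, lines in bodies.items()}
    return RenderResult(corpus=corpus, info=pd.DataFrame(info_rows))


def exaggeration_summary(
    records: Sequence[StatRecord],
    truth: pd.DataFrame,
    bins: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Winner's-curse summary: published-significant vs all-study D.

    Groups studies by true effect size and reports the mean estimated
    D (mixture conversion of the t statistic) among published records the
    pipeline would call significant, against the mean over all generated
    studies. ``records`` must align with the truth table's published rows.
    """
    from .effectsize import d_mixture as _dmix, p_two_sided as _p2

    n_pub = int(truth["published"].sum())
    if len(records) != n_pub:
        raise ValueError(
            f"records ({len(records)}) do not align with truth's published rows ({n_pub})"
        )
    t_all = truth["t_latent"].to_numpy()
    df_all = truth["df"].to_numpy()
    d_all = _dmix(t_all, df_all)

    pub = truth[truth["published"]].reset_index(drop=True)
    t_rep = np.array([r.t_value for r in records])
    df_rep = np.array([r.df for r in records])
    d_pub = _dmix(t_rep, df_rep)
    sig_pub = _p2(t_rep, df_rep) <= 0.05

    if bins is None:
        labels_all = truth["true_d"].round(6)
        labels_pub = pub["true_d"].round(6)
    else:
        labels_all = pd.cut(truth["true_d"], bins)
        labels_pub = pd.cut(pub["true_d"], bins)

    all_means = pd.Series(d_all).groupby(labels_all.to_numpy()).mean()
    sig_frame = pd.DataFrame({"d": d_pub[sig_pub]}, index=None)
    sig_frame["bin"] = labels_pub.to_numpy()[sig_pub]
    sig_means = sig_frame.groupby("bin")["d"].mean()

    out = pd.DataFrame(
        {
            "true_d_bin": all_means.index,
            "mean_d_all": all_means.to_numpy(),
        }
    )
    out["mean_d_significant_published"] = out["true_d_bin"].map(sig_means)
    return out


def default_journals(seed: int = 0) -> list[JournalMeta]:
    """A synthetic 18-journal metadata table.

    Journal names and subfield labels mirror a typical cognitive
    neuroscience / psychology / medical sample (10 + 5 + 3). The
    five-year impact factors are synthetic stand-ins drawn to span the
    2.4-17.2 range, with neuroscience journals toward the top; they are
    not the actual 2014 values.
    """
    names = [
        ("Nature Neuroscience", "neuroscience"),
        ("Neuron", "neuroscience"),
        ("Brain", "neuroscience"),
        ("The Journal of Neuroscience", "neuroscience"),
        ("Cerebral Cortex", "neuroscience"),
        ("NeuroImage", "neuroscience"),
        ("Cortex", "neuroscience"),
        ("Biological Psychology", "neuroscience"),
        ("Neuropsychologia", "neuroscience"),
        ("Neuroscience", "neuroscience"),
        ("Psychological Science", "psychology"),
        ("Cognitive Science", "psychology"),
        ("Cognition", "psychology"),
        ("Acta Psychologica", "psychology"),
        ("Journal of Experimental Child Psychology", "psychology"),
        ("Biological Psychiatry", "medical"),
        ("Journal of Psychiatric Research", "medical"),
        ("Neurobiology of Aging", "medical"),
    ]
    rng = np.random.default_rng(seed)
    out = []
    for i, (name, subfield) in enumerate(names):
        base = {"neuroscience": 9.0, "psychology": 4.5, "medical": 6.0}[subfield]
        impact = float(np.clip(base + rng.normal(0, 2.5), 2.4, 17.2))
        out.append(
            JournalMeta(
                journal_id=f"J{i + 1:02d}",
                name=name,
                subfield=subfield,
                impact_factor_5yr=round(impact, 3),
            )
        )
    return out
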