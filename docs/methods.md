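# Methods

This note records the statistical model behind `litpower`, the choices
made where the design was genuinely open, and what the synthetic
validation does and does not establish about real literatures.

## Extraction

Article bodies are treated as plain text (PDF-to-text conversion is
upstream of this package). Phase one scans each physical line for `t`
anchors: windows of 65 characters are read from each anchor, counted
*after* space removal and lowercasing, so any amount of whitespace
between tokens is immaterial. A `t(` anchor is always considered; a bare
`t` anchor only if an `=` or `(` occurs inside the window, which bounds
the false-anchor explosion from ordinary prose. A window survives only if
it contains one of `=`, `<`, `>` *and* a `p=`, `p<` or `p>` token —
demanding a complete record keeps false alarms at zero at the price of
missing stand-alone t-values (`t < 1`), which is the right trade for a
survey whose conclusions must not be contaminated by junk matches.

Phase two parses surviving windows with a start-anchored pattern for the
`t(df)=x.xx ... p=y.yy [... d=z.zz]` family. Accepted number forms are
`2.45`, `.022`, `0.022`; thousands separators are not accepted inside
numbers; Unicode minus and ASCII hyphen are both accepted; clause
separators may be `,`, `;`, `:` or nothing. A double df slot (`t(2,45)`,
an F-style pattern) never matches. Non-matching windows yield nothing —
never a partial record. The shipped dialect registry covers these
variants; it is a tuple of templates and can be extended.

Cleaning drops, in document order and with machine-readable reasons:
records whose statistical fields equal the *immediately preceding* kept
record (the same report captured twice via a stray anchor; global
deduplication would wrongly discard legitimately repeated statistics),
records with df < 1 or negative reported p (artifacts of odd character
sets), and records with df > 10,000 (outliers). Cleaning is idempotent.

## Effect sizes

Each record's Cohen's D is the df-conditional mixture
`D = w(df)·D_t1 + (1−w(df))·D_t2` with `w(df) = 0.93` for df ≤ 10, else
`0.72` — the one-sample/matched shares a hand-validation of such records
supports. Components: `D_t1 = |t|/√(df+1)` (one-sample; a matched test
with between-measure correlation 0.5 converts identically) and
`D_t2 = |t|·√(2/N)` with `N = ⌈(df+2)/2⌉` equal-group sizes (the ceiling
slightly flatters sample size, making downstream power generous).
Magnitudes only — the sign of t carries no information about effect
size here. Significance is recomputed two-sided from (t, df) at α = 0.05
instead of trusting reported p, which is often only an inequality; this
makes the significant/nonsignificant split deterministic.

A structural property worth knowing: applied to a *single* study of
known type, the mixture estimator is not unbiased — for a one-sample
study `D_t2 ≈ 2d` and for a two-sample study `D_t1 ≈ d/2`, so the
mixture overshoots an individual true d by ≈10% at w = 0.72 even at
power → 1. The mixture is calibrated for the population of records, not
for any one study; the test suite asserts exactly this (convergence of
significant-record means to all-record means at high power, not
convergence to the true d).

## Power

Two-sided power is exact noncentral-t:
`P(|T'(df, δ)| > t_crit(α, df))`, with δ = d·√(df+1) (one-sample) or
d·√(N/2) (two-sample), mixed with the same w(df). The record's reported
df is used in both branches — everything is conditioned on what the
literature actually prints. At d = 0 power reduces to α exactly (the
central-t path is special-cased; scipy's noncentral CDF is slightly less
accurate at zero noncentrality, and its opposite-tail term underflows to
NaN at large noncentrality, where it is replaced by its limit, 0).
Benchmark powers use d = 0.2 / 0.5 / 0.8; `power_published` uses the
record's own D.

## False report probability

With prestudy H0:H1 odds O, level α, bias u and power P, the model is

    FRP = (Oα + uO(1−α)) / (Oα + uO(1−α) + P + u(1−P)) ,  TRP = 1 − FRP

u acts on nonsignificant outcomes under H0 and H1 alike: it reduces to
Oα/(Oα+P) at u = 0 and to the prior P(H0) = O/(O+1) at u = 1 (with total
bias every result is significant, so significance carries no
information). A variant for settings where significant-but-tiny effects
should count as false reports replaces P by the split
`(Oα + P_S·pr(S)) / (Oα + P_S·pr(S) + P_L·pr(L))`.

`expected_frp` weighs record-level FRP by the empirical distribution —
per-record weights 1/N rather than a binned (df, D) grid, which has the
identical expectation without binning arbitrariness. All records enter,
significant and nonsignificant; each contributes the power to detect its
own published D. Published effects are inflated by selection, those
powers are therefore optimistic, and E[FRP] is a *lower limit* — the
package's FRP curves should be read as best-case floors.

O is a scenario parameter throughout; no attempt is made to estimate it
from data.

## The synthetic literature

The simulator draws, per study: H1 truth with P(H0) = O/(1+O); df from a
discretized lognormal (default median 20, σ = √ln(4/3) ≈ 0.536, which
places the continuous mode at 15 — the shape large mined corpora show);
test type with the same w(df) as the analysis; true |d| under H1 from a
lognormal (default median 0.5, σ_log 0.5 — a realistic mix of mostly
small-to-medium true effects with a heavy right tail); then t from its
exact stochastic representation (Z + δ)/√(χ²_df/df). Reporting applies
journal precision (t to 2 decimals, p to 3, `p < .001` below that),
publishes significant results always and nonsignificant ones with
probability `select_nonsig` (default 0.2, chosen so that ≈64% of
published records are significant under the other defaults, matching
observed literatures), and flips a fraction `bias_u` of
would-be-nonsignificant results into significant-looking reports (p
drawn just under α, t regenerated just above the critical value and
rounded upward so downstream recomputation also classifies them
significant — bias is defined at the reporting level). About 8% of
records carry a Cohen's d clause, rendered losslessly; 5% of rendered
records are broken across a line break inside the record, the failure
mode that defeats line-based extraction in real PDF text.

What passing the synthetic suite shows: the analytic power and FRP
models agree with brute-force simulation; the extraction grammar is
complete and false-alarm-free *for the shipped dialects*; the estimation
chain is self-consistent end-to-end. What it does not show: coverage of
reporting dialects beyond the registry (real journals use special
typesetting characters), table-formatted statistics (never extracted),
or that real literatures follow these generating distributions — the
defaults emulate their coarse features (df median/mode, significant
share, records per paper), not any particular corpus.

## Numerical and design choices

- Quantiles: linear interpolation on order statistics (numpy type 7),
  stated so cross-software mismatches can be attributed.
- The power–impact-factor correlation is Pearson r over journal medians,
  one correlation per benchmark effect size, with a 95% BCa bootstrap
  interval (bias correction from the bootstrap distribution,
  acceleration from the jackknife; `scipy.stats.bootstrap`,
  deterministic given a seed). BCa is known to undercover slightly at
  n = 18 journals; the suite's coverage check allows 0.90–0.98.
- KS comparison of extracted vs reference df distributions uses the
  asymptotic two-sample statistic/p-value.
- Monte-Carlo problem sizes: power oracle 2×10⁵ raw-data replicates per
  grid cell (MC standard error ≤ 0.0011 against a 0.005 agreement band);
  FRP oracle 10⁶ studies per scenario; end-to-end pipeline check at 10⁵
  studies. The end-to-end FRP concordance is checked in a well-powered
  configuration (fixed d ≈ 1.0, df median 40, no selection of
  nonsignificant results): there the winner's curse is negligible and
  the lower-limit E[FRP] must meet the simulated false fraction; at low
  power it is a floor by design, and the suite asserts the inequality
  structure instead.
- The MAT adapter discovers the internal layout of a deposited archive
  (named df/t/p vectors, or a single records matrix whose columns are
  assigned by value profile) and logs and returns the mapping it used.
- Degenerate inputs: empty record collections, empty samples, constant
  correlation vectors and invalid scenario parameters raise ValueError
  before any computation; parsing never raises on malformed text, it
  returns nothing.

## Known limitations

- One-sample total n is taken as df + 1 and two-sample groups as equal;
  real unbalanced designs bias D_t2 slightly.
- The extraction grammar is validated against its own dialect registry;
  porting to a new corpus requires re-validating recovery on a manual
  sample, as any text-mining survey must.
- E[FRP] is an average of record-level ratios (matching the weighting
  definition above), which differs in principle from the ratio of
  aggregated counts when power is heterogeneous; in the well-powered
  validation regime the difference is within Monte-Carlo error.
- Historical power-survey comparisons and F-test records are out of
  scope.
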