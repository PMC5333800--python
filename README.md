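# litpower

Statistical power surveys of a t-test literature: mine full t-test
reports from article text, convert them to standardized effect sizes,
estimate study power, and model how often statistically significant
findings are false.

`litpower` is aimed at meta-researchers studying publication practices in
cognitive neuroscience, psychology and neighbouring fields, where results
are overwhelmingly reported as `t(df) = x.xx, p = y.yy` (sometimes with a
Cohen's `d = z.zz` clause). From nothing but those printed numbers the
package reconstructs, at literature scale, the three quantities that
govern the credibility of a field: the distribution of published effect
sizes, the distribution of statistical power, and the false report
probability.

## The model

**Effect sizes.** A reported t statistic does not reveal its design, so
each record's Cohen's D is a df-conditional mixture of the two standard
conversions,

    D = pr(t1 | df) · D_t1 + pr(t2 | df) · D_t2

    D_t1 = |t| / √(df + 1)                     one-sample / matched (r = 0.5)
    D_t2 = |t| · √(2 / N),  N = ⌈(df + 2)/2⌉   two equal groups

with pr(t1 | df) = 0.93 for df ≤ 10 and 0.72 otherwise — the
one-sample/matched shares observed when such records are validated by
hand.

**Power.** Two-sided power at level α comes from the noncentral t
distribution, P(|T'(df, δ)| > t_crit), with noncentrality δ = d·√(df+1)
(one-sample) or d·√(N/2) (two-sample), mixed with the same weights. Power
is computed per record for benchmark effects d = 0.2 / 0.5 / 0.8 and for
the record's own published D.

**False report probability.** With prestudy H0:H1 odds O, significance
level α, bias u (the fraction of would-be-nonsignificant results reported
as significant anyway) and power,

    FRP = (Oα + uO(1−α)) / (Oα + uO(1−α) + power + u(1−power))

and the literature-wide expectation E[FRP] averages the record-level FRP
over the empirical (df, D) distribution. Because published effects are
inflated by significance selection (the winner's curse), powers computed
from them are overestimates and E[FRP] is a lower limit.

**Synthetic literatures.** A generative simulator draws studies from an
H0/H1 mixture, samples df from a right-skewed distribution (median 20,
mode ≈ 15 by default), applies significance selection and the bias flip,
and renders the surviving records as article-like text in several
reporting dialects — so extraction, estimation, power and FRP can all be
validated end-to-end against known ground truth, with no external data.

## Worked example

```python
from litpower import (SyntheticConfig, simulate_literature, render_lines,
                      extract_records, clean_records, estimate_frame, power_frame,
                      expected_frp, FRPSpec)
from litpower.records_io import records_to_frame
import numpy as np

cfg = SyntheticConfig(n_studies=20_000, seed=42)
records, truth = simulate_literature(cfg)
corpus = render_lines(records, cfg.dialects, malformed_rate=0.05, seed=43)

extracted = []
for paper_id, body in corpus.corpus.items():
    extracted.extend(extract_records(body, paper_id=paper_id))
kept, dropped = clean_records(extracted)
print(f"published records: {len(records)}, recovered: {len(kept)} "
      f"({100 * len(kept) / len(records):.1f}%)")

frame = power_frame(estimate_frame(records_to_frame(kept)))
sig = frame[frame.significant]
print(f"significant share: {100 * len(sig) / len(frame):.1f}%")
print(f"median D (significant): {np.median(sig.d_mixture):.3f}")
print(f"median power for d = 0.2 / 0.5 / 0.8: "
      f"{np.median(frame.power_small):.2f} / "
      f"{np.median(frame.power_medium):.2f} / "
      f"{np.median(frame.power_large):.2f}")

frp = expected_frp(frame.power_published.to_numpy(), FRPSpec(odds_h0_h1=1.0))
print(f"expected FRP at 1:1 odds, no bias: {100 * frp.frp:.1f}%")
```

Output:

```
published records: 8650, recovered: 8201 (94.8%)
significant share: 65.8%
median D (significant): 0.861
median power for d = 0.2 / 0.5 / 0.8: 0.13 / 0.50 / 0.81
expected FRP at 1:1 odds, no bias: 13.6%
```

Reading it: extraction recovers ~95% of the rendered records (the rest
were deliberately broken across line breaks) with zero false alarms;
about two thirds of published records are significant; significant
effects cluster near D ≈ 0.9 — far above the simulated true effects,
whose median is 0.5 — because low power inflates what survives the
significance filter; median power to detect a small effect is a dismal
0.13; and even in the optimistic scenario where half of all tested
hypotheses are true and nothing else goes wrong, roughly one significant
finding in seven is false.

The same pipeline runs from the shell:

```bash
litpower simulate --out-dir corpus/ --n-studies 20000 --seed 42
litpower extract  --in corpus/corpus --out records.csv
litpower estimate --in records.csv --out effects.csv
litpower power    --in effects.csv  --out powered.csv
litpower survey   --in powered.csv  --by all --out summary.csv
litpower frp      --in powered.csv  --odds 1,5,13 --bias 0,0.1,0.3 --out frp.csv
```

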