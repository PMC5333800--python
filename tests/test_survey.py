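import numpy as np
import pandas as pd
import pytest

from litpower.records_io import JournalMeta
from litpower.survey import (
    correlate_power_impact,
    cumulative_distribution,
    ks_two_sample,
    summarize,
)

from _oracles import ecdf_sup_distance


def _toy_frame():
    return pd.DataFrame(
        {
            "paper_id": ["a", "a", "b", "c", "c", "d"],
            "journal_id": ["J01", "J01", "J01", "J02", "J02", "J02"],
            "df": [10, 20, 30, 15, 25, 35],
            "d_mixture": [0.1, 0.2, 0.3, 0.5, 0.9, 1.4],
            "significant": [False, False, True, True, True, True],
            "power_small": [0.1, 0.12, 0.14, 0.11, 0.13, 0.15],
            "power_medium": [0.3, 0.4, 0.5, 0.35, 0.45, 0.55],
            "power_large": [0.6, 0.7, 0.8, 0.65, 0.75, 0.85],
        }
    )


JOURNALS = [
    JournalMeta("J01", "Cortex", "neuroscience", 6.1),
    JournalMeta("J02", "Cognition", "psychology", 4.2),
]


class TestSummarize:
    def test_overall_median_and_quartiles(self):
        table = summarize(_toy_frame(), by="all")
        row = table[(table.group == "all") & (table.significance == "all")].iloc[0]
        vals = np.array([0.1, 0.2, 0.3, 0.5, 0.9, 1.4])
        assert row.median_d == pytest.approx(np.quantile(vals, 0.5))
        assert row.q25_d <= row.median_d <= row.q75_d
        assert row.n_records == 6
        assert row.n_papers == 4

    def test_significance_split_partitions_counts(self):
        table = summarize(_toy_frame(), by="all")
        n_all = int(table[table.significance == "all"].n_records.iloc[0])
        n_sig = int(table[table.significance == "significant"].n_records.iloc[0])
        n_non = int(table[table.significance == "nonsignificant"].n_records.iloc[0])
        assert n_sig + n_non == n_all

    def test_subfield_grouping_partitions_counts(self):
        table = summarize(_toy_frame(), JOURNALS, by="subfield")
        sub = table[table.significance == "all"]
        assert set(sub.group) == {"neuroscience", "psychology"}
        assert sub.n_records.sum() == 6

    def test_unresolvable_journal_is_an_error(self):
        frame = _toy_frame()
        frame.loc[0, "journal_id"] = "J99"
        with pytest.raises(ValueError, match="J99"):
            summarize(frame, JOURNALS, by="subfield")

    def test_generator_medians_recovered(self, default_literature):
        """On a simulated literature the group medians equal direct
        numpy quantiles of the same columns (generator as oracle)."""
        from litpower.effectsize import estimate_frame
        from litpower.power import power_frame
        from litpower.records_io import records_to_frame

        _, records, _ = default_literature
        frame = power_frame(estimate_frame(records_to_frame(records)))
        table = summarize(frame, by="all")
        row = table[table.significance == "significant"].iloc[0]
        direct = frame[frame.significant]
        assert row.median_d == pytest.approx(np.median(direct.d_mixture))
        assert row.median_power_medium == pytest.approx(np.median(direct.power_medium))


class TestCumulative:
    def test_simple_fraction(self):
        out = cumulative_distribution([1, 2, 3], [2])
        assert out.fraction_at_least.iloc[0] == pytest.approx(2 / 3)

    def test_threshold_below_min_gives_one(self):
        out = cumulative_distribution([5, 6], [0])
        assert out.fraction_at_least.iloc[0] == 1.0

    def test_nonincreasing_and_matches_counting_oracle(self, rng):
        values = rng.normal(size=500)
        grid = np.linspace(-3, 3, 25)
        out = cumulative_distribution(values, grid)
        assert (np.diff(out.fraction_at_least) <= 0).all()
        for thr, frac in zip(out.threshold, out.fraction_at_least):
            assert frac == pytest.approx((values >= thr).sum() / 500)

    def test_empty_values_rejected(self):
        with pytest.raises(ValueError):
            cumulative_distribution([], [0.5])


class TestCorrelation:
    def test_perfect_linear_relations(self):
        x = np.arange(1.0, 11.0)
        r, _ = correlate_power_impact(x, 2 * x, n_boot=1000, seed=0)
        assert r == pytest.approx(1.0)
        r, _ = correlate_power_impact(x, -x + 3, n_boot=1000, seed=0)
        assert r == pytest.approx(-1.0)

    def test_deterministic_given_seed(self, rng):
        x, y = rng.normal(size=18), rng.normal(size=18)
        a = correlate_power_impact(x, y, n_boot=2000, seed=42)
        b = correlate_power_impact(x, y, n_boot=2000, seed=42)
        assert a == b

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlate_power_impact(np.ones(5), np.arange(5.0), n_boot=1000)

    def test_bca_interval_coverage_under_independence(self):
        """95% BCa interval covers r=0 about 95% of the time for
        independent vectors at n=18 (BCa undercovers slightly at this n)."""
        rng = np.random.default_rng(12345)
        n_rep, cover = 500, 0
        for i in range(n_rep):
            x, y = rng.normal(size=18), rng.normal(size=18)
            _, (lo, hi) = correlate_power_impact(x, y, n_boot=1999, seed=i)
            cover += lo <= 0 <= hi
        assert 0.90 <= cover / n_rep <= 0.98


class TestKS:
    def test_identical_samples_give_zero(self):
        stat, _ = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert stat == 0.0

    def test_fully_separated_samples_give_one(self):
        stat, p = ks_two_sample([0, 1, 2], [10, 11, 12])
        assert stat == 1.0
        assert p < 0.05

    def test_matches_direct_ecdf_oracle(self, rng):
        a = rng.normal(size=300)
        b = rng.normal(loc=0.4, size=200)
        stat, _ = ks_two_sample(a, b)
        assert stat == pytest.approx(ecdf_sup_distance(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])
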