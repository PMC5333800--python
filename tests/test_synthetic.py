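import numpy as np
import pytest

from litpower.extraction import extract_records
from litpower.records_io import StatRecord
from litpower.synthetic import (
    SyntheticConfig,
    default_journals,
    exaggeration_summary,
    render_lines,
    render_record,
    simulate_literature,
)


class TestSimulate:
    def test_invalid_config_rejected_before_sampling(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_studies=0).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(bias_u=1.5).validate()
        with pytest.raises(ValueError):
            simulate_literature(SyntheticConfig(odds_h0_h1=-1))

    def test_reproducible_bit_for_bit(self):
        cfg = SyntheticConfig(n_studies=2000, seed=9)
        rec_a, truth_a = simulate_literature(cfg)
        rec_b, truth_b = simulate_literature(cfg)
        assert rec_a == rec_b
        assert truth_a.equals(truth_b)

    def test_null_literature_significance_calibrated_to_alpha(self):
        """All-H0 corpus with full publication: the significant fraction
        sits at alpha within binomial error."""
        cfg = SyntheticConfig(
            n_studies=40_000, odds_h0_h1=1e9, bias_u=0.0, select_nonsig=1.0, seed=21
        )
        _, truth = simulate_literature(cfg)
        assert not truth.h1_true.any()
        frac = truth.significant_latent.mean()
        se = np.sqrt(0.05 * 0.95 / len(truth))
        assert abs(frac - 0.05) < 3 * se

    def test_no_selection_of_nonsignificant_means_all_published_significant(self):
        cfg = SyntheticConfig(n_studies=5000, select_nonsig=0.0, bias_u=0.0, seed=4)
        records, truth = simulate_literature(cfg)
        pub = truth[truth.published]
        assert pub.significant_latent.all()
        assert len(records) == len(pub)

    def test_df_distribution_hits_target_median_and_mode(self, default_literature):
        _, _, truth = default_literature
        assert abs(truth.df.median() - 20) <= 2
        mode = truth.df.mode()[0]
        assert 10 <= mode <= 20

    def test_bias_flipped_records_look_significant_downstream(self):
        cfg = SyntheticConfig(n_studies=20_000, bias_u=0.3, select_nonsig=0.0, seed=13)
        records, truth = simulate_literature(cfg)
        flipped = truth[truth.bias_flipped]
        assert len(flipped) > 0
        assert (~flipped.significant_latent).all()  # only nonsig results flip
        from litpower.effectsize import p_two_sided

        p = p_two_sided(flipped.t_reported.to_numpy(), flipped.df.to_numpy())
        assert (p <= cfg.alpha).all()

    def test_truth_published_rows_align_with_records(self, default_literature):
        _, records, truth = default_literature
        pub = truth[truth.published]
        assert len(records) == len(pub)
        assert [r.df for r in records[:100]] == pub.df.tolist()[:100]


class TestRender:
    def test_template_instance(self):
        rec = StatRecord(df=23, t_value=2.45, p_cmp="=", p_reported=0.022)
        line = render_record(rec, "t({df}) = {t}, p {pcmp} {p}", strip_zero=True)
        assert line == "t(23) = 2.45, p = .022"

    def test_well_formed_corpus_round_trips_completely(self, default_literature):
        cfg, records, _ = default_literature
        subset = records[:2000]
        rendered = render_lines(subset, cfg.dialects, malformed_rate=0.0, seed=2)
        extracted = []
        for pid, body in rendered.corpus.items():
            extracted.extend(extract_records(body, paper_id=pid))
        assert len(extracted) == len(subset)
        key = lambda r: (
            r.df,
            r.t_value,
            r.p_cmp,
            r.p_reported,
            -1.0 if r.d_reported is None else r.d_reported,
        )
        assert sorted(map(key, extracted)) == sorted(map(key, subset))

    def test_malformed_records_are_the_only_losses(self, default_literature):
        cfg, records, _ = default_literature
        subset = records[:3000]
        rendered = render_lines(subset, cfg.dialects, malformed_rate=0.05, seed=3)
        extracted = []
        for pid, body in rendered.corpus.items():
            extracted.extend(extract_records(body, paper_id=pid))
        n_malformed = int(rendered.info.malformed.sum())
        assert len(extracted) == len(subset) - n_malformed

    def test_empty_dialect_list_rejected(self):
        with pytest.raises(ValueError):
            render_lines([], dialects=[])


class TestExaggeration:
    def test_misaligned_inputs_rejected(self, default_literature):
        _, records, truth = default_literature
        with pytest.raises(ValueError):
            exaggeration_summary(records[:-1], truth)

    def test_null_effects_yield_positive_significant_mean(self):
        cfg = SyntheticConfig(
            n_studies=30_000, odds_h0_h1=1e9, select_nonsig=1.0, seed=31
        )
        records, truth = simulate_literature(cfg)
        out = exaggeration_summary(records, truth)
        row = out[out.true_d_bin == 0.0].iloc[0]
        assert row.mean_d_significant_published > row.mean_d_all > 0

    def test_exaggeration_shrinks_as_power_grows(self):
        """Winner's curse: the mean significant D over true d falls toward
        1 as df (hence power) increases, monotonically along the grid."""
        ratios = []
        ratios_vs_all = []
        for df_med in (8.0, 20.0, 60.0, 200.0, 1000.0):
            cfg = SyntheticConfig(
                n_studies=30_000,
                odds_h0_h1=0.0,
                effect_median=0.3,
                effect_sigma=1e-9,
                df_median=df_med,
                df_sigma=1e-9,
                select_nonsig=1.0,
                seed=17,
            )
            records, truth = simulate_literature(cfg)
            out = exaggeration_summary(records, truth, bins=[0.0, 1.0])
            sig = float(out.mean_d_significant_published.iloc[0])
            allr = float(out.mean_d_all.iloc[0])
            ratios.append(sig / 0.3)
            ratios_vs_all.append(sig / allr)
        assert all(a > b for a, b in zip(ratios, ratios[1:]))
        assert ratios[0] > 1.5  # strongly inflated when underpowered
        # at high power the significance truncation vanishes: significant
        # and all-study means converge (what remains relative to the true
        # d is the ~10% structural overshoot of applying population
        # mixture weights to individual studies, not truncation)
        assert ratios_vs_all[-1] < 1.01


def test_default_journals_table_shape():
    journals = default_journals()
    assert len(journals) == 18
    subfields = [j.subfield for j in journals]
    assert subfields.count("neuroscience") == 10
    assert subfields.count("psychology") == 5
    assert subfields.count("medical") == 3
    assert all(2.3 < j.impact_factor_5yr < 17.3 for j in journals)
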