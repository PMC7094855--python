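"""ANOVA/Tukey calling cascade, BH correction, and the pattern taxonomy."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from woundca.differential import (
    ALL_PATTERNS,
    anova_per_gene,
    bh_adjust,
    build_threshold_sets,
    call_significance,
    classify_pattern,
    pattern_counts,
    studentized_range_sf,
    tukey_control_contrasts,
)
from woundca.preprocess import normalize_per_array
from woundca.synthetic import StudyConfig, generate_study


def _per_array_log2(sm):
    """Clipped log2 per-array signals (no inter-array shift): the module's input."""
    clipped = sm.signals.where(sm.signals >= 0, 1.0)
    return np.log2(clipped)


class TestAnova:
    def test_equal_group_means_give_zero_f(self):
        groups = [[1.0, 2.0], [2.0, 1.0], [0.5, 2.5]]  # all means 1.5
        f, p = anova_per_gene(groups)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_sum_of_squares(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        # grand mean 5; SSB = 3*((2-5)^2 + (5-5)^2 + (8-5)^2) = 54, df 2
        # SSW = 3 * ((1)^2 + 0 + (1)^2) = 6, df 6 -> F = 27 / 1 = 27
        f, p = anova_per_gene(groups)
        assert f == pytest.approx(27.0, rel=1e-12)
        assert p == pytest.approx(stats.f.sf(27.0, 2, 6), rel=1e-12)

    def test_degenerate_constant_input_is_a_no_call(self):
        f, p = anova_per_gene([[1.0, 1.0], [1.0, 1.0]])
        assert np.isnan(f) and np.isnan(p)

    def test_null_type_one_error_rate(self):
        """Raw ANOVA p < 0.05 on ~5% of null genes (4 groups x 4 replicates)."""
        rng = np.random.default_rng(42)
        n = 10_000
        groups = [rng.normal(size=(n, 4)) for _ in range(4)]
        _, p = stats.f_oneway(*groups, axis=1)
        frac = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < 3 * se

    def test_rejects_single_replicate(self):
        with pytest.raises(ValueError):
            anova_per_gene([[1.0], [2.0]])


class TestTukey:
    def test_identical_control_and_time_gives_p_one(self):
        groups = [[1.0, 1.2, 0.8, 1.0]] * 2 + [[9.0, 9.1, 8.9, 9.0], [5.0, 5.2, 4.8, 5.0]]
        p = tukey_control_contrasts(groups)
        assert p[0] == pytest.approx(1.0)  # zero mean difference
        assert p[1] < 1e-6

    def test_matches_scipy_all_pairs_hsd(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(loc=m, size=4) for m in (0.0, 0.2, 1.0, 0.5)]
        ours = tukey_control_contrasts(groups)
        ref = stats.tukey_hsd(*groups)
        np.testing.assert_allclose(ours, ref.pvalue[0, 1:], rtol=1e-8)

    def test_matches_statsmodels_studentized_range_tables(self):
        """Independent oracle: libqsturng's studentized-range approximation."""
        from statsmodels.stats.libqsturng import psturng

        rng = np.random.default_rng(4)
        for _ in range(5):
            groups = [rng.normal(loc=m, size=4) for m in rng.normal(size=4)]
            ours = tukey_control_contrasts(groups)
            ns = 4
            means = np.array([np.mean(g) for g in groups])
            mse = np.mean([np.var(g, ddof=1) for g in groups])
            q = np.abs(means[1:] - means[0]) / np.sqrt(mse / ns)
            ref = np.atleast_1d(psturng(q, 4, 12))
            # libqsturng is itself a table interpolation, good to ~1%
            np.testing.assert_allclose(
                np.clip(ours, 1e-3, 0.9), np.clip(ref, 1e-3, 0.9), atol=0.015
            )

    def test_interpolated_sf_tracks_exact_sf(self):
        rng = np.random.default_rng(5)
        q = np.abs(rng.normal(scale=5.0, size=80)) + 0.01
        exact = studentized_range_sf(q, 4, 12, method="exact")
        interp = studentized_range_sf(q, 4, 12, method="interp")
        np.testing.assert_allclose(interp, exact, atol=1e-4)

    def test_familywise_error_respects_hsd_guarantee(self):
        """P(any control contrast falsely significant) <= 0.05 under the null."""
        rng = np.random.default_rng(6)
        n = 4000
        groups = [rng.normal(size=(n, 4)) for _ in range(4)]
        from woundca.differential import _tukey_vectorized

        p, _ = _tukey_vectorized(groups, method="interp")
        fwer = (p < 0.05).any(axis=1).mean()
        se = np.sqrt(0.05 * 0.95 / n)
        assert fwer <= 0.05 + 3 * se


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.031]), [0.031])

    def test_equal_ps_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_hand_applied_step_up_rule(self):
        # p_(i) * m / i = (.04, .04, .04, .04) after the step-up minimum
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(7)
        p = rng.random(100)
        assert np.all(bh_adjust(p) >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestPatternCalls:
    def test_planted_patterns_recovered(self):
        """>=95% of the confusion-matrix mass sits on the diagonal at an
        8-fold planted effect, replicate noise sd 0.25, and n = 4."""
        mix = {p: 0.0 for p in ALL_PATTERNS}
        for code, prop in [("UUU", 0.2), ("DDD", 0.2), ("U-D", 0.2), ("---", 0.2), ("-U-", 0.2)]:
            mix[code] = prop
        config = StudyConfig(
            n_genes=1500, noise_log2_sd=0.25, effect_log2fc=3.0, pattern_mix=mix,
            flag_cm_rate=0.0, flag_ndt_rate=0.0, n_terms=1, n_enriched_terms=0, seed=21,
        )
        sm, _, truth = generate_study(config)
        calls = call_significance(_per_array_log2(sm), alpha=0.05)
        diagonal = (calls.patterns == truth.patterns).mean()
        assert diagonal >= 0.95

    def test_all_up_planting_recalled(self):
        """Spec of the generator: a pure (U,U,U) planting at 8-fold is recalled."""
        mix = {p: 0.0 for p in ALL_PATTERNS}
        mix["UUU"] = 1.0
        config = StudyConfig(
            n_genes=800, pattern_mix=mix, effect_log2fc=3.0, noise_log2_sd=0.25,
            flag_cm_rate=0.0, flag_ndt_rate=0.0, n_terms=1, n_enriched_terms=0,
            enrichment_fraction=0.0, term_size=5, seed=22,
        )
        sm, _, _ = generate_study(config)
        calls = call_significance(_per_array_log2(sm), alpha=0.05)
        assert (calls.patterns == "UUU").mean() >= 0.95

    def test_classify_pattern_joins_calls(self, small_study):
        _, sm, _, _ = small_study
        calls = call_significance(normalize_per_array(sm), alpha=0.05)
        gene = calls.calls.index[0]
        assert classify_pattern(calls, gene) == "".join(calls.calls.loc[gene])
        assert set(calls.patterns.unique()) <= set(ALL_PATTERNS)

    def test_pattern_counts_sum_to_gene_count(self, small_study):
        _, sm, _, _ = small_study
        calls = call_significance(normalize_per_array(sm), alpha=0.05)
        counts = pattern_counts(calls.patterns)
        assert len(counts) == 27
        assert counts.sum() == len(calls.calls)

    def test_null_study_rarely_calls_anything(self):
        """Under the global null the BH screen keeps non-'-' calls below alpha."""
        mix = {p: 0.0 for p in ALL_PATTERNS}
        mix["---"] = 1.0
        config = StudyConfig(
            n_genes=4000, pattern_mix=mix, flag_cm_rate=0.0, flag_ndt_rate=0.0,
            n_terms=1, n_enriched_terms=0, seed=23,
        )
        sm, _, _ = generate_study(config)
        calls = call_significance(_per_array_log2(sm), alpha=0.05)
        frac_called = (calls.patterns != "---").mean()
        se = np.sqrt(0.05 * 0.95 / config.n_genes)
        assert frac_called <= 0.05 + 3 * se


class TestThresholdSets:
    @pytest.fixture()
    def calls_and_fc(self):
        genes = ["g1", "g2", "g3", "g4", "g5"]
        calls_df = pd.DataFrame(
            {"t6": ["U", "U", "D", "U", "-"], "t12": ["-"] * 5, "t24": ["-"] * 5},
            index=genes,
        )
        from woundca.differential import SignificanceCalls

        dummy = pd.Series(np.nan, index=genes)
        nan_tbl = pd.DataFrame(np.nan, index=genes, columns=calls_df.columns)
        calls = SignificanceCalls(
            anova_p=dummy, anova_q=dummy, tukey_p=nan_tbl, tukey_q=nan_tbl.copy(),
            calls=calls_df, alpha=0.05,
        )
        fc = pd.DataFrame(
            {"FC6": [4.0, 6.0, 0.25, 10.0, 50.0], "FC12": [1.0] * 5, "FC24": [1.0] * 5},
            index=genes,
        )
        return calls, fc

    def test_membership_rules(self, calls_and_fc):
        calls, fc = calls_and_fc
        up3 = build_threshold_sets(calls, fc, 3, "up", "t6")
        up5 = build_threshold_sets(calls, fc, 5, "up", "t6")
        down3 = build_threshold_sets(calls, fc, 3, "down", "t6")
        down5 = build_threshold_sets(calls, fc, 5, "down", "t6")
        assert "g1" in up3.genes and "g1" not in up5.genes       # FC 4: 3-fold only
        assert "g2" in up3.genes and "g2" in up5.genes           # FC 6: both
        assert "g3" in down3.genes and "g3" not in down5.genes   # FC 0.25: 3-fold only
        assert "g5" not in up3.genes                             # not significant
        assert set(up5.genes) <= set(up3.genes)
        assert not set(up3.genes) & set(down3.genes)

    def test_unknown_time_rejected(self, calls_and_fc):
        calls, fc = calls_and_fc
        with pytest.raises(ValueError):
            build_threshold_sets(calls, fc, 3, "up", "t48")
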