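"""The seeded generator: determinism, planted structure, noise moments."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mirtime.errors import ConfigurationError, InputError
from mirtime.matrix import log_transform, quantile_normalize
from mirtime.pairs import pearson_corr_test
from mirtime.smallrna import length_histogram
from mirtime.synthetic import (
    SynthConfig,
    correlated_series,
    expected_mirna_means,
    gen_annotation,
    gen_ground_truth,
    gen_mirna_counts,
    gen_mrna_expression,
    gen_reference_catalogs,
    gen_tag_library,
    gen_target_predictions,
)


class TestConfigValidation:
    def test_planted_exceeding_total_rejected(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(n_mirna=10, n_planted_up=8, n_planted_updown=5)

    def test_nonmonotone_timepoints_rejected(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(timepoints=(0, 4, 1))

    def test_rates_bounded(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(target_fp_rate=1.5)
        with pytest.raises(ConfigurationError):
            SynthConfig(repression_strength=-0.1)


class TestTagLibrary:
    def test_zero_library_size_empty(self):
        cfg = SynthConfig(seed=1, n_mirna=20, n_mrna=60, n_planted_up=2,
                          n_planted_updown=2, library_size=0)
        lib = gen_tag_library(cfg, "DRG_d0")
        assert lib.n_tags == 0

    def test_seed_determinism_bitwise(self, small_cfg):
        a = gen_tag_library(small_cfg, "DRG_d0")
        b = gen_tag_library(small_cfg, "DRG_d0")
        assert a.tags == b.tags and list(a.tags) == list(b.tags)

    def test_modal_length_is_22(self):
        cfg = SynthConfig(seed=1, n_mirna=60, n_mrna=200, n_planted_up=6,
                          n_planted_updown=6, library_size=10_000)
        lib = gen_tag_library(cfg, "SN_d1")
        hist = length_histogram(lib)
        assert max(hist, key=hist.get) == 22

    def test_invalid_sample_rejected(self, small_cfg):
        with pytest.raises(ConfigurationError):
            gen_tag_library(small_cfg, "LIVER_d0")


class TestMirnaCounts:
    def test_no_signal_rows_flat_in_expectation(self):
        cfg = SynthConfig(seed=2, n_mirna=50, n_mrna=150, n_planted_up=5,
                          n_planted_updown=5, dispersion=0.0, effect_size=1.0)
        mu, _ = expected_mirna_means(cfg, "DRG")
        assert np.allclose(mu.to_numpy(), mu.to_numpy()[:, [0]])

    def test_planted_up_strictly_increasing_without_overdispersion(self):
        cfg = SynthConfig(seed=3, n_mirna=100, n_mrna=300, n_planted_up=10,
                          n_planted_updown=10, dispersion=0.0, effect_size=4.0)
        counts, truth = gen_mirna_counts(cfg, "DRG")
        up = [m for m, k in truth.planted_profile_of.items() if k == "up"]
        diffs = counts.loc[up].diff(axis=1).iloc[:, 1:]
        assert (diffs.to_numpy() > 0).all()

    def test_nb_sample_means_match_configured_means(self):
        # Monte-Carlo across seeds; per-row mean within 3 standard errors
        cfg0 = SynthConfig(seed=0, n_mirna=40, n_mrna=120, n_planted_up=4,
                           n_planted_updown=4, dispersion=0.2)
        m, _ = expected_mirna_means(cfg0, "DRG")
        mu = m.to_numpy()
        rng = np.random.default_rng(123)
        n_draws = 200
        alpha = cfg0.dispersion
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + mu)
        samples = rng.negative_binomial(
            n_param, p_param, size=(n_draws, *mu.shape)
        )
        sample_mean = samples.mean(axis=0)
        se = np.sqrt((mu + alpha * mu**2) / n_draws)
        assert (np.abs(sample_mean - mu) <= 3 * se + 1e-9).mean() > 0.98

    def test_determinism(self, small_cfg):
        a, _ = gen_mirna_counts(small_cfg, "SN")
        b, _ = gen_mirna_counts(small_cfg, "SN")
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_tissue_rejected(self, small_cfg):
        with pytest.raises(ConfigurationError):
            gen_mirna_counts(small_cfg, "LIVER")


class TestMrnaExpression:
    def _norm_mirna(self, cfg):
        counts, truth = gen_mirna_counts(cfg, "DRG")
        return quantile_normalize(log_transform(counts)), truth

    def test_perfect_repression_gives_exact_anticorrelation(self, small_cfg):
        cfg = dataclasses.replace(
            small_cfg, repression_strength=1.0, mrna_noise_sd=0.0
        )
        norm, truth = self._norm_mirna(cfg)
        expr = gen_mrna_expression(cfg, truth, norm)
        from mirtime.pairs import collapse_replicates

        day_means = collapse_replicates(expr)
        m, g = sorted(truth.true_pairs)[0]
        r, _ = pearson_corr_test(
            norm.loc[m].to_numpy(), day_means.loc[g].to_numpy()
        )
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_zero_repression_leaves_targets_unligated(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, repression_strength=0.0)
        norm, truth = self._norm_mirna(cfg)
        expr = gen_mrna_expression(cfg, truth, norm)
        from mirtime.pairs import collapse_replicates

        day_means = collapse_replicates(expr)
        rs = [
            pearson_corr_test(norm.loc[m].to_numpy(), day_means.loc[g].to_numpy())[0]
            for m, g in sorted(truth.true_pairs)[:20]
        ]
        # independent noise: correlations centred on zero, not pinned negative
        assert abs(np.mean(rs)) < 0.5

    def test_missing_regulator_rejected(self, small_cfg):
        norm, truth = self._norm_mirna(small_cfg)
        with pytest.raises(InputError):
            gen_mrna_expression(small_cfg, truth, norm.iloc[:2])

    def test_replicate_count(self, small_cfg):
        norm, truth = self._norm_mirna(small_cfg)
        expr = gen_mrna_expression(small_cfg, truth, norm)
        assert expr.shape[1] == 5 * small_cfg.replicates_per_timepoint


class TestTargetPredictions:
    def test_zero_fp_rate_equals_truth(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, target_fp_rate=0.0)
        truth = gen_ground_truth(cfg)
        a, b = gen_target_predictions(truth, cfg)
        assert a.pairs() == truth.true_pairs == b.pairs()

    def test_intersection_contains_truth(self, small_cfg):
        from mirtime.enrichment import intersect_targets

        truth = gen_ground_truth(small_cfg)
        a, b = gen_target_predictions(truth, small_cfg)
        assert truth.true_pairs <= intersect_targets(a, b).pairs()

    def test_intersection_has_fewer_decoys_on_average(self):
        from mirtime.enrichment import intersect_targets

        ratios = []
        for seed in range(20):
            cfg = SynthConfig(seed=seed, n_mirna=40, n_mrna=150, n_planted_up=6,
                              n_planted_updown=6, target_fp_rate=0.4,
                              targets_per_mirna=3)
            truth = gen_ground_truth(cfg)
            a, b = gen_target_predictions(truth, cfg)
            inter = intersect_targets(a, b)
            decoys_a = len(a.pairs() - truth.true_pairs)
            decoys_i = len(inter.pairs() - truth.true_pairs)
            ratios.append((decoys_i, decoys_a))
        mean_i = np.mean([x for x, _ in ratios])
        mean_a = np.mean([y for _, y in ratios])
        assert mean_i < mean_a


class TestAnnotation:
    def test_planted_term_with_full_overlap_ranks_first(self, small_cfg):
        from mirtime.enrichment import hypergeom_enrichment

        truth = gen_ground_truth(small_cfg)
        ann = gen_annotation(small_cfg, truth)
        query = {g for _, g in truth.true_pairs}
        results = hypergeom_enrichment(query, ann)
        assert results[0].term in truth.enriched_terms

    def test_no_planted_terms_yields_calibrated_nulls(self):
        fracs = []
        for seed in range(5):
            cfg = SynthConfig(seed=seed, n_mirna=40, n_mrna=400, n_planted_up=6,
                              n_planted_updown=6, n_planted_terms=0, n_terms=60)
            truth = gen_ground_truth(cfg)
            ann = gen_annotation(cfg, truth)
            rng = np.random.default_rng(seed)
            query = set(rng.choice(sorted(ann.universe), size=60, replace=False))
            from mirtime.enrichment import hypergeom_enrichment

            results = hypergeom_enrichment(query, ann)
            fracs.append(np.mean([r.qfdr < 0.05 for r in results]))
        assert np.mean(fracs) <= 0.10

    def test_empty_universe_rejected(self):
        with pytest.raises(ConfigurationError):
            cfg = SynthConfig(n_mirna=10, n_mrna=0, n_planted_up=0,
                              n_planted_updown=0, targets_per_mirna=0)
            gen_annotation(cfg, gen_ground_truth(cfg))


class TestCorrelatedSeries:
    @pytest.mark.parametrize("r", [-0.962, -0.5, 0.0, 0.7, 0.999])
    def test_sample_correlation_is_exact(self, r):
        x, y = correlated_series(r, 5)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(r, abs=1e-12)
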