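"""Generator statistics: marginal frequencies, LD structure, discovery
summary calibration, heritability recovery and the mediation chain."""

import numpy as np
import pandas as pd
import pytest

from prsconv.errors import ConfigurationError
from prsconv.simulate import (
    QcViolationRates,
    SimConfig,
    draw_true_betas,
    inject_qc_violations,
    simulate_discovery_summary,
    simulate_genotypes,
    simulate_target_cohort,
    _simulate_discovery,
)


def _pair_r2(dosage, j, k):
    ok = ~np.isnan(dosage[:, j]) & ~np.isnan(dosage[:, k])
    r = np.corrcoef(dosage[ok, j], dosage[ok, k])[0, 1]
    return r * r


class TestGenotypes:
    def test_reproducible_bit_identical(self, small_cfg):
        a = simulate_genotypes(small_cfg)
        b = simulate_genotypes(small_cfg)
        np.testing.assert_array_equal(a.dosage, b.dosage)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_dosage_domain(self, small_panel):
        vals = small_panel.dosage[~np.isnan(small_panel.dosage)]
        assert set(np.unique(vals)) <= {0.0, 1.0, 2.0}

    def test_allele_freq_within_binomial_bound(self):
        cfg = SimConfig(n_target=400, n_variants=200, n_blocks=10,
                        missing_rate=0.0, seed=5)
        panel = simulate_genotypes(cfg)
        f = panel.variants["freq"].to_numpy()
        se = np.sqrt(f * (1 - f) / (2 * cfg.n_target))
        assert np.all(np.abs(panel.allele_freq() - f) <= 4 * se)

    def test_no_copying_means_no_ld(self):
        cfg = SimConfig(n_target=3000, n_variants=20, n_blocks=2, n_causal=5,
                        ld_copy_prob=0.0, missing_rate=0.0, seed=7)
        panel = simulate_genotypes(cfg)
        r2 = [
            _pair_r2(panel.dosage, j, k)
            for j in range(20) for k in range(j + 1, 20)
        ]
        assert max(r2) < 0.01

    def test_high_copy_prob_high_adjacent_r2(self):
        cfg = SimConfig(n_target=5000, n_variants=2, n_blocks=1, n_causal=1,
                        maf_range=(0.3, 0.3), ld_copy_prob=0.99,
                        missing_rate=0.0, seed=3)
        panel = simulate_genotypes(cfg)
        assert _pair_r2(panel.dosage, 0, 1) > 0.8

    def test_ld_decays_with_distance(self):
        cfg = SimConfig(n_target=4000, n_variants=40, n_blocks=2, n_causal=10,
                        ld_copy_prob=0.8, missing_rate=0.0, seed=13)
        panel = simulate_genotypes(cfg)
        block = panel.variants["block"].to_numpy()
        by_dist = {}
        for j in range(40):
            for k in range(j + 1, 40):
                if block[j] != block[k]:
                    continue
                by_dist.setdefault(k - j, []).append(_pair_r2(panel.dosage, j, k))
        dists = sorted(by_dist)
        means = [np.mean(by_dist[d]) for d in dists]
        # theoretical mean r^2 is c^(2d); empirical means may wiggle slightly
        assert all(means[i] >= means[i + 1] - 0.05 for i in range(len(means) - 1))
        assert means[0] > 0.5 > means[-1]

    @pytest.mark.parametrize(
        "field,value",
        [("n_target", 0), ("maf_range", (0.0, 0.5)), ("ld_copy_prob", 1.0),
         ("h2", 1.5), ("n_causal", 999999), ("base_rate", 0.0)],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = SimConfig(**{field: value})
        with pytest.raises(ConfigurationError, match=field.split("_")[0]):
            simulate_genotypes(cfg)


class TestDiscoverySummary:
    def test_null_p_value_calibration(self):
        cfg = SimConfig(n_discovery=2000, n_variants=500, n_blocks=500,
                        ld_copy_prob=0.0, n_causal=0, seed=17)
        summary = simulate_discovery_summary(cfg, np.zeros(500))
        frac = (summary["P"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_marginal_effect_unbiased_single_causal(self):
        estimates = []
        for seed in range(40):
            cfg = SimConfig(n_discovery=400, n_variants=5, n_blocks=5,
                            ld_copy_prob=0.0, h2=0.2, n_causal=1, seed=100 + seed)
            betas = np.zeros(5)
            betas[2] = 0.4
            summary = simulate_discovery_summary(cfg, betas)
            estimates.append(summary["BETA"].iloc[2])
        mean_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 0.4) < 4 * mean_se

    def test_ld_tagging_of_neighbor(self):
        # adjacent same-frequency variants have dosage correlation c, so the
        # neighbour's expected marginal effect is c * beta_causal
        c = 0.894  # r^2 ~ 0.8
        estimates = []
        for seed in range(30):
            cfg = SimConfig(n_discovery=1000, n_variants=2, n_blocks=1, n_causal=1,
                            maf_range=(0.3, 0.3), ld_copy_prob=c,
                            h2=0.1, seed=200 + seed)
            betas = np.array([0.5, 0.0])
            summary = simulate_discovery_summary(cfg, betas)
            estimates.append(summary["BETA"].iloc[1])
        expected = c * 0.5
        mean_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - expected) < 4 * mean_se

    def test_heritability_recovery(self):
        cfg = SimConfig(n_discovery=5000, n_variants=400, n_blocks=20,
                        h2=0.4, n_causal=40, seed=31)
        betas = draw_true_betas(cfg)
        dosage, y = _simulate_discovery(cfg, betas)
        s = dosage @ betas
        r2 = np.corrcoef(s, y)[0, 1] ** 2
        assert abs(r2 - cfg.h2) < 0.05

    def test_refuses_tiny_discovery(self):
        cfg = SimConfig(n_discovery=10, n_variants=5, n_blocks=5, n_causal=2)
        with pytest.raises(ConfigurationError, match="n_discovery"):
            simulate_discovery_summary(cfg, np.zeros(5))


class TestTargetCohort:
    def test_null_conversion_rate_matches_base_rate(self):
        cfg = SimConfig(n_target=2000, n_variants=100, n_blocks=10,
                        gamma_med=0.0, beta_direct=0.0, beta_med_out=0.0,
                        base_rate=0.15, n_regions=5, seed=41)
        panel = simulate_genotypes(cfg)
        cohort = simulate_target_cohort(cfg, panel, draw_true_betas(cfg))
        rate = cohort["conversion_1yr"].mean()
        se = np.sqrt(0.15 * 0.85 / cfg.n_target)
        assert abs(rate - 0.15) <= 3 * se

    def test_sign_propagates_through_mediation_chain(self):
        # higher score -> smaller mediator -> (negative mediator effect)
        # higher conversion: corr(S, conversion) positive in expectation
        corrs = []
        for seed in range(8):
            cfg = SimConfig(n_target=500, n_variants=100, n_blocks=10,
                            gamma_med=0.8, beta_med_out=-1.0, beta_direct=0.0,
                            n_regions=3, seed=300 + seed)
            panel = simulate_genotypes(cfg)
            cohort = simulate_target_cohort(cfg, panel, draw_true_betas(cfg))
            s = cohort.attrs["true_score"]
            corrs.append(np.corrcoef(s, cohort["conversion_1yr"])[0, 1])
        assert np.mean(corrs) > 0

    def test_region_column_layout(self, small_cfg, small_panel):
        cohort = simulate_target_cohort(small_cfg, small_panel, draw_true_betas(small_cfg))
        for measure in ("surface_area", "thickness", "volume"):
            cols = [c for c in cohort.columns if c.endswith(f"_{measure}")]
            assert len(cols) == 130

    def test_mediator_loads_negatively_on_score(self, small_cfg, small_panel):
        cohort = simulate_target_cohort(small_cfg, small_panel, draw_true_betas(small_cfg))
        med = cohort[f"{cohort.attrs['mediator_region']}_surface_area"]
        r = np.corrcoef(cohort.attrs["true_score"], med)[0, 1]
        assert r < -0.2

    def test_event_time_consistent_with_1yr_outcome(self, small_cfg, small_panel):
        cohort = simulate_target_cohort(small_cfg, small_panel, draw_true_betas(small_cfg))
        assert ((cohort["time_to_event"] <= 1.0) == (cohort["conversion_1yr"] == 1)).all()
        assert (cohort["time_to_event"] <= 10.0).all()


class TestInjectViolations:
    def test_zero_rates_identity(self, small_cfg, small_panel):
        cohort = simulate_target_cohort(small_cfg, small_panel, draw_true_betas(small_cfg))
        panel2, cohort2, truth = inject_qc_violations(small_panel, cohort, small_cfg)
        np.testing.assert_array_equal(small_panel.dosage, panel2.dosage)
        pd.testing.assert_frame_equal(cohort, cohort2)
        assert len(truth) == 0

    def test_missingness_injection_forces_low_call_rate(self, small_cfg, small_panel):
        cfg = SimConfig(**{**small_cfg.__dict__,
                           "qc_violation_rates": QcViolationRates(missingness=0.05)})
        cohort = simulate_target_cohort(cfg, small_panel, draw_true_betas(cfg))
        panel2, _, truth = inject_qc_violations(small_panel, cohort, cfg)
        victims = truth.loc[truth["violation"] == "missingness", "sample_id"]
        assert len(victims) > 0
        call = dict(zip(panel2.samples, panel2.sample_call_rate()))
        assert all(call[s] < 0.97 for s in victims)

    def test_rate_above_half_refused(self, small_cfg):
        with pytest.raises(ConfigurationError, match="sex_flip"):
            QcViolationRates(sex_flip=0.6).validate()
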