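import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from snpower import (
    ADDITIVE,
    DOMINANT,
    ScenarioConfig,
    beta0_from_prevalence,
    code_genotype,
    cohort_to_frame,
    combine_alleles,
    simulate_alleles,
    simulate_binary_outcome,
    simulate_cohort,
    simulate_continuous_outcome,
    subject_effect_sd,
    substream,
)
from snpower.simcohort import Z95


class TestSimulateAlleles:
    def test_sample_mean_matches_maf(self, rng):
        n, maf = 100_000, 0.1
        a, b = simulate_alleles(n, maf, rng)
        tol = 3 * math.sqrt(maf * (1 - maf) / n)
        assert abs(a.mean() - maf) < tol
        assert abs(b.mean() - maf) < tol

    def test_near_zero_maf_limit(self, rng):
        a, b = simulate_alleles(1000, 1e-12, rng)
        assert not a.any() and not b.any()

    def test_deterministic_under_seeding(self):
        a1, b1 = simulate_alleles(500, 0.3, substream(99, 1))
        a2, b2 = simulate_alleles(500, 0.3, substream(99, 1))
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(b1, b2)

    def test_vectors_are_independent_draws(self, rng):
        a, b = simulate_alleles(50_000, 0.5, rng)
        assert not np.array_equal(a, b)

    @pytest.mark.parametrize("maf", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_maf_rejected(self, maf, rng):
        with pytest.raises(ValueError, match="maf"):
            simulate_alleles(100, maf, rng)

    def test_invalid_n_rejected(self, rng):
        with pytest.raises(ValueError, match="n"):
            simulate_alleles(0, 0.1, rng)


class TestCombineAlleles:
    def test_genotype_codes(self):
        a = np.array([0, 0, 1])
        b = np.array([0, 1, 1])
        np.testing.assert_array_equal(combine_alleles(a, b), [0, 1, 2])

    def test_all_zero(self):
        z = np.zeros(10, dtype=int)
        assert not combine_alleles(z, z).any()

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            combine_alleles(np.zeros(3), np.zeros(4))

    def test_non_binary_entries(self):
        with pytest.raises(ValueError, match="0 or 1"):
            combine_alleles(np.array([0, 2]), np.array([0, 0]))

    @pytest.mark.parametrize("p", [0.008, 0.025, 0.1])
    def test_hwe_genotype_frequencies(self, p):
        n = 100_000
        rng = substream(2025, 5)
        counts = combine_alleles(*simulate_alleles(n, p, rng))
        expected = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p * p}
        for geno, freq in expected.items():
            observed = (counts == geno).mean()
            tol = 3 * math.sqrt(freq * (1 - freq) / n)
            assert abs(observed - freq) < tol


class TestCodeGenotype:
    def test_dominant_collapses_carriers(self):
        np.testing.assert_array_equal(
            code_genotype(np.array([0, 1, 2]), DOMINANT), [0, 1, 1])

    def test_additive_is_identity(self):
        np.testing.assert_array_equal(
            code_genotype(np.array([0, 1, 2]), ADDITIVE), [0, 1, 2])

    def test_all_zero_input(self):
        z = np.zeros(5, dtype=int)
        for model in (DOMINANT, ADDITIVE):
            assert not code_genotype(z, model).any()

    def test_unknown_model(self):
        with pytest.raises(ValueError, match="model"):
            code_genotype(np.array([0, 1]), "recessive")

    def test_out_of_range_count(self):
        with pytest.raises(ValueError, match="allele_count"):
            code_genotype(np.array([0, 3]), ADDITIVE)

    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=50))
    def test_dominant_equals_indicator_of_additive(self, counts):
        ac = np.array(counts)
        dom = code_genotype(ac, DOMINANT)
        add = code_genotype(ac, ADDITIVE)
        np.testing.assert_array_equal(dom, (add >= 1).astype(int))


class TestBeta0:
    def test_half_prevalence_is_zero(self):
        assert beta0_from_prevalence(0.5) == 0.0

    def test_ten_percent(self):
        assert beta0_from_prevalence(0.1) == pytest.approx(-2.1972246, abs=1e-6)

    @pytest.mark.parametrize("p", [0.01, 0.2, 0.7])
    def test_round_trip(self, p):
        assert expit(beta0_from_prevalence(p)) == pytest.approx(p, rel=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2])
    def test_boundary_rejected(self, p):
        with pytest.raises(ValueError, match="prevalence"):
            beta0_from_prevalence(p)


class TestSubjectEffectSd:
    def test_no_heterogeneity(self):
        assert subject_effect_sd(1.0) == 0.0

    def test_baseline_or_ten(self):
        assert subject_effect_sd(10.0) == pytest.approx(0.699936, abs=1e-5)

    @pytest.mark.parametrize("b", [2.0, 10.0, 20.0])
    def test_round_trip_95th_vs_5th_odds_ratio(self, b):
        # the 95th-vs-5th percentile contrast of N(0, sd^2) spans 2*Z95*sd
        assert math.exp(2 * Z95 * subject_effect_sd(b)) == pytest.approx(
            b, rel=1e-12)

    def test_below_one_rejected(self):
        with pytest.raises(ValueError, match="baseline_or"):
            subject_effect_sd(0.9)


class TestBinaryOutcome:
    def test_symmetric_null(self, rng):
        g = np.zeros(100_000)
        y = simulate_binary_outcome(g, 0.0, 0.0, 0.0, rng)
        assert set(np.unique(y)) <= {0, 1}
        assert abs(y.mean() - 0.5) < 3 * math.sqrt(0.25 / 100_000)

    def test_case_fraction_matches_prevalence(self, rng):
        n = 100_000
        g = np.zeros(n)
        y = simulate_binary_outcome(g, beta0_from_prevalence(0.1), 0.0, 0.0, rng)
        assert abs(y.mean() - 0.1) < 3 * math.sqrt(0.1 * 0.9 / n)

    def test_carrier_case_fraction(self, rng):
        # expit(-2.19722 + ln 2) = 0.18182
        n = 100_000
        g = np.ones(n)
        y = simulate_binary_outcome(g, -2.1972246, math.log(2), 0.0, rng)
        assert abs(y.mean() - 0.18182) < 3 * math.sqrt(0.18182 * 0.81818 / n)

    def test_negative_subject_sd_rejected(self, rng):
        with pytest.raises(ValueError, match="subject_sd"):
            simulate_binary_outcome(np.zeros(10), 0.0, 0.0, -0.5, rng)


class TestContinuousOutcome:
    def test_noiseless_limit(self, rng):
        y = simulate_continuous_outcome(np.array([0, 1, 2]), 0.0, 1.0, 0.0, rng)
        np.testing.assert_allclose(y, [0.0, 1.0, 2.0])

    def test_trait_sd_recovered(self, rng):
        y = simulate_continuous_outcome(np.zeros(100_000), 0.0, 0.0, 1.0, rng)
        assert abs(y.std() - 1.0) < 0.02

    def test_carrier_group_mean_shift(self):
        cfg = ScenarioConfig(maf=0.2, effect_size=0.7,
                             outcome_type="continuous", n=100_000, seed=3)
        cohort = simulate_cohort(cfg)
        carriers = cohort.g_coded == 1
        shift = cohort.outcome[carriers].mean() - cohort.outcome[~carriers].mean()
        assert shift == pytest.approx(0.7, abs=0.02)

    def test_negative_sd_rejected(self, rng):
        with pytest.raises(ValueError, match="trait_sd"):
            simulate_continuous_outcome(np.zeros(10), 0.0, 0.0, -1.0, rng)


class TestScenarioConfig:
    def test_defaults(self):
        cfg = ScenarioConfig(maf=0.1, effect_size=1.5, outcome_type="binary")
        assert cfg.alpha == 0.05
        assert cfg.target_power == 0.80
        assert cfg.reps == 1000
        assert cfg.prevalence == 0.1
        assert cfg.baseline_or == 10.0

    def test_beta1_log_scale_for_binary(self):
        cfg = ScenarioConfig(maf=0.1, effect_size=2.0, outcome_type="binary")
        assert cfg.beta1 == pytest.approx(math.log(2.0), rel=1e-12)

    def test_null_detection(self):
        assert ScenarioConfig(maf=0.1, effect_size=1.0,
                              outcome_type="binary").is_null
        assert ScenarioConfig(maf=0.1, effect_size=0.0,
                              outcome_type="continuous").is_null

    @pytest.mark.parametrize("field,value", [
        ("maf", 0.0), ("maf", 1.2), ("prevalence", 1.0),
        ("baseline_or", 0.5), ("alpha", 0.0), ("target_power", 1.0),
        ("reps", 0), ("n", 0), ("effect_size", -1.0),
    ])
    def test_validation_names_field(self, field, value):
        kwargs = dict(maf=0.1, effect_size=1.5, outcome_type="binary")
        kwargs[field] = value
        with pytest.raises(ValueError, match=field):
            ScenarioConfig(**kwargs)

    def test_continuous_allows_negative_effect(self):
        ScenarioConfig(maf=0.1, effect_size=-0.5, outcome_type="continuous")

    def test_continuous_requires_positive_trait_sd(self):
        with pytest.raises(ValueError, match="trait_sd"):
            ScenarioConfig(maf=0.1, effect_size=0.5,
                           outcome_type="continuous", trait_sd=0.0)


class TestCohort:
    def test_seed_reproducibility_bitwise(self, binary_config):
        c1 = simulate_cohort(binary_config)
        c2 = simulate_cohort(binary_config)
        np.testing.assert_array_equal(c1.allele_count, c2.allele_count)
        np.testing.assert_array_equal(c1.g_coded, c2.g_coded)
        np.testing.assert_array_equal(c1.outcome, c2.outcome)

    def test_binary_outcome_in_01(self, binary_config):
        cohort = simulate_cohort(binary_config)
        assert set(np.unique(cohort.outcome)) <= {0, 1}
        assert set(np.unique(cohort.allele_count)) <= {0, 1, 2}
        assert set(np.unique(cohort.g_coded)) <= {0, 1}

    def test_tidy_frame(self, continuous_config):
        cohort = simulate_cohort(continuous_config)
        frame = cohort_to_frame(cohort, ADDITIVE)
        assert list(frame.columns) == ["id", "allele_count", "g_true",
                                       "g_analysis", "outcome"]
        assert len(frame) == continuous_config.n
        np.testing.assert_array_equal(frame["g_analysis"],
                                      cohort.allele_count)
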