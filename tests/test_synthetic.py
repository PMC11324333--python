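"""Synthetic cohort generator: determinism, structure, and effect recovery."""

import numpy as np
import pytest
from conftest import fast_config

from sitpose.cop import total_excursion
from sitpose.exceptions import ConfigurationError
from sitpose.questionnaires import normalize_likert
from sitpose.reach import DIRECTIONS, frts
from sitpose.synthetic import (
    CohortConfig,
    SwayParams,
    cohort_from_dir,
    cohort_to_dir,
    generate_cohort,
    generate_cop_series,
    generate_questionnaire,
    generate_reach_trial,
    validate_subject_record,
)


class TestGenerateReachTrial:
    def test_noise_free_peak_equals_amplitude(self):
        t = generate_reach_trial("F", amplitude=0.30, noise_sd=0.0, seed=0)
        dists = np.linalg.norm(t.fingertip.values - t.start_position, axis=1)
        assert dists.max() == pytest.approx(0.30, abs=1e-12)

    def test_same_seed_identical_trajectories(self):
        a = generate_reach_trial("FD", 0.25, noise_sd=0.005, seed=42)
        b = generate_reach_trial("FD", 0.25, noise_sd=0.005, seed=42)
        np.testing.assert_array_equal(a.fingertip.values, b.fingertip.values)
        np.testing.assert_array_equal(a.com.values, b.com.values)

    def test_com_is_scaled_fingertip_displacement(self):
        t = generate_reach_trial("D", 0.2, noise_sd=0.003, seed=7, com_ratio=0.4)
        np.testing.assert_allclose(
            t.com.values, 0.4 * (t.fingertip.values - t.start_position), atol=1e-12
        )

    def test_noisy_peak_bias_matches_monte_carlo_oracle(self):
        # the max over a noisy path exceeds the true amplitude by a bias that
        # a direct Monte-Carlo of max-of-noisy-path reproduces
        amplitude, noise_sd, n_rep = 0.30, 0.005, 400
        peaks = []
        for seed in range(n_rep):
            t = generate_reach_trial("F", amplitude, noise_sd=noise_sd, seed=seed)
            peaks.append(
                np.linalg.norm(t.fingertip.values - t.start_position, axis=1).max()
            )
        # independent oracle: noise-free profile + fresh Gaussian noise
        rng = np.random.default_rng(987654)
        n = 301
        tgrid = np.linspace(0, 1, n)
        tau = np.where(tgrid <= 0.5, 2 * tgrid, 2 * (1 - tgrid))
        profile = amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
        oracle_peaks = []
        for _ in range(2000):
            xy = np.column_stack([np.zeros(n), profile]) + rng.normal(
                0, noise_sd, (n, 2)
            )
            oracle_peaks.append(np.linalg.norm(xy - xy[0], axis=1).max())
        se = np.std(peaks, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(peaks) - np.mean(oracle_peaks)) < 3 * se + 3 * np.std(
            oracle_peaks, ddof=1
        ) / np.sqrt(len(oracle_peaks))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_reach_trial("F", amplitude=0.0)
        with pytest.raises(ConfigurationError):
            generate_reach_trial("F", amplitude=0.3, rate=0.0)
        with pytest.raises(ConfigurationError):
            generate_reach_trial("Q", amplitude=0.3)


class TestGenerateCopSeries:
    def test_degenerate_sway_is_constant(self):
        sway = SwayParams(diffusion=0.0, osc_weight=0.0)
        s = generate_cop_series(5.0, sway, seed=0)
        assert total_excursion(s) == 0.0

    def test_same_seed_identical(self):
        sway = SwayParams()
        a = generate_cop_series(5.0, sway, seed=3)
        b = generate_cop_series(5.0, sway, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_higher_diffusion_longer_excursion(self):
        lo = SwayParams(diffusion=0.01, osc_weight=0.0)
        hi = SwayParams(diffusion=0.05, osc_weight=0.0)
        lo_exc = [total_excursion(generate_cop_series(5.0, lo, seed=s)) for s in range(50)]
        hi_exc = [total_excursion(generate_cop_series(5.0, hi, seed=s + 50)) for s in range(50)]
        from scipy.stats import mannwhitneyu

        assert np.mean(hi_exc) > np.mean(lo_exc)
        assert mannwhitneyu(hi_exc, lo_exc, alternative="greater").pvalue < 1e-6

    def test_negative_diffusion_rejected(self):
        with pytest.raises(ConfigurationError):
            SwayParams(diffusion=-0.1)

    def test_nominal_rate_and_duration(self):
        s = generate_cop_series(10.0, SwayParams(), seed=0)
        assert s.nominal_rate == 56.0
        assert s.duration == pytest.approx(10.0, abs=1.0 / 56.0)


class TestGenerateQuestionnaire:
    def test_degenerate_extremes(self):
        assert generate_questionnaire(1.0, 10, seed=0, response_sd=0.0) == (7,) * 10
        assert generate_questionnaire(0.0, 10, seed=0, response_sd=0.0) == (1,) * 10

    def test_scores_within_scale(self, rng):
        items = generate_questionnaire(0.5, 200, seed=5, response_sd=2.0)
        assert min(items) >= 1 and max(items) <= 7

    def test_mean_score_increases_with_latent(self):
        means = []
        for latent in (0.2, 0.5, 0.8):
            scores = [
                normalize_likert(generate_questionnaire(latent, 12, seed=s))
                for s in range(200)
            ]
            means.append(np.mean(scores))
        assert means[0] < means[1] < means[2]

    def test_invalid_latent_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_questionnaire(1.2, 10)


class TestGenerateCohort:
    def test_counting_and_structure(self):
        config = CohortConfig(n_per_group=2, trial_duration_s=1.0, rate_hz=25.0)
        cohort = generate_cohort(config)
        assert len(cohort) == 6
        for rec in cohort:
            validate_subject_record(rec)
            assert set(rec.pre_trials) == set(DIRECTIONS)
            assert len(rec.training_rounds) == 12
            assert all(len(rnd) == 8 for rnd in rec.training_rounds)
            assert rec.cop_pre is not None and rec.cop_post is not None
            assert len(rec.cop_by_round) == 12
            instruments = {(q.instrument, q.phase) for q in rec.questionnaires}
            assert ("SSQ", "pre") in instruments and ("SSQ", "post") in instruments
            assert ("ITQ", "pre") in instruments
            if rec.group == "PR":
                assert ("PQ", "post") not in instruments
            else:
                assert ("PQ", "post") in instruments

    def test_seeded_determinism_byte_identical_serialization(self, tmp_path):
        config = fast_config(n_per_group=2, seed=11)
        d1 = cohort_to_dir(generate_cohort(config), config, tmp_path / "a")
        d2 = cohort_to_dir(generate_cohort(config), config, tmp_path / "b")
        for name in ("trajectories.csv", "questionnaires.csv", "manifest.yaml"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_round_trip_serialization(self, tmp_path):
        config = CohortConfig(n_per_group=2, trial_duration_s=0.5, rate_hz=20.0,
                              seed=5)
        cohort = generate_cohort(config)
        out = cohort_to_dir(cohort, config, tmp_path / "c")
        loaded, loaded_config = cohort_from_dir(out)
        assert loaded_config == config
        assert len(loaded) == len(cohort)
        by_id = {r.subject_id: r for r in loaded}
        for rec in cohort:
            other = by_id[rec.subject_id]
            assert other.group == rec.group
            for d in DIRECTIONS:
                np.testing.assert_array_equal(
                    other.pre_trials[d].fingertip.values,
                    rec.pre_trials[d].fingertip.values,
                )
            assert other.bout_levels == rec.bout_levels
            assert [q.items for q in sorted(other.questionnaires,
                                            key=lambda q: (q.instrument, q.phase))] == [
                q.items for q in sorted(rec.questionnaires,
                                        key=lambda q: (q.instrument, q.phase))
            ]

    def test_null_gains_leave_pre_post_distributions_identical(self):
        matched = 0
        n_runs = 40
        from scipy.stats import mannwhitneyu

        for seed in range(n_runs):
            config = fast_config(
                n_per_group=7,
                gain_by_group={"PR": 1.0, "AR": 1.0, "VR": 1.0},
                gain_subject_cv=0.0,
                seed=seed,
            )
            cohort = generate_cohort(config)
            pre = [frts(t).distance for r in cohort for t in r.pre_trials.values()]
            post = [frts(t).distance for r in cohort for t in r.post_trials.values()]
            p = mannwhitneyu(pre, post).pvalue
            matched += p > 0.05
        assert matched >= int(0.93 * n_runs) - 2

    def test_group_gain_ratios_recovered(self):
        config = fast_config(n_per_group=21, seed=3)
        cohort = generate_cohort(config)
        for group, expected in (("PR", 1.1), ("AR", 1.3), ("VR", 1.3)):
            ratios = []
            for rec in (r for r in cohort if r.group == group):
                pre = np.mean([frts(t).distance for t in rec.pre_trials.values()])
                post = np.mean([frts(t).distance for t in rec.post_trials.values()])
                ratios.append(post / pre)
            se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
            assert abs(np.mean(ratios) - expected) < 3 * se + 0.01

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_per_group=1)
        with pytest.raises(ConfigurationError):
            CohortConfig(gain_by_group={"PR": 0.0, "AR": 1.0, "VR": 1.0})
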