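"""Generator contracts: determinism, template geometry, trial timing,
planted-energy calibration and the statistical structure the analyses assume."""

import numpy as np
import pytest
from scipy import stats as sps

from tmrdecode import (
    CohortConfig,
    generate_behavior,
    generate_class_templates,
    generate_cohort,
    generate_participant,
    generate_sleep_session,
    generate_wake_session,
)
from tmrdecode.synthetic import make_participant_truth


class TestClassTemplates:
    def test_shapes_and_norms(self):
        tps = generate_class_templates(58, 200, 1.15, seed=1)
        assert len(tps) == 4
        for tp in tps:
            assert tp.waveform.size == round(1.15 * 200) == 230
            assert np.linalg.norm(tp.spatial_weights) == pytest.approx(1.0, abs=1e-9)
            assert np.sqrt(np.mean(tp.waveform**2)) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic(self):
        a = generate_class_templates(58, 200, 1.15, seed=3)
        b = generate_class_templates(58, 200, 1.15, seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x.spatial_weights, y.spatial_weights)
            assert np.array_equal(x.waveform, y.waveform)

    def test_pairwise_non_collinear(self):
        tps = generate_class_templates(58, 200, 1.15, seed=1)
        flat = np.array([tp.pattern.ravel() for tp in tps])
        flat = flat / np.linalg.norm(flat, axis=1, keepdims=True)
        cos = np.abs(flat @ flat.T)
        np.fill_diagonal(cos, 0)
        assert cos.max() < 0.95

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            generate_class_templates(4, 200, 1.15, seed=1)


class TestWakeSession:
    def test_balanced_labels_and_conditions(self, small_config, participant):
        wake = participant.wake
        counts = np.bincount(wake.labels, minlength=5)[1:]
        assert np.all(counts == small_config.n_wake_trials_per_class)
        # both sequences present within every class
        for c in (1, 2, 3, 4):
            conds = wake.condition[wake.labels == c]
            assert set(conds) == {"cued", "uncued"}

    def test_zero_noise_returns_exact_templates(self):
        cfg = CohortConfig()
        truth = make_participant_truth(cfg, 0, seed=5, snr=1.0)
        wake = generate_wake_session(truth, 2, noise_sd=0.0, cfg=cfg)
        for trial, lab in zip(wake.trials, wake.labels):
            assert np.allclose(trial, truth.templates[lab - 1].pattern, atol=1e-12)

    def test_trial_length(self, participant):
        assert all(t.shape == (58, 230) for t in participant.wake.trials)


class TestSleepSession:
    def test_lengths_within_jitter_bounds(self):
        cfg = CohortConfig()
        truth = make_participant_truth(cfg, 0, seed=11, snr=1.0)
        sleep = generate_sleep_session(truth, 200, cfg)
        assert sleep.lengths_s.min() >= 2.5
        assert sleep.lengths_s.max() <= 3.5
        # sample counts match the stored lengths
        for trial, L in zip(sleep.trials, sleep.lengths_s):
            assert trial.shape[1] == round(L * 200)

    def test_compressed_motif_duration(self):
        cfg = CohortConfig(compression_factor=5.0)
        truth = make_participant_truth(cfg, 0, seed=2, snr=1.0)
        assert truth.reactivation.motif_duration_s == pytest.approx(0.23)
        assert round(truth.reactivation.motif_duration_s * cfg.rate) == 46

    def test_embed_probability_zero_plants_nothing(self):
        cfg = CohortConfig(embed_probability=0.0, spindle_coupling=0.0)
        truth = make_participant_truth(cfg, 0, seed=4, snr=1.0)
        sleep = generate_sleep_session(truth, 12, cfg)
        assert not sleep.meta["embedded"].any()
        assert np.isnan(sleep.meta["latency_s"]).all()

    def test_motif_energy_matches_requested_snr(self):
        """Motif RMS over its support is within 5% of snr times the
        background RMS there.

        The background is recovered exactly by regenerating the same session
        at snr=0 (identical random draws; only the added motif differs).
        """
        for snr in (0.5, 1.3):
            cfg = CohortConfig(n_repeats=1, spindle_coupling=0.0)
            truth = make_participant_truth(cfg, 0, seed=9, snr=snr)
            truth0 = make_participant_truth(cfg, 0, seed=9, snr=0.0)
            withm = generate_sleep_session(truth, 8, cfg)
            without = generate_sleep_session(truth0, 8, cfg)
            for i in range(8):
                lat = withm.meta["latency_s"][i]
                if np.isnan(lat):
                    continue
                a, b = round(lat * cfg.rate), round(lat * cfg.rate) + 230
                motif = withm.trials[i][:, a:b] - without.trials[i][:, a:b]
                bg = without.trials[i][:, a:b]
                ratio = np.sqrt(np.mean(motif**2)) / np.sqrt(np.mean(bg**2))
                assert ratio == pytest.approx(snr, rel=0.05)

    def test_burst_trials_have_higher_sigma_power(self):
        """Sigma-burst trials show higher 11-16 Hz Hilbert power at Cz over
        [0, 2.5] s than burst-free trials (rank-sum p < 0.01 at n=200)."""
        from tmrdecode.spindles import sigma_power

        cfg = CohortConfig(embed_probability=0.0, spindle_coupling=0.0,
                           baseline_burst_rate=0.5)
        truth = make_participant_truth(cfg, 0, seed=21, snr=1.0)
        sleep = generate_sleep_session(truth, 200, cfg)
        scores = sigma_power(sleep)
        burst = sleep.meta["sigma_burst"]
        assert 30 < burst.sum() < 170
        stat = sps.ranksums(scores.power[burst], scores.power[~burst],
                            alternative="greater")
        assert stat.pvalue < 0.01

    def test_motif_too_long_rejected(self):
        cfg = CohortConfig(compression_factor=1 / 2.2)
        with pytest.raises(ValueError):
            make_participant_truth(cfg, 0, seed=1, snr=1.0)

    def test_wake_trained_template_matcher_recovers_sleep_labels(self):
        """At c=1 with snr >= 1, matching sleep trials against the wake
        templates (max sliding cross-correlation) beats chance: the
        generator carries class information by construction."""
        cfg = CohortConfig()
        truth = make_participant_truth(cfg, 0, seed=13, snr=1.0)
        sleep = generate_sleep_session(truth, 60, cfg)
        correct = 0
        for trial, lab in zip(sleep.trials, sleep.labels):
            scores = []
            for tp in truth.templates:
                proj = tp.spatial_weights @ trial  # time course along the map
                xc = np.correlate(proj, tp.waveform, mode="valid")
                scores.append(xc.max())
            correct += truth.templates[int(np.argmax(scores))].class_id == lab
        assert correct / 60 > 0.33  # chance is 0.25


class TestBehavior:
    def test_record_count(self, participant):
        # 24 blocks x 4 sessions x 2 sequences
        assert len(participant.behavior) == 24 * 4 * 2

    def test_zero_noise_benefit_equals_slope_times_snr(self):
        from tmrdecode.behavior import cueing_benefit

        cfg = CohortConfig(snr_range=(0.8, 0.8))
        truth = make_participant_truth(cfg, 3, seed=6, snr=0.8)
        table = generate_behavior(truth, sd_ms=0.0)
        benefit = cueing_benefit(table, 3)
        assert benefit == pytest.approx(truth.behavior_slope_ms * 0.8, abs=1e-9)

    def test_zero_slope_means_no_conditional_difference(self):
        cfg = CohortConfig(slope_ms=0.0)
        truth = make_participant_truth(cfg, 0, seed=6, snr=1.0)
        truth.behavior_slope_ms = 0.0
        table = generate_behavior(truth, sd_ms=0.0)
        post = table[table["session"] == "24h"]
        cued = post[post["sequence"] == "cued"]["rt_ms"].mean()
        uncued = post[post["sequence"] == "uncued"]["rt_ms"].mean()
        assert cued == pytest.approx(uncued, abs=1e-9)

    def test_negative_rt_parameters_rejected(self):
        cfg = CohortConfig()
        truth = make_participant_truth(cfg, 0, seed=6, snr=1.0)
        with pytest.raises(ValueError):
            generate_behavior(truth, pre_mean_ms=30.0, sd_ms=20.0)


class TestCohort:
    def test_deterministic(self):
        cfg = CohortConfig(n_sleep_trials=8, n_wake_trials_per_class=2, n_repeats=1)
        a = generate_cohort(cfg, 3, master_seed=7)
        b = generate_cohort(cfg, 3, master_seed=7)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.sleep.trials[0], rb.sleep.trials[0])
            assert np.array_equal(ra.wake.trials[-1], rb.wake.trials[-1])
            assert ra.behavior.equals(rb.behavior)
            assert ra.truth.seed == rb.truth.seed

    def test_snr_within_configured_range(self):
        cfg = CohortConfig(n_sleep_trials=8, n_wake_trials_per_class=2,
                           snr_range=(0.2, 1.5), n_repeats=1)
        cohort = generate_cohort(cfg, 8, master_seed=3)
        snrs = [r.truth.reactivation.snr for r in cohort]
        assert min(snrs) >= 0.2 and max(snrs) <= 1.5

    def test_planted_snr_benefit_association(self):
        """With a positive slope, true benefit increases with snr across the
        cohort (checked on the generated ground truth)."""
        cfg = CohortConfig(n_sleep_trials=8, n_wake_trials_per_class=2,
                           snr_range=(0.2, 1.5), n_repeats=1)
        cohort = generate_cohort(cfg, 15, master_seed=5)
        snrs = np.array([r.truth.reactivation.snr for r in cohort])
        benefit = np.array(
            [r.truth.behavior_slope_ms * r.truth.reactivation.snr for r in cohort]
        )
        rho, _ = sps.spearmanr(snrs, benefit)
        assert rho > 0
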