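"""Generator fidelity: envelope, coordination, determinism, protocol timing."""

import numpy as np
import pytest

from posturadapt import (
    CCCourse,
    Envelope,
    SynthConfig,
    cc_per_cycle,
    detect_onset,
    generate_cohort,
    generate_platform,
    generate_trial,
    per_cycle_metrics,
    segment_cycles,
)


def segmented(rec, frequency):
    onset = detect_onset(rec)
    return segment_cycles(rec, onset, frequency)


class TestPlatform:
    def test_post_onset_duration(self):
        """27 cycles at 0.18 Hz last 27/0.18 = 150 s after onset."""
        cfg = SynthConfig(frequency=0.18, n_cycles=27)
        rec = generate_platform(cfg)
        assert rec.duration == pytest.approx(5.0 + 27 / 0.18, abs=1 / 140)

    def test_platform_pp_is_10cm(self):
        """Every generated cycle measures 10 cm PP up to discretization."""
        cfg = SynthConfig()
        rec = generate_platform(cfg)
        series = per_cycle_metrics(rec, segmented(rec, 0.18), "platform")
        bound = 10.0 * (1 - np.cos(np.pi * 0.18 / 140.0)) + 1e-9
        np.testing.assert_allclose(series.pp, 10.0, atol=max(bound, 1e-4))

    def test_hf_platform_segments_into_31_cycles(self):
        cfg = SynthConfig.hf()
        rec = generate_platform(cfg)
        assert len(segmented(rec, 0.56)) == 31

    def test_onset_is_positive_going_from_midline(self):
        rec = generate_platform(SynthConfig())
        onset = detect_onset(rec)
        assert rec.platform_ap[onset - 1] == 0.0
        assert rec.platform_ap[onset + 5] > 0


class TestEnvelopeFidelity:
    @pytest.mark.parametrize(
        "envelope",
        [Envelope(12.0, 8.0, 3.0), Envelope(5.0, 9.0, 1.5), Envelope(10.0, 10.0, 2.0)],
    )
    def test_noiseless_pp_matches_envelope(self, envelope):
        """With zero noise and lambda=1 the measured per-cycle PP equals G(n)."""
        cfg = SynthConfig(
            head=envelope, noise_sd=0.0, coordination=1.0, n_cycles=20, seed=0
        )
        rec = generate_trial(cfg)
        series = per_cycle_metrics(rec, segmented(rec, cfg.frequency), "head")
        n = np.arange(1, series.n_cycles + 1)
        expected = envelope.value(n)
        bound = 2 * np.max(expected) * (1 - np.cos(np.pi * cfg.frequency / 140.0))
        assert np.max(np.abs(series.pp - expected)) <= bound + 1e-9

    def test_envelope_reaches_asymptote_by_cycle_15(self):
        env = Envelope(12.0, 8.0, 3.0)
        assert abs(env.value(15) - 12.0) / 12.0 < 0.01

    def test_invalid_envelope_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            Envelope(-1.0, 8.0, 2.0)
        with pytest.raises(ValueError, match="positive"):
            Envelope(10.0, 0.0, 2.0)


class TestCoordination:
    def test_lambda_one_gives_unit_cc(self, lf_clean_trial):
        ccs = cc_per_cycle(lf_clean_trial, segmented(lf_clean_trial, 0.18))
        np.testing.assert_allclose(ccs.cc, 1.0, atol=1e-12)

    def test_mean_cc_matches_lambda(self):
        """Shared:independent variance 9:1 -> expected per-cycle CC = 0.9.

        Monte-Carlo oracle from the generative variance decomposition:
        the empirical mean over 100 seeds must sit within +-0.02.
        """
        means = []
        for seed in range(100):
            cfg = SynthConfig.hf(
                noise_sd=0.0, coordination=0.9, n_cycles=8, pre_period=2.0, seed=seed
            )
            rec = generate_trial(cfg)
            ccs = cc_per_cycle(rec, segmented(rec, 0.56))
            means.append(np.mean(ccs.cc))
        assert np.mean(means) == pytest.approx(0.9, abs=0.02)

    def test_cc_course_tracks_lambda_profile(self):
        course = CCCourse(asymptote=0.9, intercept=0.5, tau=3.0)
        cfg = SynthConfig(coordination=course, noise_sd=0.0, seed=3)
        lam = cfg.lambda_per_cycle()
        assert lam[0] == pytest.approx(0.5)
        assert lam[-1] == pytest.approx(0.9, abs=0.01)
        assert np.all(np.diff(lam) >= 0)


class TestDeterminismAndCohort:
    def test_identical_seed_bit_identical(self):
        a = generate_trial(SynthConfig(seed=42))
        b = generate_trial(SynthConfig(seed=42))
        assert np.array_equal(a.head_ap, b.head_ap)
        assert np.array_equal(a.pelvis_ap, b.pelvis_ap)

    def test_different_seed_differs(self):
        a = generate_trial(SynthConfig(seed=1))
        b = generate_trial(SynthConfig(seed=2))
        assert not np.array_equal(a.head_ap, b.head_ap)

    def test_cohort_cardinality(self):
        """2 subjects x 2 conditions x 2 trials -> 8 recordings, keyed truth."""
        configs = {
            "EO@LF": SynthConfig(n_cycles=3, pre_period=1.0),
            "EC@LF": SynthConfig(n_cycles=3, pre_period=1.0),
        }
        recs, truth = generate_cohort(configs, n_subjects=2, n_trials=2, seed=5)
        assert len(recs) == 8
        assert len(truth) == 2 * 2 * 2  # subjects x conditions x segments
        assert set(truth["segment"]) == {"head", "pelvis"}

    def test_cohort_deterministic(self):
        configs = {"EO@LF": SynthConfig(n_cycles=2, pre_period=1.0)}
        r1, t1 = generate_cohort(configs, 2, 1, seed=9)
        r2, t2 = generate_cohort(configs, 2, 1, seed=9)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.head_ap, b.head_ap)
        assert t1.equals(t2)

    def test_zero_jitter_makes_subjects_identical(self):
        configs = {"EO@LF": SynthConfig(n_cycles=2, pre_period=1.0)}
        _, truth = generate_cohort(configs, 3, 1, seed=9, jitter_sd=0.0)
        assert truth.groupby("segment")["true_tau"].nunique().max() == 1


class TestConfigValidation:
    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            SynthConfig(frequency=80.0, sampling_rate=140.0)

    def test_lambda_range_guard(self):
        with pytest.raises(ValueError, match="lambda"):
            SynthConfig(coordination=1.5)

    def test_mean_drift_shifts_positions(self):
        cfg = SynthConfig(mean_drift=2.0, noise_sd=0.0, coordination=1.0, seed=0)
        rec = generate_trial(cfg)
        series = per_cycle_metrics(rec, segmented(rec, 0.18), "head")
        # linear drift of 2 cm across 27 cycles: ~0.077 cm per cycle
        slope = np.polyfit(np.arange(27), series.mean_ap, 1)[0]
        assert slope == pytest.approx(2.0 / 27, rel=0.05)
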