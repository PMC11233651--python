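"""Stimulus/trial synthesis and cohort emulation."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import find_peaks

import ddkscreen as dd
from ddkscreen import config
from ddkscreen.synth import DEFAULT_GROUP_STATS, PARAM_BOUNDS


class TestTrialSynthSpec:
    @pytest.mark.parametrize(
        "kwargs,fragment",
        [
            ({"syllable_duration": 0.0}, "syllable_duration"),
            ({"syllabic_rate": -1.0}, "syllabic_rate"),
            ({"sample_rate": 4000}, "sample_rate"),
            ({"n_syllables": 30}, "phase_duration"),  # 30/4 + 0.5 > 5.5
            ({"onset_delay": -0.1}, "onset_delay"),
            ({"rate_jitter_sd": -0.01}, "rate_jitter_sd"),
        ],
    )
    def test_invariant_violations_name_the_constraint(self, kwargs, fragment):
        spec = dd.TrialSynthSpec(**kwargs)
        with pytest.raises(ValueError, match=fragment):
            dd.synthesize_trial(spec)

    def test_ground_truth_echoes_parameters(self):
        spec = dd.TrialSynthSpec(syllabic_rate=4.0, onset_delay=0.5, rate_jitter_sd=0.0)
        _, truth = dd.synthesize_trial(spec)
        assert truth.onset == 0.5
        assert truth.rate == 4.0

    def test_same_seed_bit_identical(self):
        spec = dd.TrialSynthSpec(seed=42, rate_jitter_sd=0.02)
        w1, _ = dd.synthesize_trial(spec)
        w2, _ = dd.synthesize_trial(spec)
        np.testing.assert_array_equal(w1, w2)

    def test_waveform_length_matches_phase(self, sr):
        wave, _ = dd.synthesize_trial(dd.TrialSynthSpec())
        assert wave.size == int(config.PHASE_DURATION * sr)


class TestTargetAudio:
    def test_duration_and_burst_count(self, sr):
        wave = dd.synthesize_target_audio(voiced=True)
        assert wave.size == int(3.75 * sr)
        env = dd.compute_envelope(wave, sr).samples
        peaks, _ = find_peaks(env, height=0.4 * env.max(), distance=int(0.15 * sr))
        assert peaks.size == 15  # three-syllable pattern repeated five times

    def test_envelope_peak_at_4hz(self, sr):
        wave = dd.synthesize_target_audio(voiced=True)
        spec = dd.envelope_spectrum(dd.compute_envelope(wave, sr))
        assert dd.syllabic_rate(spec) == pytest.approx(4.0, abs=0.2)

    def test_whispered_target_is_whisper(self, sr):
        wave = dd.synthesize_target_audio(voiced=False)
        vd = dd.voiced_duration(wave, sr).voiced_duration
        assert dd.classify_whisper(vd)


class TestMasker:
    def test_noise_has_no_dominant_rhythm(self, sr):
        wave = dd.synthesize_masker("noise", duration=5.5, seed=3)
        assert wave.size == int(5.5 * sr)
        spec = dd.envelope_spectrum(dd.compute_envelope(wave, sr))
        ratio = spec.power.max() / np.median(spec.power)
        rhythmic = dd.envelope_spectrum(
            dd.compute_envelope(dd.synthesize_trial(dd.TrialSynthSpec(seed=3))[0], sr)
        )
        rhythmic_ratio = rhythmic.power.max() / np.median(rhythmic.power)
        assert ratio < rhythmic_ratio / 10

    def test_exogenous_speech_rate_and_count(self, sr):
        wave = dd.synthesize_masker("exogenous_speech", duration=5.5, seed=4)
        env = dd.compute_envelope(wave, sr)
        assert dd.syllabic_rate(dd.envelope_spectrum(env)) == pytest.approx(4.0, abs=0.2)
        peaks, _ = find_peaks(env.samples, height=0.3 * env.samples.max(), distance=int(0.15 * sr))
        assert peaks.size == 22  # 5.5 s / 0.25 s per syllable

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            dd.synthesize_masker("noise", duration=0.0)
        with pytest.raises(ValueError, match="unknown"):
            dd.synthesize_masker("chirp", duration=1.0)


class TestEmulateCohort:
    def test_shape_and_reproducibility(self, cohort_table):
        assert len(cohort_table) == 58
        assert set(cohort_table["group"]) == {"PD", "control"}
        again = dd.emulate_cohort(dd.CohortEffectSpec(seed=0))
        pd.testing.assert_frame_equal(cohort_table, again)

    def test_group_sizes_respected(self):
        t = dd.emulate_cohort(dd.CohortEffectSpec(n_pd=5, n_ctrl=7, seed=1))
        assert (t["group"] == "PD").sum() == 5
        assert (t["group"] == "control").sum() == 7

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError):
            dd.emulate_cohort(dd.CohortEffectSpec(n_pd=0, seed=1))

    def test_zero_sd_gives_identical_rows(self):
        stats = {k: ((m_pd, 0.0), (m_c, 0.0)) for k, ((m_pd, _), (m_c, _)) in DEFAULT_GROUP_STATS.items()}
        t = dd.emulate_cohort(dd.CohortEffectSpec(group_stats=stats, n_pd=4, n_ctrl=4, seed=2))
        pd_rows = t[t["group"] == "PD"]
        for (param, cond), ((m_pd, _), _) in stats.items():
            col = config.feature_column(param, cond)
            assert (pd_rows[col] == m_pd).all()

    def test_truncation_respects_bounds_on_many_draws(self):
        t = dd.emulate_cohort(dd.CohortEffectSpec(n_pd=5000, n_ctrl=5000, seed=3))
        for (param, cond) in DEFAULT_GROUP_STATS:
            lo, hi = PARAM_BOUNDS[param]
            col = config.feature_column(param, cond)
            assert t[col].between(lo, hi).all()

    def test_sample_means_match_configured_means(self):
        """Group sample means stay within 3 SE of the configured means."""
        t = dd.emulate_cohort(dd.CohortEffectSpec(seed=5))
        for (param, cond), stats in DEFAULT_GROUP_STATS.items():
            col = config.feature_column(param, cond)
            for group, (m, s) in zip(("PD", "control"), stats):
                vals = t.loc[t["group"] == group, col]
                se = max(s, 1e-9) / np.sqrt(len(vals))
                assert abs(vals.mean() - m) <= 3 * se + 1e-12

    def test_identical_group_distributions_rarely_significant(self):
        """Null cohorts: any single feature non-significant in >=90% of seeds."""
        null_stats = {k: (v[1], v[1]) for k, v in DEFAULT_GROUP_STATS.items()}
        col = config.feature_column("RT", "RedF")
        hits = 0
        for s in range(40):
            t = dd.emulate_cohort(dd.CohortEffectSpec(group_stats=null_stats, seed=600 + s))
            a = t.loc[t["group"] == "PD", col]
            b = t.loc[t["group"] == "control", col]
            _, p = dd.mann_whitney_u(a, b)
            hits += p < 0.05
        assert hits <= 4  # >=90% non-significant


class TestCohortAudio:
    def test_manifest_and_waveforms(self):
        manifest, waves = dd.synth.synthesize_cohort_audio(
            n_pd=2, n_ctrl=2, n_trials=2, conditions=("NF", "RedF"), seed=9
        )
        assert len(manifest) == 4 * 2 * 2
        assert set(manifest["condition"]) == {"NF", "RedF"}
        assert len(waves) == len(manifest)
        # NF trials are always voiced (speaking aloud)
        assert manifest.loc[manifest["condition"] == "NF", "true_voiced"].all()

    def test_deterministic_under_seed(self):
        m1, w1 = dd.synth.synthesize_cohort_audio(n_pd=1, n_ctrl=1, n_trials=1, seed=5)
        m2, w2 = dd.synth.synthesize_cohort_audio(n_pd=1, n_ctrl=1, n_trials=1, seed=5)
        pd.testing.assert_frame_equal(m1, m2)
        for k in w1:
            np.testing.assert_array_equal(w1[k], w2[k])
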