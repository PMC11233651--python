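"""Silence-based segmentation, onset detection, voicing and the whisper rule."""

import numpy as np
import pytest

import ddkscreen as dd
from ddkscreen.segmentation import SpeechIntervals

SR = 16000


def _oracle_intervals(rms_db, threshold, min_silent_frames, min_sounding_frames, frame):
    """Naive reference: threshold each frame, absorb short quiet gaps, drop blips."""
    sounding = [d > threshold for d in rms_db]
    n = len(sounding)

    def runs(mask, value):
        out, i = [], 0
        while i < n:
            if mask[i] == value:
                j = i
                while j < n and mask[j] == value:
                    j += 1
                out.append((i, j))
                i = j
            else:
                i += 1
        return out

    for s, e in runs(sounding, False):
        if e - s < min_silent_frames:
            for k in range(s, e):
                sounding[k] = True
    for s, e in runs(sounding, True):
        if e - s < min_sounding_frames:
            for k in range(s, e):
                sounding[k] = False
    return [(s * frame, e * frame) for s, e in runs(sounding, True)]


class TestDetectSpeechIntervals:
    def test_single_block_recovered(self, voiced_trial):
        wave, truth, spec = voiced_trial
        res = dd.detect_speech_intervals(wave, SR)
        assert len(res.intervals) == 1
        start, end = res.intervals[0]
        assert start == pytest.approx(truth.onset, abs=0.025)
        expected_end = truth.onset + (spec.n_syllables - 1) / spec.syllabic_rate + 0.2
        assert end == pytest.approx(expected_end, abs=0.06)

    def test_all_zeros_yields_empty(self):
        assert dd.detect_speech_intervals(np.zeros(SR), SR).intervals == []

    def test_speech_from_time_zero(self):
        wave, _ = dd.synthesize_trial(
            dd.TrialSynthSpec(onset_delay=0.0, n_syllables=20, seed=2)
        )
        res = dd.detect_speech_intervals(wave, SR)
        assert res.intervals[0][0] == 0.0

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            dd.detect_speech_intervals(np.zeros(100), SR)

    def test_matches_bruteforce_oracle_on_toys(self):
        rng = np.random.default_rng(5)
        frame = 0.01
        for _ in range(20):
            # piecewise-constant amplitude toy: 50 frames of 10 ms at 16 kHz
            n_frames = 50
            amps = rng.choice([0.0, 0.001, 0.5, 1.0], size=n_frames)
            wave = np.repeat(amps, int(frame * SR)) * np.sign(
                np.sin(2 * np.pi * 1000 * np.arange(n_frames * int(frame * SR)) / SR)
            )
            res = dd.detect_speech_intervals(wave, SR, frame=frame)
            rms = np.sqrt(np.mean(wave[: n_frames * 160].reshape(n_frames, 160) ** 2, axis=1))
            peak = rms.max()
            if peak == 0:
                assert res.intervals == []
                continue
            db = 20 * np.log10(np.where(rms > 0, rms / peak, 1e-30))
            expected = _oracle_intervals(db, -25.0, 10, 5, frame)
            got = [(round(s, 6), round(e, 6)) for s, e in res.intervals]
            expected = [(round(s, 6), round(e, 6)) for s, e in expected]
            assert got == expected


class TestSpeechOnset:
    def test_first_interval_start(self):
        si = SpeechIntervals(intervals=[(0.5, 5.0), (5.2, 5.4)])
        assert dd.speech_onset(si) == 0.5

    def test_no_speech_returns_none(self):
        assert dd.speech_onset(SpeechIntervals(intervals=[])) is None

    @pytest.mark.parametrize("true_onset", [0.2, 0.6, 1.0])
    def test_synthetic_onsets_recovered(self, true_onset):
        wave, truth = dd.synthesize_trial(
            dd.TrialSynthSpec(onset_delay=true_onset, n_syllables=16, seed=7)
        )
        got = dd.speech_onset(dd.detect_speech_intervals(wave, SR))
        assert got == pytest.approx(truth.onset, abs=0.025)

    @pytest.mark.parametrize("pad", [0.2, 0.5, 1.0])
    def test_onset_shifts_with_prepended_silence(self, pad):
        wave, truth = dd.synthesize_trial(
            dd.TrialSynthSpec(onset_delay=0.3, n_syllables=10, seed=8)
        )
        padded = np.concatenate([np.zeros(int(pad * SR)), wave])
        o1 = dd.speech_onset(dd.detect_speech_intervals(wave, SR))
        o2 = dd.speech_onset(dd.detect_speech_intervals(padded, SR))
        assert o2 - o1 == pytest.approx(pad, abs=0.015)


class TestVoicedDuration:
    def test_voiced_trial_duration_near_truth(self, voiced_trial):
        wave, truth, _ = voiced_trial
        vd = dd.voiced_duration(wave, SR).voiced_duration
        assert 0.7 * truth.voiced_duration <= vd <= 1.2 * truth.voiced_duration

    def test_whispered_trial_nearly_unvoiced(self, whispered_trial):
        wave, _, _ = whispered_trial
        assert dd.voiced_duration(wave, SR).voiced_duration < 0.2

    def test_whispered_at_20db_snr(self):
        wave, _ = dd.synthesize_trial(
            dd.TrialSynthSpec(voiced=False, snr_db=20.0, n_syllables=18, seed=14)
        )
        assert dd.voiced_duration(wave, SR).voiced_duration < 0.2

    def test_silence_is_zero(self):
        assert dd.voiced_duration(np.zeros(SR), SR).voiced_duration == 0.0

    def test_decision_invariant_to_gain(self, voiced_trial, whispered_trial):
        for wave, _, _ in (voiced_trial, whispered_trial):
            base = dd.voiced_duration(wave, SR).voiced_duration
            for c in (0.01, 10.0):
                scaled = dd.voiced_duration(c * wave, SR).voiced_duration
                assert dd.classify_whisper(scaled) == dd.classify_whisper(base)


class TestClassifyWhisper:
    def test_default_threshold_is_tenth_of_phase(self):
        assert dd.config.WHISPER_THRESHOLD == pytest.approx(0.55)
        assert dd.config.WHISPER_THRESHOLD == pytest.approx(
            0.10 * dd.config.PHASE_DURATION
        )

    def test_boundary_is_strict_less_than(self):
        assert dd.classify_whisper(0.55, threshold=0.55) is False
        assert dd.classify_whisper(0.5499, threshold=0.55) is True

    def test_extremes(self):
        assert dd.classify_whisper(0.0) is True
        assert dd.classify_whisper(5.0) is False

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dd.classify_whisper(-0.1)
        with pytest.raises(ValueError):
            dd.classify_whisper(0.2, threshold=0.0)
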