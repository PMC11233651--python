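"""Silence-based speech segmentation, onset detection, and the whisper rule.

Speech/silence labelling follows the convention of Praat's silence
annotator: frames whose intensity falls below a threshold relative to the
trial maximum (default -25 dB) for at least a minimum silent duration are
silence, and sounding runs shorter than a minimum duration are discarded.
The speech onset of a trial is the start of its first speech interval.

Voicing (vocal-fold activation) is detected per frame from the normalized
autocorrelation peak within the f0 search range; a trial whose total voiced
duration is below 10% of the repetition phase (0.55 s for the 5.5-s phase,
strict less-than) is classified as whispered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfft

from . import config


@dataclass(frozen=True)
class SpeechIntervals:
    """Detected speech segments (start, end) in seconds, sorted and disjoint."""

    intervals: list[tuple[float, float]]
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class VoicingResult:
    """Total voiced duration plus the frame-level decisions behind it."""

    voiced_duration: float
    frame_times: np.ndarray
    is_voiced: np.ndarray
    params: dict = field(default_factory=dict)


def _frame_rms(waveform: np.ndarray, sample_rate: float, frame: float) -> np.ndarray:
    n = int(round(frame * sample_rate))
    n_frames = waveform.size // n
    if n_frames == 0:
        return np.array([])
    x = waveform[: n_frames * n].reshape(n_frames, n)
    return np.sqrt(np.mean(x**2, axis=1))


def detect_speech_intervals(
    waveform: np.ndarray,
    sample_rate: float,
    silence_threshold_db: float = config.SILENCE_THRESHOLD_DB,
    min_silent: float = config.MIN_SILENT_DURATION,
    min_sounding: float = config.MIN_SOUNDING_DURATION,
    frame: float = config.INTENSITY_FRAME,
) -> SpeechIntervals:
    """Threshold-and-merge silence detection on frame intensities.

    Frames more than ``silence_threshold_db`` below the trial's maximum frame
    intensity are candidate silence; quiet gaps shorter than ``min_silent``
    are absorbed into speech, then sounding runs shorter than ``min_sounding``
    are dropped. An all-silent trial yields an empty interval list.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size < int(0.2 * sample_rate):
        raise ValueError("waveform shorter than 0.2 s")
    params = {
        "silence_threshold_db": silence_threshold_db,
        "min_silent": min_silent,
        "min_sounding": min_sounding,
        "frame": frame,
    }
    rms = _frame_rms(waveform, sample_rate, frame)
    peak = np.max(rms)
    if peak <= 0:
        return SpeechIntervals(intervals=[], params=params)
    with np.errstate(divide="ignore"):
        db = 20 * np.log10(np.where(rms > 0, rms / peak, 1e-30))
    sounding = db > silence_threshold_db

    min_silent_frames = max(1, int(round(min_silent / frame)))
    min_sounding_frames = max(1, int(round(min_sounding / frame)))

    # short quiet gaps inside speech are kept as speech
    sounding = _absorb_short_runs(sounding, value=False, max_len=min_silent_frames - 1)
    # then short sounding blips are discarded
    sounding = _absorb_short_runs(sounding, value=True, max_len=min_sounding_frames - 1)

    intervals = []
    for start, end in _runs(sounding, True):
        intervals.append((start * frame, end * frame))
    return SpeechIntervals(intervals=intervals, params=params)


def _runs(mask: np.ndarray, value: bool) -> list[tuple[int, int]]:
    """Half-open index runs [start, end) where mask == value."""
    out = []
    n = mask.size
    i = 0
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


def _absorb_short_runs(mask: np.ndarray, value: bool, max_len: int) -> np.ndarray:
    if max_len < 1:
        return mask
    out = mask.copy()
    for start, end in _runs(mask, value):
        if end - start <= max_len:
            out[start:end] = not value
    return out


def speech_onset(intervals: SpeechIntervals) -> float | None:
    """Start of the first detected speech interval; ``None`` if no speech."""
    if not intervals.intervals:
        return None
    return intervals.intervals[0][0]


def voiced_duration(
    waveform: np.ndarray,
    sample_rate: float,
    frame: float = config.VOICING_FRAME,
    hop: float = config.VOICING_HOP,
    f0_range: tuple[float, float] = config.F0_SEARCH_RANGE,
    harmonicity_threshold: float = config.HARMONICITY_THRESHOLD,
    energy_floor_db: float = config.SILENCE_THRESHOLD_DB,
) -> VoicingResult:
    """Total duration of voiced (periodic) speech via short-time autocorrelation.

    A frame is voiced when its normalized autocorrelation attains at least
    ``harmonicity_threshold`` at some lag inside the f0 search range (default
    75-400 Hz) and its level is above ``energy_floor_db`` re the loudest
    frame — quiet background frames are never voiced. The decision depends on
    periodicity, not amplitude, so it is invariant to global gain.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size < int(0.2 * sample_rate):
        raise ValueError("waveform shorter than 0.2 s")
    n_frame = int(round(frame * sample_rate))
    n_hop = int(round(hop * sample_rate))
    lag_min = max(1, int(np.floor(sample_rate / f0_range[1])))
    lag_max = min(n_frame - 1, int(np.ceil(sample_rate / f0_range[0])))

    starts = np.arange(0, waveform.size - n_frame + 1, n_hop)
    rms = np.array(
        [np.sqrt(np.mean(waveform[s : s + n_frame] ** 2)) for s in starts]
    )
    peak = np.max(rms) if rms.size else 0.0
    floor = peak * 10 ** (energy_floor_db / 20)

    is_voiced = np.zeros(starts.size, dtype=bool)
    for i, s in enumerate(starts):
        if rms[i] <= floor or rms[i] == 0:
            continue
        x = waveform[s : s + n_frame]
        x = x - x.mean()
        energy = np.dot(x, x)
        if energy <= 0:
            continue
        # FFT-based raw autocorrelation, normalized per-lag so that a
        # perfectly periodic frame scores ~1 regardless of lag
        ac = irfft(np.abs(rfft(x, 2 * n_frame)) ** 2, 2 * n_frame)[: n_frame]
        csum = np.concatenate(([0.0], np.cumsum(x**2)))
        lags = np.arange(lag_min, lag_max + 1)
        head = csum[n_frame - lags]            # sum x[:N-lag]**2
        tail = csum[n_frame] - csum[lags]      # sum x[lag:]**2
        denom = np.sqrt(head * tail)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm_ac = np.where(denom > 0, ac[lag_min : lag_max + 1] / denom, 0.0)
        if np.max(norm_ac) >= harmonicity_threshold:
            is_voiced[i] = True

    dur = float(hop * np.count_nonzero(is_voiced))
    return VoicingResult(
        voiced_duration=dur,
        frame_times=starts / sample_rate,
        is_voiced=is_voiced,
        params={
            "frame": frame,
            "hop": hop,
            "f0_range": f0_range,
            "harmonicity_threshold": harmonicity_threshold,
            "energy_floor_db": energy_floor_db,
        },
    )


def classify_whisper(
    voiced_dur: float, threshold: float = config.WHISPER_THRESHOLD
) -> bool:
    """Whisper rule: voiced speech strictly less than the threshold duration.

    The default threshold is 10% of the 5.5-s repetition phase (0.55 s). A
    trial with exactly the threshold of voiced speech is NOT whispered.
    """
    if voiced_dur < 0:
        raise ValueError("voiced duration must be >= 0")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return voiced_dur < threshold
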