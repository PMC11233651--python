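"""Per-trial measurement and participant-level feature aggregation.

One trial yields: a whisper flag (from the voiced-duration rule), the speech
onset, the envelope spectrum and its peak frequency (fMAX), and an
annotation-derived speech-error count. Seven trials of one condition are
aggregated into the five condition-level parameters:

* ``pct_whispered`` — percentage of whispered trials,
* ``errors_per_sec`` — total annotated errors per second of attempted speech,
* ``mean_rt`` — mean speech onset (reaction time) across trials,
* ``mean_rate`` — mean syllabic rate across trials,
* ``rhythm_consistency`` — mean pairwise correlation of trial envelope spectra.

Error counting itself is annotation-driven (syllable repetitions, exchanges
and misarticulations are identified by a human listener); this module only
normalizes the counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import config
from .signal_features import (
    EnvelopeSpectrum,
    NoRhythmicPeakError,
    compute_envelope,
    envelope_spectrum,
    syllabic_rate,
    rhythm_consistency,
    DegenerateSpectrumError,
)
from .segmentation import (
    detect_speech_intervals,
    speech_onset,
    voiced_duration,
    classify_whisper,
)


@dataclass(frozen=True)
class TrialMeasurements:
    whis: bool
    voiced_duration: float
    onset: float | None
    spectrum: EnvelopeSpectrum | None
    f_max: float | None
    error_count: int = 0


@dataclass(frozen=True)
class ConditionFeatures:
    pct_whispered: float
    errors_per_sec: float | None
    mean_rt: float | None
    mean_rate: float | None
    rhythm_consistency: float | None
    n_trials: int
    n_trials_with_speech: int


def measure_trial(
    waveform: np.ndarray,
    sample_rate: float,
    error_count: int = 0,
    whisper_threshold: float = config.WHISPER_THRESHOLD,
    band: tuple[float, float] = config.ANALYSIS_BAND,
) -> TrialMeasurements:
    """Run segmentation and envelope analysis on one repetition-phase trial.

    A trial with no detected speech gets ``onset=None`` and ``f_max=None``
    (and, having no voiced frames, counts as whispered); envelope spectra are
    only retained for trials with a detectable rhythmic peak.
    """
    intervals = detect_speech_intervals(waveform, sample_rate)
    onset = speech_onset(intervals)
    voicing = voiced_duration(waveform, sample_rate)
    whis = classify_whisper(voicing.voiced_duration, whisper_threshold)

    spectrum: EnvelopeSpectrum | None = None
    f_max: float | None = None
    if onset is not None:
        env = compute_envelope(waveform, sample_rate)
        spec = envelope_spectrum(env, band=band)
        try:
            f_max = syllabic_rate(spec)
            spectrum = spec
        except NoRhythmicPeakError:
            pass
    return TrialMeasurements(
        whis=whis,
        voiced_duration=voicing.voiced_duration,
        onset=onset,
        spectrum=spectrum,
        f_max=f_max,
        error_count=int(error_count),
    )


def condition_features(
    measurements: Sequence[TrialMeasurements],
    phase_duration: float = config.PHASE_DURATION,
) -> ConditionFeatures:
    """Aggregate one participant's trials of a single condition.

    Reaction time, rate and consistency are computed over trials with
    detected speech; the error rate is normalized by the total attempted
    speech time (trials with speech x phase duration) so silent trials do
    not dilute it. When no trial contains detectable speech the rhythm and
    timing features are missing but ``pct_whispered`` is still defined.
    """
    if not measurements:
        raise ValueError("need at least one trial measurement")
    n = len(measurements)
    n_whis = sum(m.whis for m in measurements)
    with_speech = [m for m in measurements if m.onset is not None]

    pct = 100.0 * n_whis / n
    if with_speech:
        errors = sum(m.error_count for m in with_speech)
        errors_per_sec = errors / (len(with_speech) * phase_duration)
        mean_rt = float(np.mean([m.onset for m in with_speech]))
    else:
        errors_per_sec = None
        mean_rt = None

    rates = [m.f_max for m in measurements if m.f_max is not None]
    mean_rate = float(np.mean(rates)) if rates else None

    spectra = [m.spectrum for m in measurements if m.spectrum is not None]
    consistency: float | None = None
    if len(spectra) >= 2:
        try:
            consistency = rhythm_consistency(spectra)
        except DegenerateSpectrumError:
            consistency = None

    return ConditionFeatures(
        pct_whispered=pct,
        errors_per_sec=errors_per_sec,
        mean_rt=mean_rt,
        mean_rate=mean_rate,
        rhythm_consistency=consistency,
        n_trials=n,
        n_trials_with_speech=len(with_speech),
    )


_FEATURE_OF_PARAM = {
    "whis": "pct_whispered",
    "SpErr": "errors_per_sec",
    "RT": "mean_rt",
    "rate": "mean_rate",
    "RhyStrCons": "rhythm_consistency",
}


def build_cohort_table(
    manifest: pd.DataFrame,
    measurements: Mapping[tuple[str, str, int], TrialMeasurements],
    phase_duration: float = config.PHASE_DURATION,
) -> pd.DataFrame:
    """Assemble the participants x features table from per-trial measurements.

    ``manifest`` needs columns ``participant_id``, ``group``, ``condition``,
    ``trial_index`` and optionally ``age``; ``measurements`` is keyed by
    ``(participant_id, condition, trial_index)``. Conditions with no trials
    for a participant leave their feature block missing (NaN). Duplicate
    trial keys are rejected.
    """
    required = {"participant_id", "group", "condition", "trial_index"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    keys = list(zip(manifest["participant_id"], manifest["condition"], manifest["trial_index"]))
    dupes = pd.Series(keys).duplicated()
    if dupes.any():
        raise ValueError(f"duplicate trial key: {keys[int(np.flatnonzero(dupes)[0])]}")

    rows = []
    for pid, part in manifest.groupby("participant_id", sort=False):
        row: dict = {"participant_id": pid, "group": part["group"].iloc[0]}
        if "age" in part.columns:
            row["age"] = part["age"].iloc[0]
        for cond in config.CONDITIONS:
            trials = part[part["condition"] == cond]
            if trials.empty:
                continue
            ms = [
                measurements[(pid, cond, int(ti))]
                for ti in trials["trial_index"]
                if (pid, cond, int(ti)) in measurements
            ]
            if not ms:
                continue
            feats = condition_features(ms, phase_duration=phase_duration)
            for param, attr in _FEATURE_OF_PARAM.items():
                val = getattr(feats, attr)
                row[config.feature_column(param, cond)] = np.nan if val is None else val
        rows.append(row)
    return pd.DataFrame(rows)
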