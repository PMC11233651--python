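"""Synthesis of syllable-train stimuli, ground-truth trials, and emulated cohorts.

Three levels of synthetic data are produced:

* target-style stimuli and maskers matching the paradigm (15 syllables at
  4/s for the 3.75-s target; white noise or an exogenous rhythmic voice for
  the 5.5-s repetition phase),
* single-trial waveforms with known ground truth (onset, rate, voicing) for
  validating segmentation and envelope analysis, and
* participant-level cohort feature tables drawn from configurable group
  means/SDs, whose defaults reproduce the summary statistics of the pilot
  PD/control cohort this paradigm was developed on (28 PD, 30 controls).

Voiced syllables use a harmonic complex at f0 (default 200 Hz, the pitch of
the synthesized voice used in the paradigm); whispered syllables use
band-limited noise. Both are amplitude-modulated by one Hann burst per
syllable: the downstream metrics operate on the envelope, which a single
burst per syllable preserves, so no formant structure is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import least_squares
from scipy.stats import truncnorm

from . import config


@dataclass(frozen=True)
class GroundTruth:
    """Known generation parameters of a synthesized trial."""

    onset: float            # s; start of the first syllable burst
    rate: float             # Hz; nominal syllabic rate
    voiced_duration: float  # s; total duration of voiced (periodic) signal


@dataclass(frozen=True)
class TrialSynthSpec:
    """Generation parameters for one synthetic repetition-phase trial.

    ``rate_jitter_sd`` perturbs each syllable onset independently (seconds);
    ``snr_db`` sets the level of additive white background noise relative to
    the RMS of the syllable bursts (``None`` disables noise).
    """

    syllabic_rate: float = config.TARGET_SYLLABIC_RATE
    n_syllables: int = 20
    syllable_duration: float = config.SYLLABLE_DURATION
    onset_delay: float = 0.5
    rate_jitter_sd: float = 0.0
    voiced: bool = True
    f0: float = config.DEFAULT_F0
    snr_db: float | None = 30.0
    phase_duration: float = config.PHASE_DURATION
    sample_rate: int = config.DEFAULT_SAMPLE_RATE
    seed: int = 0

    def validate(self) -> None:
        if self.syllable_duration <= 0:
            raise ValueError("syllable_duration must be > 0")
        if self.syllabic_rate <= 0:
            raise ValueError("syllabic_rate must be > 0")
        if self.n_syllables < 1:
            raise ValueError("n_syllables must be >= 1")
        if self.onset_delay < 0:
            raise ValueError("onset_delay must be >= 0")
        if self.rate_jitter_sd < 0:
            raise ValueError("rate_jitter_sd must be >= 0")
        if self.sample_rate < 8000:
            raise ValueError("sample_rate must be >= 8000 Hz")
        span = self.n_syllables / self.syllabic_rate + self.onset_delay
        if span > self.phase_duration + 1e-9:
            raise ValueError(
                "n_syllables/syllabic_rate + onset_delay "
                f"({span:.3f} s) exceeds phase_duration ({self.phase_duration} s)"
            )


def _harmonic_complex(n: int, sample_rate: int, f0: float, n_harmonics: int = 5) -> np.ndarray:
    """Periodic glottal-like source: harmonics of f0 with 1/k amplitudes."""
    t = np.arange(n) / sample_rate
    nyquist = sample_rate / 2
    out = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        if k * f0 >= nyquist:
            break
        out += np.sin(2 * np.pi * k * f0 * t) / k
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def _whisper_source(n: int, sample_rate: int, rng: np.random.Generator) -> np.ndarray:
    """Aperiodic source: white noise band-limited to 500-4000 Hz."""
    noise = rng.standard_normal(n)
    high = min(4000.0, 0.45 * sample_rate)
    sos = signal.butter(4, [500.0, high], btype="bandpass", fs=sample_rate, output="sos")
    out = signal.sosfilt(sos, noise)
    rms = np.sqrt(np.mean(out**2))
    return out / rms


def _burst_train(
    spec: TrialSynthSpec,
    rng: np.random.Generator,
    amplitudes: np.ndarray | None = None,
    burst_fraction: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum of per-syllable Hann bursts; returns (waveform, realized onsets)."""
    sr = spec.sample_rate
    n_total = int(round(spec.phase_duration * sr))
    wave = np.zeros(n_total)
    burst_len = int(round(burst_fraction * spec.syllable_duration * sr))
    window = signal.windows.hann(burst_len)
    if amplitudes is None:
        amplitudes = np.ones(spec.n_syllables)

    period = 1.0 / spec.syllabic_rate
    nominal = spec.onset_delay + period * np.arange(spec.n_syllables)
    jitter = (
        rng.normal(0.0, spec.rate_jitter_sd, spec.n_syllables)
        if spec.rate_jitter_sd > 0
        else np.zeros(spec.n_syllables)
    )
    onsets = np.clip(nominal + jitter, 0.0, spec.phase_duration - burst_len / sr)

    for t0, amp in zip(onsets, amplitudes):
        i0 = int(round(t0 * sr))
        i1 = min(i0 + burst_len, n_total)
        seg = i1 - i0
        if spec.voiced:
            carrier = _harmonic_complex(seg, sr, spec.f0)
        else:
            carrier = _whisper_source(seg, sr, rng)
        wave[i0:i1] += amp * window[:seg] * carrier
    return wave, onsets


def _add_noise(wave: np.ndarray, snr_db: float | None, rng: np.random.Generator) -> np.ndarray:
    if snr_db is None or not np.isfinite(snr_db):
        return wave
    active = np.abs(wave) > 1e-6 * max(np.max(np.abs(wave)), 1e-30)
    signal_rms = np.sqrt(np.mean(wave[active] ** 2)) if active.any() else 0.0
    noise_rms = signal_rms * 10 ** (-snr_db / 20)
    return wave + rng.normal(0.0, noise_rms if noise_rms > 0 else 1e-6, wave.size)


def synthesize_trial(spec: TrialSynthSpec) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize one repetition-phase trial with known ground truth.

    Returns the waveform (length ``phase_duration * sample_rate`` samples)
    and a :class:`GroundTruth` carrying the realized onset, the nominal
    syllabic rate, and the total voiced duration (0 for whispered trials).
    Identical specs (including seed) give bit-identical waveforms.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    wave, onsets = _burst_train(spec, rng)
    wave = _add_noise(wave, spec.snr_db, rng)
    burst_dur = 0.8 * spec.syllable_duration
    voiced_dur = spec.n_syllables * burst_dur if spec.voiced else 0.0
    truth = GroundTruth(onset=float(onsets[0]), rate=spec.syllabic_rate, voiced_duration=voiced_dur)
    return wave, truth


def synthesize_target_audio(
    voiced: bool = True,
    sample_rate: int = config.DEFAULT_SAMPLE_RATE,
    seed: int = 0,
) -> np.ndarray:
    """Synthesize the 3.75-s target stimulus: 15 syllables at 4 syllables/s.

    The three-syllable PA-TA-KA pattern repeated five times is rendered as
    a cyclic triplet of burst amplitudes so consecutive syllables differ
    slightly, as in natural productions; the envelope rhythm stays at 4 Hz.
    """
    spec = TrialSynthSpec(
        syllabic_rate=config.TARGET_SYLLABIC_RATE,
        n_syllables=config.N_TARGET_SYLLABLES,
        onset_delay=0.0,
        voiced=voiced,
        snr_db=None,
        phase_duration=config.TARGET_DURATION,
        sample_rate=sample_rate,
        seed=seed,
    )
    spec.validate()
    rng = np.random.default_rng(seed)
    amplitudes = np.tile([1.0, 0.92, 0.85], 5)[: spec.n_syllables]
    wave, _ = _burst_train(spec, rng, amplitudes=amplitudes)
    return wave


def synthesize_masker(
    kind: Literal["noise", "exogenous_speech"],
    duration: float = config.PHASE_DURATION,
    seed: int = 0,
    sample_rate: int = config.DEFAULT_SAMPLE_RATE,
) -> np.ndarray:
    """Synthesize a repetition-phase masker.

    ``noise`` is flat-spectrum white noise; ``exogenous_speech`` is a train
    of randomly-varied voiced syllables at 4 syllables/s (0.25 s each),
    emulating an external voice producing a steady rhythm.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    if kind == "noise":
        return rng.standard_normal(n)
    if kind == "exogenous_speech":
        n_syl = int(np.floor(duration / config.SYLLABLE_DURATION))
        spec = TrialSynthSpec(
            syllabic_rate=1.0 / config.SYLLABLE_DURATION,
            n_syllables=n_syl,
            onset_delay=0.0,
            voiced=True,
            snr_db=None,
            phase_duration=duration,
            sample_rate=sample_rate,
            seed=seed,
        )
        amplitudes = rng.uniform(0.7, 1.0, n_syl)
        wave, _ = _burst_train(spec, rng, amplitudes=amplitudes)
        return wave
    raise ValueError(f"unknown masker kind: {kind!r}")


# --- cohort emulation ---------------------------------------------------------

# (parameter, condition) -> ((mean_pd, sd_pd), (mean_ctrl, sd_ctrl)).
# Defaults are the group-level summary statistics of the pilot cohort:
# whispered-trial percentages, errors/s, reaction times (s), syllabic rates
# (Hz), and rhythmic-structure consistency, per feedback condition.
DEFAULT_GROUP_STATS: dict[tuple[str, str], tuple[tuple[float, float], tuple[float, float]]] = {
    ("whis", "RedF"): ((66.0, 38.0), (79.0, 37.0)),
    ("whis", "MF"): ((43.0, 33.0), (72.0, 38.0)),
    ("whis", "RepF"): ((36.0, 38.0), (70.0, 41.0)),
    ("SpErr", "NF"): ((0.039, 0.069), (0.044, 0.126)),
    ("SpErr", "RedF"): ((0.082, 0.092), (0.022, 0.076)),
    ("RT", "NF"): ((0.59, 0.20), (0.49, 0.15)),
    ("RT", "RedF"): ((0.50, 0.18), (0.39, 0.14)),
    ("rate", "NF"): ((3.74, 0.81), (4.05, 0.71)),
    ("rate", "RedF"): ((3.56, 0.87), (3.94, 0.68)),
    ("RhyStrCons", "NF"): ((0.70, 0.16), (0.82, 0.13)),
    ("RhyStrCons", "RedF"): ((0.81, 0.11), (0.85, 0.13)),
}

# Feature support used for truncated-normal sampling.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "whis": (0.0, 100.0),
    "SpErr": (0.0, np.inf),
    "RT": (0.0, np.inf),
    "rate": (0.0, np.inf),
    "RhyStrCons": (-1.0, 1.0),
}

DEFAULT_AGE = {"PD": (68.6, 11.0, (38.0, 88.0)), "control": (66.0, 9.0, (46.0, 93.0))}


@dataclass(frozen=True)
class CohortEffectSpec:
    """Sampling distributions for an emulated participant-level feature table."""

    group_stats: dict[tuple[str, str], tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_STATS)
    )
    age: dict[str, tuple[float, float, tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_AGE)
    )
    n_pd: int = 28
    n_ctrl: int = 30
    seed: int = 0

    def validate(self) -> None:
        if self.n_pd < 1 or self.n_ctrl < 1:
            raise ValueError("group sizes must be positive")
        for key, ((m_pd, s_pd), (m_c, s_c)) in self.group_stats.items():
            if s_pd < 0 or s_c < 0:
                raise ValueError(f"negative SD for {key}")


@lru_cache(maxsize=512)
def _matched_truncnorm_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent (loc, scale) whose truncation to [lo, hi] has the target moments.

    The target mean/SD describe the observed feature distribution, so the
    truncated distribution — not the unbounded parent — should carry them.
    When the target SD is unattainable on the support (e.g. a percentage
    with SD 40 on [0, 100], which only a bimodal distribution can achieve,
    or an error rate whose SD exceeds its mean under truncation at zero),
    the mean is matched exactly and the SD as closely as the support
    allows: the emulated group means must stay faithful to the configured
    ones for downstream sample-mean checks to hold.
    """

    def residuals(theta):
        loc, log_scale = theta
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        unit = max(sd, 0.05 * abs(mean), 1e-6)
        # mean residual dominates: SD is a best-effort match on the support
        return [100.0 * (float(m) - mean) / unit, (np.sqrt(float(v)) - sd) / unit]

    span = hi - lo if np.isfinite(hi - lo) else 10 * sd
    theta0 = np.array([mean, np.log(max(sd, 1e-6))])
    sol = least_squares(
        residuals,
        theta0,
        bounds=([mean - 5 * max(sd, 1e-6), np.log(1e-6)], [mean + 5 * max(sd, 1e-6), np.log(10 * max(sd, span, 1e-6))]),
        xtol=1e-10,
        ftol=1e-12,
    )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _sample_truncnorm(
    mean: float, sd: float, bounds: tuple[float, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = bounds
    if sd == 0:
        return np.full(n, np.clip(mean, lo, hi))
    loc, scale = _matched_truncnorm_params(float(mean), float(sd), float(lo), float(hi))
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


def synthesize_cohort_audio(
    n_pd: int = 4,
    n_ctrl: int = 4,
    n_trials: int = config.N_TRIALS_PER_CONDITION,
    conditions: tuple[str, ...] = config.CONDITIONS,
    sample_rate: int = config.DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    group_stats: dict | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str, int], np.ndarray]]:
    """Generate a small waveform-level cohort with group-dependent behavior.

    Participant-level latent traits (whispering reliability, reaction time,
    syllabic rate, timing jitter, error rate) are drawn from the same group
    distributions as :func:`emulate_cohort` and rendered into trial
    waveforms: in whisper-required conditions each trial is whispered with
    the participant's whispering probability, onsets and rates follow the
    participant's draws, and timing jitter increases as the participant's
    rhythm consistency decreases. Error counts are attached as annotations
    (Poisson with the participant's error rate), mirroring their
    human-annotated origin.

    Returns a trials manifest (participant_id, group, age, condition,
    trial_index, error_count plus ground-truth columns) and a dict of
    waveforms keyed by (participant_id, condition, trial_index).
    """
    stats_map = group_stats or DEFAULT_GROUP_STATS
    rng = np.random.default_rng(seed)
    rows = []
    waves: dict[tuple[str, str, int], np.ndarray] = {}
    for gi, (group, n) in enumerate([("PD", n_pd), ("control", n_ctrl)]):
        age_m, age_s, age_b = DEFAULT_AGE[group]
        for p in range(n):
            pid = f"{'PD' if group == 'PD' else 'C'}{p + 1:02d}"
            age = float(_sample_truncnorm(age_m, age_s, age_b, 1, rng)[0])
            for cond in conditions:
                stat_cond = cond if ("RT", cond) in stats_map else "RedF"
                whis_p = (
                    0.0
                    if cond == "NF"
                    else float(
                        _sample_truncnorm(*stats_map[("whis", cond)][gi], (0, 100), 1, rng)[0]
                    )
                    / 100.0
                )
                rt_mean = float(
                    _sample_truncnorm(*stats_map[("RT", stat_cond)][gi], (0.05, 2.0), 1, rng)[0]
                )
                rate = float(
                    _sample_truncnorm(*stats_map[("rate", stat_cond)][gi], (2.0, 6.0), 1, rng)[0]
                )
                cons = float(
                    _sample_truncnorm(
                        *stats_map[("RhyStrCons", stat_cond)][gi], (-1, 1), 1, rng
                    )[0]
                )
                jitter_sd = 0.005 + 0.06 * max(0.0, 1.0 - cons)
                err_rate = float(
                    _sample_truncnorm(*stats_map[("SpErr", stat_cond)][gi], (0, np.inf), 1, rng)[0]
                )
                for t in range(1, n_trials + 1):
                    onset = float(np.clip(rng.normal(rt_mean, 0.08), 0.05, 1.5))
                    n_syl = max(1, int(np.floor((config.PHASE_DURATION - onset) * rate)))
                    voiced = cond == "NF" or rng.random() > whis_p
                    tspec = TrialSynthSpec(
                        syllabic_rate=rate,
                        n_syllables=n_syl,
                        onset_delay=onset,
                        rate_jitter_sd=jitter_sd,
                        voiced=voiced,
                        snr_db=30.0,
                        sample_rate=sample_rate,
                        seed=int(rng.integers(2**31 - 1)),
                    )
                    wave, truth = synthesize_trial(tspec)
                    errors = int(rng.poisson(err_rate * config.PHASE_DURATION))
                    waves[(pid, cond, t)] = wave
                    rows.append(
                        {
                            "participant_id": pid,
                            "group": group,
                            "age": age,
                            "condition": cond,
                            "trial_index": t,
                            "error_count": errors,
                            "true_onset": truth.onset,
                            "true_rate": truth.rate,
                            "true_voiced": voiced,
                        }
                    )
    return pd.DataFrame(rows), waves


def emulate_cohort(spec: CohortEffectSpec | None = None) -> pd.DataFrame:
    """Draw a participant-level feature table from group sampling distributions.

    Each feature is drawn independently from a normal with the configured
    group mean/SD, truncated to its natural support (percentages to [0, 100],
    consistency to [-1, 1], rates/times/error rates to non-negative values).
    Returns a table with one row per participant and columns
    ``participant_id``, ``group``, ``age``, and one column per
    parameter/condition pair (e.g. ``whis_MF``, ``RT_RedF``).
    """
    spec = spec or CohortEffectSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    groups = [("PD", spec.n_pd), ("control", spec.n_ctrl)]
    frames = []
    for gi, (group, n) in enumerate(groups):
        mean, sd, bounds = spec.age[group]
        data = {
            "participant_id": [f"{'PD' if group == 'PD' else 'C'}{i + 1:02d}" for i in range(n)],
            "group": group,
            "age": _sample_truncnorm(mean, sd, bounds, n, rng),
        }
        for (param, cond), stats in spec.group_stats.items():
            m, s = stats[gi]
            data[config.feature_column(param, cond)] = _sample_truncnorm(
                m, s, PARAM_BOUNDS[param], n, rng
            )
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)
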