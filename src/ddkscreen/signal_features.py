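"""Envelope-domain rhythm features: envelope, modulation spectrum, syllabic rate.

The speech envelope is the magnitude of the analytic (Hilbert-transformed)
signal. Because the task elicits trains of non-coarticulated syllables, each
envelope cycle corresponds to one syllable, so the frequency of maximal power
in the envelope's spectrum (fMAX) estimates the syllabic rate. The
rhythmic-structure consistency of a set of trials is the mean pairwise
Pearson correlation between their envelope spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.fft import rfft, rfftfreq

from . import config


class NoRhythmicPeakError(ValueError):
    """Raised when an envelope spectrum has no peak above the numerical floor."""


class DegenerateSpectrumError(ValueError):
    """Raised when a zero-variance spectrum makes a correlation undefined."""


@dataclass(frozen=True)
class Envelope:
    """Non-negative amplitude contour of a waveform, at the source sample rate."""

    samples: np.ndarray
    sample_rate: float


@dataclass(frozen=True)
class EnvelopeSpectrum:
    """Power of the mean-removed envelope on a uniform frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    band: tuple[float, float]


def compute_envelope(
    waveform: np.ndarray,
    sample_rate: float,
    lowpass_hz: float | None = config.ENVELOPE_LOWPASS_HZ,
) -> Envelope:
    """Magnitude of the analytic signal, optionally low-pass smoothed.

    ``lowpass_hz`` (default 10 Hz) removes carrier/f0 leakage so only the
    syllabic-scale amplitude modulation remains; pass ``None`` for the raw
    rectified analytic magnitude. The output has the input's length and
    sample rate and is non-negative.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size == 0:
        raise ValueError("empty waveform")
    if not np.all(np.isfinite(waveform)):
        raise ValueError("waveform contains non-finite values")
    env = np.abs(sps.hilbert(waveform))
    if lowpass_hz is not None and lowpass_hz < sample_rate / 2:
        sos = sps.butter(4, lowpass_hz, btype="low", fs=sample_rate, output="sos")
        # zero-phase filtering keeps burst timing unshifted; clip tiny ringing
        env = np.clip(sps.sosfiltfilt(sos, env), 0.0, None)
    return Envelope(samples=env, sample_rate=float(sample_rate))


def envelope_spectrum(
    env: Envelope,
    band: tuple[float, float] = config.ANALYSIS_BAND,
    resolution: float = config.SPECTRUM_RESOLUTION,
    envelope_rate: float = config.ENVELOPE_RATE,
) -> EnvelopeSpectrum:
    """FFT power spectrum of the mean-removed envelope, restricted to ``band``.

    The envelope is resampled to ``envelope_rate`` (default 100 Hz, with
    anti-aliasing) and zero-padded so the frequency grid spacing is at most
    ``resolution`` (default 0.05 Hz). The mean is removed before the FFT so
    the DC bin never masks the syllabic peak.
    """
    lo, hi = band
    if not 0 <= lo < hi:
        raise ValueError("band must satisfy 0 <= low < high")
    if hi > env.sample_rate / 2:
        raise ValueError("band exceeds the Nyquist frequency")
    x = np.asarray(env.samples, dtype=float)
    if env.sample_rate > envelope_rate:
        decim = int(round(env.sample_rate / envelope_rate))
        x = sps.resample_poly(x, 1, decim)
        fs = env.sample_rate / decim
    else:
        fs = env.sample_rate
    duration = x.size / fs
    if lo < 1.0 / duration:
        raise ValueError(
            f"band low edge {lo} Hz below minimum resolvable frequency {1.0 / duration:.3f} Hz"
        )
    x = x - x.mean()
    n_fft = max(x.size, int(np.ceil(fs / resolution)))
    power = np.abs(rfft(x, n=n_fft)) ** 2
    freqs = rfftfreq(n_fft, d=1.0 / fs)
    mask = (freqs >= lo) & (freqs <= hi)
    return EnvelopeSpectrum(freqs=freqs[mask], power=power[mask], band=(lo, hi))


def syllabic_rate(spectrum: EnvelopeSpectrum, floor: float = 1e-12) -> float:
    """Frequency of maximal power (fMAX); ties break toward lower frequency.

    Raises :class:`NoRhythmicPeakError` when the spectrum is numerically flat
    (e.g. a constant envelope after mean removal).
    """
    if spectrum.power.size == 0:
        raise ValueError("empty spectrum")
    peak = float(np.max(spectrum.power))
    if peak <= floor * max(1.0, float(np.sum(spectrum.power))):
        raise NoRhythmicPeakError("no rhythmic peak above the numerical floor")
    return float(spectrum.freqs[int(np.argmax(spectrum.power))])


def rhythm_consistency(spectra: Sequence[EnvelopeSpectrum]) -> float:
    """Mean pairwise Pearson correlation between trial envelope spectra.

    With n trials this is the average of the n(n-1)/2 lower-triangle elements
    of the spectra's correlation matrix — 1.0 when the rhythmic structure is
    identical across trials, lower when it varies. Spectra must share one
    frequency grid; a zero-variance spectrum is degenerate and rejected.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra")
    base = spectra[0].freqs
    for sp in spectra[1:]:
        if sp.freqs.shape != base.shape or not np.allclose(sp.freqs, base):
            raise ValueError("spectra are on mismatched frequency grids")
    powers = np.vstack([sp.power for sp in spectra])
    if np.any(np.std(powers, axis=1) == 0):
        raise DegenerateSpectrumError("zero-variance spectrum in consistency computation")
    corr = np.corrcoef(powers)
    il = np.tril_indices(len(spectra), k=-1)
    return float(np.mean(corr[il]))
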