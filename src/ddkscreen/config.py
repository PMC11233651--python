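"""Task constants and default analysis parameters.

All timing constants of the behavioral paradigm live here so that no stage
hard-codes them: the 250-ms syllable, the 3.75-s target stimulus (15 syllables
at 4/s), the 5.5-s repetition phase, 7 trials per condition, the four
auditory-feedback conditions, and the whisper-classification threshold
(10% of the repetition phase, i.e. 0.55 s of voiced speech).
"""

from __future__ import annotations

# --- paradigm timing ---------------------------------------------------------
SYLLABLE_DURATION = 0.25          # s per syllable in the target stimulus
TARGET_SYLLABIC_RATE = 4.0        # syllables/s of the target stimulus
N_TARGET_SYLLABLES = 15           # three-syllable pattern repeated five times
TARGET_DURATION = 3.75            # s; N_TARGET_SYLLABLES * SYLLABLE_DURATION
PHASE_DURATION = 5.5              # s; repetition (production) phase analyzed
N_TRIALS_PER_CONDITION = 7

# Auditory-feedback conditions: Normal (speak aloud, hear self), Reduced
# (whisper, hear self), Masked (whisper, hear white noise), Replaced (whisper,
# hear an external rhythmic voice).
CONDITIONS = ("NF", "RedF", "MF", "RepF")
WHISPER_CONDITIONS = ("RedF", "MF", "RepF")

# --- whisper rule ------------------------------------------------------------
WHISPER_THRESHOLD_FRACTION = 0.10
WHISPER_THRESHOLD = WHISPER_THRESHOLD_FRACTION * PHASE_DURATION  # 0.55 s, strict <

# --- synthesis defaults ------------------------------------------------------
DEFAULT_SAMPLE_RATE = 16000       # Hz; ample for voicing detection up to 400 Hz f0
DEFAULT_F0 = 200.0                # Hz; pitch of the synthesized voiced source

# --- envelope / spectrum analysis --------------------------------------------
ANALYSIS_BAND = (1.0, 10.0)       # Hz; search band covering human syllabic rates
ENVELOPE_LOWPASS_HZ = 10.0        # Hz; removes carrier/f0 leakage from |analytic|
ENVELOPE_RATE = 100.0             # Hz; envelope sampling rate before the FFT
SPECTRUM_RESOLUTION = 0.05        # Hz; zero-padded FFT grid spacing

# --- silence / voicing detection ---------------------------------------------
SILENCE_THRESHOLD_DB = -25.0      # dB re trial maximum frame intensity
MIN_SILENT_DURATION = 0.1         # s; shorter quiet gaps are kept as speech
MIN_SOUNDING_DURATION = 0.05      # s; shorter bursts are discarded
INTENSITY_FRAME = 0.01            # s; intensity analysis frame/hop

VOICING_FRAME = 0.04              # s; autocorrelation analysis window
VOICING_HOP = 0.01                # s
F0_SEARCH_RANGE = (75.0, 400.0)   # Hz; lag range for the periodicity search
HARMONICITY_THRESHOLD = 0.45      # normalized autocorrelation peak for "voiced"

# --- statistics / classification ---------------------------------------------
ALPHA = 0.05
N_LOO_REPEATS = 100               # repeats of leave-one-out evaluation
RF_N_ESTIMATORS = 500
RF_MAX_FEATURES = "sqrt"

# Short feature names follow the field's condition/parameter pairing:
# whis = % whispered trials, SpErr = speech errors per second, RT = mean
# reaction time (s), rate = mean syllabic rate (Hz), RhyStrCons = rhythmic
# structure consistency across trials.
PARAM_CONDITIONS = {
    "whis": ("RedF", "MF", "RepF"),
    "SpErr": ("NF", "RedF"),
    "RT": ("NF", "RedF"),
    "rate": ("NF", "RedF"),
    "RhyStrCons": ("NF", "RedF"),
}

# Default group-comparison plan: 11 parameter/condition tests, FDR-corrected
# jointly. Whispering ability is only compared where whispering was required;
# the remaining parameters are compared in the Normal and Reduced feedback
# conditions, where both groups speak at the same voice level.
DEFAULT_COMPARISON_PLAN = tuple(
    (param, cond) for param, conds in PARAM_CONDITIONS.items() for cond in conds
)


def feature_column(param: str, condition: str) -> str:
    """Canonical cohort-table column name for a parameter/condition pair."""
    return f"{param}_{condition}"
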