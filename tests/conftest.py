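import numpy as np
import pytest

import ddkscreen as dd

SR = dd.config.DEFAULT_SAMPLE_RATE


@pytest.fixture(scope="session")
def sr():
    return SR


@pytest.fixture(scope="session")
def voiced_trial():
    """Standard voiced trial: 4 syll/s, onset 0.5 s, no jitter, 30 dB SNR."""
    spec = dd.TrialSynthSpec(
        syllabic_rate=4.0, n_syllables=18, onset_delay=0.5, voiced=True, seed=11
    )
    wave, truth = dd.synthesize_trial(spec)
    return wave, truth, spec


@pytest.fixture(scope="session")
def whispered_trial():
    spec = dd.TrialSynthSpec(
        syllabic_rate=4.0, n_syllables=18, onset_delay=0.5, voiced=False, seed=12
    )
    wave, truth = dd.synthesize_trial(spec)
    return wave, truth, spec


@pytest.fixture(scope="session")
def cohort_table():
    return dd.emulate_cohort(dd.CohortEffectSpec(seed=0))
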