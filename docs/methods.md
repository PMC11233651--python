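# Methods

## Signal model and feature extraction

**Envelope.** The speech envelope is the magnitude of the analytic signal
(Hilbert transform) of the trial waveform. Because each repeated syllable in
this task is produced without coarticulation, one envelope cycle corresponds
to one syllable. By default the raw magnitude is zero-phase low-pass filtered
at 10 Hz (4th-order Butterworth, applied forward-backward so burst timing is
not shifted) to remove carrier/f0 leakage; this can be disabled for the raw
rectified magnitude. Low-pass ringing can dip microscopically below zero, so
the filtered envelope is clipped at 0 to preserve non-negativity.

**Envelope spectrum and fMAX.** The envelope is resampled to 100 Hz with
anti-aliasing, mean-removed (otherwise the DC bin always dominates), and
zero-padded so the FFT grid spacing is at most 0.05 Hz. Power is analyzed in
1–10 Hz, a band that covers human syllabic rates; both band and resolution
are parameters. The syllabic rate fMAX is the argmax frequency, ties broken
toward the lower frequency; a numerically flat spectrum (e.g. a constant
envelope) raises a "no rhythmic peak" error rather than returning the first
bin.

**Rhythm consistency.** The mean of the n(n−1)/2 lower-triangle Pearson
correlations between the trials' band-limited power spectra. Correlations
are computed on power (not log power) within the analysis band; both choices
are exposed because either convention is defensible. A zero-variance
spectrum makes the correlation undefined and is treated as a degenerate
trial, not silently as r = 0.

**Silence detection and onset.** Frame intensities (10-ms non-overlapping
frames) are thresholded at −25 dB relative to the trial's loudest frame;
quiet runs shorter than 0.1 s are absorbed into speech, then sounding runs
shorter than 0.05 s are dropped. These are conventional silence-annotator
settings, not measured constants, and are all parameters. The reaction time
of a trial is the start of its first speech interval; trials with no
detected speech contribute no RT and no rate but still count in the
whispered-trial denominator.

**Voicing and the whisper rule.** A 40-ms frame (10-ms hop) is voiced when
its lag-normalized autocorrelation reaches 0.45 at a lag corresponding to
75–400 Hz and its level is above the silence floor (the energy gate keeps
background frames from scoring as periodic; the periodicity criterion itself
is amplitude-invariant). Total voiced duration below 10% of the 5.5-s
repetition phase — 0.55 s, strict less-than — classifies the trial as
whispered. In the original protocol this judgment was made by ear; the
autocorrelation criterion automates it with an equivalent acoustic
definition, and the threshold is a parameter.

**Aggregation.** Errors/s uses the denominator (trials with detected speech
× phase duration), so fully silent trials do not dilute the rate; error
counts themselves are annotations (human-identified syllable repetitions,
exchanges, misarticulations), not acoustic measurements. Rate, RT and
consistency are extracted for every condition regardless of whisper status;
the comparison plan, not the extraction, restricts which condition's values
are tested.

## Statistics

Two-sided Mann-Whitney U tests per parameter/condition pair: exact null
distribution when the combined n ≤ 20 without ties, tie-corrected normal
approximation otherwise. The default plan runs 11 tests (%whispered in the
three whisper-required conditions; the other four parameters in Normal and
Reduced feedback) and adjusts them jointly with Benjamini-Hochberg FDR — the
family is configurable since nothing forces the joint choice. Effect sizes
are rank-biserial correlations from direct pair counting, ties contributing
zero, signed so that positive r means controls exceed the PD group; both raw
and adjusted p are reported.

## Classification

Random forest (default 500 trees, √p features per split, unlimited depth —
conventional defaults, fully exposed) on four fixed feature sets: the five
separating parameters (Model 1), dropping the Masked or Replaced whisper
percentage (Models 2, 3), and Model 2 plus age (Model 4). Evaluation is
leave-one-out: every participant is predicted by a forest trained on all
others, the pooled predictions give one accuracy/sensitivity/specificity
triple (PD positive), and the procedure is repeated (default 100×) with
fresh forest randomness, reporting means and SDs. Participants missing a
required feature are median-imputed from the training fold of each split,
so LOO never silently drops a test subject.

## Synthetic data

**Waveforms.** A trial is a train of per-syllable Hann bursts (200 ms of a
250-ms slot) on a carrier: a harmonic complex at f0 = 200 Hz with 1/k
harmonic rolloff for voiced speech, or 500–4000 Hz band-limited noise for
whispering, plus white background noise at a configurable SNR (default
30 dB; SNR is defined against the RMS of the active burst samples). Syllable
onsets are nominal grid times plus independent Gaussian jitter. The
generator returns the realized ground truth (onset, rate, voiced duration),
and the target-style stimulus is 15 syllables at 4/s over 3.75 s with a
cyclic triplet of burst amplitudes standing in for the pa-ta-ka alternation.
This emulates the envelope-scale structure the metrics operate on and
nothing below it: there are no formants, no consonant/vowel internal
structure, no coarticulation and no room acoustics, so passing tests
demonstrate correct envelope-domain computation, not robustness to real
recording conditions.

**Feature cohorts.** Participant-level features are drawn independently per
parameter from truncated normals on each feature's natural support
(percentages in [0, 100], consistency in [−1, 1], rates/times/error rates
≥ 0), with group means/SDs defaulting to the pilot-cohort summary statistics
(28 PD, 30 controls). The parent location/scale are solved numerically so
that the *truncated* distribution carries the configured moments, with the
mean matched exactly and the SD best-effort: some printed moment pairs are
unattainable on the support (a percentage with SD ≈ 40 on [0, 100] implies a
bimodal distribution — participants who whisper almost all or almost none of
their 7 trials; an error rate with SD > mean under zero-truncation implies
zero-inflation), and in those cases the sampler keeps the mean faithful and
accepts the largest SD the family allows. Features are drawn independently
across parameters; real features are correlated, so classifier results on
emulated cohorts probe the pipeline, not the paradigm's true effect size.
The audio-level cohort generator maps the same group distributions onto
waveform parameters (whispering probability, onset, rate, jitter increasing
as consistency decreases) and attaches Poisson error counts as annotations.

## Problem sizes and numerical choices

Statistical checks run 50–100 emulated cohorts; classifier checks use one
evaluation repeat with 30–100-tree forests on cohorts of 16–58 participants,
and the analysis driver defaults to 5 repeats × 100 trees — the LOO metrics
stabilize well below the heavyweight 100 × 500 configuration, which remains
available through `ModelSpec`. Determinism: every stochastic component takes
a seed; repeated runs with the same configuration are bit-identical.
Degenerate inputs (all-silent trials, constant envelopes, single-class
tables, zero-variance spectra) raise typed errors or produce defined missing
values rather than NaNs.

## Known limitations

Synthetic whispered speech is stationary band-noise; real whispers retain
formant structure that can weakly autocorrelate. The silence-annotator
parameter values are conventions (the original protocol used an interactive
tool without publishing its settings). Error counts are never derived from
audio. The emulated cohort cannot reproduce inter-feature correlations or
the exact discreteness of 7-trial percentages, and group-level conclusions
on it validate the machinery rather than the clinical effect.
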