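# ddkscreen

Rhythm and articulation analysis of syllable-repetition speech under altered
auditory feedback, for screening Parkinsonism.

## The problem

Dysarthria is an early symptom of Parkinson's disease (PD), and people with
PD also integrate auditory feedback abnormally during speech production. This
package implements the analysis for a behavioral test that combines the two
observations: participants rhythmically repeat the syllables PA-TA-KA at a
trained pace (4 syllables/s) during a 5.5-s repetition phase, under four
auditory-feedback conditions — Normal (speak aloud, hear yourself), Reduced
(whisper, hear your whisper), Masked (whisper, hear white noise) and Replaced
(whisper, hear an external voice at the target rhythm) — with 7 trials per
condition.

From each trial's recording five per-condition parameters are derived:

1. **%whis** — percentage of whispered trials. A trial is whispered when its
   voiced (vocal-fold-activated) speech lasts less than 10% of the phase
   (0.55 s, strict), detected by short-time autocorrelation periodicity.
2. **Sp.Err** — annotated speech errors (syllable repetitions, exchanges,
   misarticulations) per second of attempted speech.
3. **RT** — mean reaction time: the onset of the first speech interval found
   by Praat-style silence detection (intensity threshold −25 dB re trial
   maximum, minimum silent 0.1 s, minimum sounding 0.05 s).
4. **rate** — mean syllabic rate fMAX: the frequency of maximal power in the
   spectrum of the speech envelope |H(x)| (magnitude of the Hilbert-transform
   analytic signal), searched in 1–10 Hz.
5. **Rhy.Str.Cons** — rhythmic structure consistency: the mean of the
   lower-triangle pairwise Pearson correlations between the 7 trial envelope
   spectra, Sp₁…Sp₇.

The statistics layer compares PD vs control with two-sided Mann-Whitney U
tests (11 planned parameter/condition tests, Benjamini-Hochberg FDR jointly)
and rank-biserial effect sizes r = p(favorable) − p(unfavorable). The
screening layer feeds the separating parameters into a random-forest
classifier evaluated by repeated leave-one-out cross-validation (accuracy,
sensitivity and specificity with PD as the positive class, averaged over
repeats).

Because clinical recordings cannot ship with the package, a synthesis module
generates (a) ground-truth-annotated syllable-train waveforms (voiced
harmonic or whispered noise bursts, with controllable onset, rate, timing
jitter and SNR) and (b) participant-level cohort tables drawn from
configurable group means/SDs, whose defaults emulate the 28 PD + 30 control
pilot cohort this paradigm was developed on.

## Worked example

```python
import ddkscreen as dd

# a 3.75-s target-style stimulus: 15 syllables at 4/s
wave = dd.synthesize_target_audio(voiced=True)
spec = dd.envelope_spectrum(dd.compute_envelope(wave, 16000))
print(dd.syllabic_rate(spec))          # 4.0  (Hz; the trained syllabic rate)

# emulated 28 + 30 cohort and the planned group comparisons
table = dd.emulate_cohort(dd.CohortEffectSpec(seed=1))
res = dd.compare_groups(table)
print(res.loc[res.parameter == "whis",
              ["condition", "p_fdr", "r_rank_biserial"]])
#   condition     p_fdr  r_rank_biserial
# 0      RedF  0.079682         0.283333
# 1        MF  0.005025         0.459524
# 2      RepF  0.000010         0.752381
```

Whispering ability separates the groups only when feedback is masked or
replaced (FDR-adjusted p < 0.05 with positive r: controls whisper more
reliably than the PD group), not under reduced feedback — the pattern the
test is designed to elicit.

The numbered drivers under `analysis/` run the full study flow and write
their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py     # cohort.csv, trials_manifest.csv (+ WAVs in scratch/)
python analysis/02_extract_features.py    # cohort_from_audio.csv, extraction_quality.csv
python analysis/03_group_statistics.py    # comparisons.csv
python analysis/04_classify.py            # classifier_report.csv
```

On the simulated audio cohort the extraction recovers the generator's ground
truth with ~16 ms onset error, ~0.01 Hz rate error and 100% whisper
agreement; on the emulated feature cohort the four screening models reach
leave-one-out accuracies near 80%, with the Replaced-feedback model (Model 2)
ahead of its Masked-feedback counterpart (Model 3) and age adding nothing.

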