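"""Simulate the study cohort at both levels: feature table and trial audio.

Writes:
  results/cohort.csv           — emulated 28 PD + 30 control feature table
  results/trials_manifest.csv  — manifest of a small audio-level cohort
                                 (4 + 4 participants, 7 trials x 4 conditions)
  scratch/audio/*.wav          — the rendered trial waveforms (scratch only)
"""

from pathlib import Path

import ddkscreen as dd

RESULTS = Path("results")
SCRATCH = Path("scratch/audio")
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    table = dd.emulate_cohort(dd.CohortEffectSpec(seed=SEED))
    table.to_csv(RESULTS / "cohort.csv", index=False, float_format="%.6f")
    means = table.groupby("group")[["whis_MF", "whis_RepF", "RT_RedF", "RhyStrCons_NF"]].mean()
    print(f"Emulated feature cohort: {len(table)} participants -> results/cohort.csv")
    print(means.round(2).to_string())

    manifest, waves = dd.synth.synthesize_cohort_audio(n_pd=4, n_ctrl=4, seed=SEED)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    paths = []
    for (pid, cond, t), wave in waves.items():
        p = SCRATCH / f"{pid}_{cond}_{t}.wav"
        dd.io.write_wav(p, wave, dd.config.DEFAULT_SAMPLE_RATE)
        paths.append(str(p))
    manifest["wav_path"] = paths
    manifest.to_csv(RESULTS / "trials_manifest.csv", index=False, float_format="%.6f")
    print(
        f"\nAudio cohort: {manifest.participant_id.nunique()} participants, "
        f"{len(manifest)} trials -> results/trials_manifest.csv (+ WAVs in scratch/audio)"
    )


if __name__ == "__main__":
    main()
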