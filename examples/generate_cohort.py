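"""Generate a small synthetic conversation-EEG cohort and write it to disk.

Builds 2 subjects x 4 one-minute trials with the default signal model
(1/f background, theta/alpha/beta oscillations, 60 Hz mains, drift and a
lateralized alpha-power class effect), then writes one OpenBCI-dialect
TXT per trial plus a ratings CSV.
"""

from pathlib import Path

from rteeg.synthetic import GeneratorConfig, generate_cohort, write_cohort

config = GeneratorConfig(n_subjects=2, n_trials_per_subject=4, seed=42)
cohort = generate_cohort(config)

print(f"cohort: {len(cohort)} sessions "
      f"({config.n_subjects} subjects x {config.n_trials_per_subject} trials)")
for s in cohort.sessions[:4]:
    rec = s.recording
    print(f"  {s.subject_id} trial {s.trial_index}: "
          f"{rec.n_channels} ch x {rec.n_samples} samples @ {rec.fs:g} Hz, "
          f"ratings P={s.ratings.pleasure:+d} A={s.ratings.arousal:+d} "
          f"S={s.ratings.stress}, label={s.true_label.value}")

out = Path("scratch/example_cohort")
manifest = write_cohort(cohort, out)
print(f"wrote {len(manifest['txt_files'])} TXT recordings and "
      f"{manifest['ratings_file'].name} to {out}/")
# Each TXT is a full 60-s, 8-channel recording; the ratings CSV holds one
# self-assessment row per trial, the input to the emotion-labeling step.
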