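#!/usr/bin/env python
"""Simulate the study cohort.

Generates the full behavioral trial table (6 subjects x 175 trials x 2
masking conditions, latent-state-coupled keyword outcomes and ground-truth
band powers) and a reduced EEG cohort (6 subjects x 20 trials x 2
conditions) whose epochs carry calibrated alpha/beta oscillations, 1/f
background, common-mode signal, and blink artifacts.

Outputs: results/trial_table.csv, scratch/epochs_raw.h5.
"""

from pathlib import Path

from oscispeech import synthgen

ROOT = Path(__file__).resolve().parents[1]
SEED = 2023

results = ROOT / "results"
scratch = ROOT / "scratch"
results.mkdir(exist_ok=True)
scratch.mkdir(exist_ok=True)

full = synthgen.SynthParams(seed=SEED)
table = synthgen.simulate_behavior(full)
table.to_csv(results / "trial_table.csv", index=False)

counts = table.groupby("condition").size()
mean_score = table.groupby("condition")["score"].mean()
print(f"trial table: {len(table)} trials "
      f"({', '.join(f'{c}: {n}' for c, n in counts.items())})")
print("mean percent-correct by condition:",
      {c: round(v, 1) for c, v in mean_score.items()})

eeg_params = synthgen.SynthParams(n_trials_per_condition=20, seed=SEED)
eeg_table = synthgen.simulate_behavior(eeg_params)
epochs, truth = synthgen.synthesize_cohort(eeg_params, eeg_table)
synthgen.save_epochs_h5(scratch / "epochs_raw.h5", epochs)
n_blinks = sum(len(o) for o in truth["blink_onsets"])
print(f"EEG cohort: {len(epochs)} epochs of "
      f"{epochs.data.shape[2]} samples at {epochs.sampling_rate:g} Hz, "
      f"{n_blinks} blink events injected")
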