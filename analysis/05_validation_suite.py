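#!/usr/bin/env python
"""Run the calibration/power validation suite at reduced replicate counts.

A quick-look version of scripts/acceptance.py: null-test calibration and
power, band-power recovery, score-model power/type-I, multinomial
independent-contribution rates, and pre/during shared-variance recovery.

Output: results/validation.json.
"""

import json
from pathlib import Path

from oscispeech import validation

ROOT = Path(__file__).resolve().parents[1]
SEED = 2023

out = {
    "design": validation.design_degrees_of_freedom(SEED),
    "timeline": validation.timeline_geometry(),
    "spectrogram_oracle": validation.spectrogram_oracle(SEED),
    "null_calibration": validation.null_test_calibration(SEED, n_datasets=100),
    "null_power": validation.null_test_power(SEED, n_datasets=50),
    "band_recovery": validation.band_power_recovery(SEED, n_epochs=100),
    "score_anova_rates": validation.score_anova_rates(SEED, n_power=50, n_null=100),
    "multinomial_rates": validation.multinomial_contribution_rates(SEED, n_cohorts=50),
    "rho_recovery": validation.rho_period_recovery(SEED, n_cohorts=30),
}
(ROOT / "results" / "validation.json").write_text(json.dumps(out, indent=2))
for name, block in out.items():
    print(f"{name}: {block}")
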