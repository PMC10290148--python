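#!/usr/bin/env python
"""Fit the brain-behavior model chain on the full simulated cohort.

Uses the ground-truth single-trial band powers of the full 2100-trial table
(the design-scale analogue of the extracted powers in
results/band_power.csv): ordered-factor ANOVA of log power on percent-
correct score, successive-difference step tests, the alpha-beta random-
intercept mixed model, individual-differences ANOVAs, the multinomial
deviance partition, and the pre/during regression.

Outputs: results/model_results.json, results/deviance_table.csv.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from oscispeech import stats

ROOT = Path(__file__).resolve().parents[1]

table = pd.read_csv(ROOT / "results" / "trial_table.csv")

results = {}
for band in ("alpha", "beta"):
    anova = stats.power_score_anova(table, band=band)
    results[f"{band}_score_anova"] = anova
    term = anova.term("score")
    print(f"{band}: score F({term.df_num:.0f},{term.df_den:.0f}) = "
          f"{term.statistic:.3f}, p = {term.p_value:.3g}; "
          f"linear-contrast t = {anova.term('score_linear').statistic:.2f}")
    results[f"{band}_steps"] = stats.successive_difference_tests(table, band=band)
    predur = stats.pre_during_correlation(table, band=band)
    results[f"{band}_pre_during"] = predur
    print(f"{band}: pre/during R^2 = {predur.extras['r_squared']:.4f}, "
          f"df = {predur.extras['df']}")

lmm = stats.alpha_beta_association(table)
t = lmm.term("alpha")
print(f"alpha-beta LMM: F(1, {t.df_den:.1f}) = {t.statistic:.2f}, "
      f"p = {t.p_value:.3g} (slope {t.estimate:.3f} dB/dB)")
results["alpha_beta_association"] = lmm

for outcome in ("alpha_db", "beta_db", "log_ratio"):
    res = stats.individual_differences_anova(table, outcome=outcome)
    term = res.term("subject")
    print(f"individual differences in {outcome}: "
          f"F({term.df_num:.0f},{term.df_den:.0f}) = {term.statistic:.1f}")
    results[f"individual_{outcome}"] = res

multinom = stats.multinomial_deviance(table)
results["multinomial"] = multinom
rows = [
    {"term": t.name, "chi_square": t.statistic, "df": t.df_num, "p": t.p_value}
    for t in multinom.terms
]
pd.DataFrame(rows).to_csv(ROOT / "results" / "deviance_table.csv", index=False)
print("analysis of deviance (score ~ alpha + beta + condition):")
for row in rows:
    print(f"  {row['term']:>9}: chi2 = {row['chi_square']:.2f}, "
          f"df = {row['df']:.0f}, p = {row['p']:.3g}")

payload = {
    name: {
        "description": res.description,
        "terms": [dataclasses.asdict(t) for t in res.terms],
        "extras": {k: v for k, v in res.extras.items() if not hasattr(v, "to_dict")},
        "notes": res.notes,
    }
    for name, res in results.items()
}
(ROOT / "results" / "model_results.json").write_text(json.dumps(payload, indent=2))
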