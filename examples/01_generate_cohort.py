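"""Generate a synthetic ICU cohort and inspect its structure.

The generator emits four tidy tables: patients (demographics and stay),
observations (long-format physiological time series over 33 variables),
interventions (timed vasoactive / fluid / transfusion records) and a
ground-truth table recording each patient's destined group and, for
unstable patients, the true intervention onset time.
"""

import hemodyn as h

config = h.GeneratorConfig(n_patients=300, prevalence=0.19, seed=42)
cohort = h.generate_cohort(config)

print(f"patients:      {len(cohort.patients)} rows")
print(f"observations:  {len(cohort.observations)} rows, "
      f"{cohort.observations['variable'].nunique()} variables")
print(f"interventions: {len(cohort.interventions)} rows")
print(cohort.ground_truth["group"].value_counts().to_string())

unstable = cohort.ground_truth.query("group == 'unstable'")
print(f"\nmedian onset: {unstable['onset_time'].median():.1f} h after admission")
print(f"theoretical AUROC of the latent signal at lead 1: "
      f"{h.theoretical_auroc(config.latent_separation_d):.4f}")
# About 19% of patients are destined to receive a qualifying hemodynamic
# intervention; a perfect score recovering the latent severity would
# discriminate them from stable patients with the printed AUROC.
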