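# hemodyn

An external-validation harness for hemodynamic-instability early-warning
scores in the intensive care unit.

## The problem

Roughly one in five ICU patients deteriorates to the point of needing a
hemodynamic intervention — vasoactive drugs, large-volume fluid
resuscitation, or blood transfusion. Early-warning scores that estimate the
hourly probability of such an intervention exist (commercial tree-ensemble
scores over ~33 routinely measured physiological variables, as well as
single-parameter indicators like systolic blood pressure and the shock
index SI = HR/SBP), but validating one on a new cohort requires a long
chain of infrastructure that is rarely published:

1. **Outcome annotation from intervention logs** — instability is
   operationalized as receipt of a qualifying intervention: any dose of an
   inotrope/vasopressor; crystalloid/colloid ≥ 2400 cc in 8 h or ≥ 3000 cc
   in 12 h; 25% albumin ≥ 200 cc in 2 h; PRBC > 1500 cc in 24 h; or a
   PRBC + FFP + platelet-pheresis bundle (500 cc each) within 6 h. Onsets
   are detected with half-open look-back windows evaluated at event times,
   merged into unstable segments; only the first segment beginning more
   than 6 h after ICU admission is validated.
2. **Feature extraction** — plausibility filtering, hourly sampling with
   last-observation-carried-forward under per-variable staleness limits,
   and fallback imputation (noninvasive pressures fill invasive ones;
   missing FiO₂ → 0.21; everything else stays missing).
3. **Evaluation** — AUROC with DeLong confidence intervals and paired
   tests against baselines, time-varying AUROC per pre-onset hour,
   threshold sweeps (alarm when score > 0.7 by default), alarm lead-time
   and false-alarm analysis, calibration tables, subgroup and case-mix
   (median-shift) reports.

`hemodyn` implements that whole chain as a library, together with a
**synthetic ICU cohort generator** with known latent structure, so every
stage is testable end to end without access to any protected data. Any
conforming scorer can be plugged into the evaluation harness; a retrainable
gradient-boosted tree ensemble with native missing-value handling is
provided as the reference scorer.

## The synthetic cohort's key property

Each patient carries a latent severity process `z(t)` (stationary,
unit-variance, Ornstein–Uhlenbeck). Destined-unstable patients accrue a
linear deterioration ramp that raises the latent signal by `d` standard
deviations by one hour before onset, and every physiological variable
loads on the latent signal with a signed clinical drift (BP, hemoglobin,
hematocrit fall; HR, CVP, BUN, lactate, AST, creatinine, airway pressures,
FiO₂ rise). A score equal to the latent signal therefore has the
closed-form AUROC

    AUROC(lead 1) = Φ(d / √2),    e.g. Φ(1.5/√2) ≈ 0.856,

which the full pipeline (generate → annotate → featurize → train →
evaluate) is required to recover on held-out patients — a parameter-recovery
check of the entire harness, not of any single stage.

## Worked example

```python
import hemodyn as h

config = h.RunConfig(out_dir="scratch/example_run", seed=11,
                     generator={"n_patients": 600})
result = h.run_full_pipeline(config)
```

Output (from `examples/04_full_validation_run.py`):

```
held-out AUROC at lead 1: 0.827 (0.772-0.882)
  vs shock_index  AUROC 0.753, paired DeLong p = 0.026
  vs sbp          AUROC 0.704, paired DeLong p = 0.00054
alarm threshold 0.70: recall 0.21, specificity 0.97
median first-alarm lead 14.0 h; 60% of unstable patients alarmed >= 5 h early;
stable false-alarm rate 0.08
```

The first line is the discrimination of the retrained reference score one
hour before intervention onset on held-out patients, with its 95% DeLong
interval; the paired p-values test whether it beats the single-parameter
baselines on the same samples. The threshold line reads off the confusion
matrix at the default alarm cutoff (alarm when score > 0.7), and the last
line summarizes when alarms first fire relative to onset and how often
stable patients' hourly scores cross the threshold.

Narrative scripts in `examples/` cover each capability: cohort generation,
annotation, feature extraction + training, and the full run. A thin CLI
mirrors the stages (`hemodyn generate|annotate|featurize|train|score|run`).

## What this is not

The package does not ship, and cannot reproduce, any proprietary trained
score or any protected patient cohort; the reference scorer is a stand-in
with the same contract (hourly probability, tolerant of missing inputs).
See `docs/methods.md` for the model of the generator, the annotation
conventions, and known limitations.
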