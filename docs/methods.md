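# Methods

This note documents the models, conventions and numerical choices behind
`hemodyn`: what the synthetic cohort emulates, how instability is
annotated, how features are sampled and imputed, what the reference scorer
is, and how the evaluation statistics are computed. It also records the
design decisions that were genuinely open and why they were resolved the
way they were.

## 1. Synthetic cohort model

### Latent severity

Every patient carries a latent severity process `z(t)`, a stationary
unit-variance Ornstein–Uhlenbeck process on an hourly grid with
correlation time `severity_corr_time_h` (default 36 h): severity
fluctuates over a stay and decorrelates over about a day and a half.
Destined-unstable patients (Bernoulli with probability `prevalence`,
default 0.19) additionally accrue a deterministic linear ramp: over the
`deterioration_horizon_h` (default 24 h) preceding their intervention
onset, the latent signal rises from `z(t)` to `z(t) + d`, reaching the
full separation `d = latent_separation_d` exactly one hour before onset
and holding there. Consequently the latent signal one hour pre-onset is
`N(d, 1)` for unstable and `N(0, 1)` for stable patients, and a score
equal to it has AUROC `Φ(d/√2)` (`theoretical_auroc`).

Each of the 33 registry variables is charted on a category schedule
(vitals hourly, blood gas 8-hourly, ventilation 4-hourly, labs daily) as

    value = ref + ref_sd · (0.4·b + drift·L(t) + 0.8·ε),

where `b` is a per-patient baseline offset, `ε` per-observation noise,
`L(t)` the latent signal at the charting time, and `drift` a signed
per-variable magnitude (0.1–0.8 SD) whose direction matches the clinical
picture of impending instability: falling blood pressures, hemoglobin,
hematocrit, SpO₂, pH, bicarbonate; rising heart rate, CVP, respiratory
rate, BUN, creatinine, AST, lactate, airway pressures, FiO₂. Values are
clipped into the registry plausibility ranges, so the plausibility filter
is a no-op on clean synthetic data. Scheduled samples are then dropped
independently per variable (vitals 5%, labs and blood gas 15%, lactate
22.1%, ventilation 30% by default).

**Why an OU process rather than a fixed per-patient severity.** With a
severity frozen at admission, a flexible model can *cancel* the latent
noise by differencing fresh measurements (carrying the full ramp) against
stale ones (carrying less of it), and thereby beat the `Φ(d/√2)` ceiling
that the parameter-recovery check requires the pipeline to match. A
fluctuating severity is both more realistic and removes that artificial
channel: stale observations decorrelate from the state at the reference
time. The correlation time and the observation-noise scale (0.8 reference
SDs) were calibrated once so that the held-out pipeline AUROC at lead 1
centers on the closed form for d = 1.5, and then frozen; they are the two
parameters that control how much of the latent separation survives
realistic sampling.

### Stays, onsets, interventions

Length of stay is lognormal with medians of 5 days (stable) and 12 days
(unstable), σ = 0.7 on the log scale, floored at 7 h and capped at 30
days. Onset times are `8 h + Gamma(shape 2, scale 14 h)` after admission —
always beyond the 6-h first-segment rule — and stays are extended to at
least onset + 12 h. Each unstable patient receives an explicit
intervention bundle whose *first qualifying crossing is exactly the true
onset*, rotating among four trigger kinds: a single vasoactive dose (raw
agent names mix brands and cases, e.g. "Levophed", to exercise
normalization); three 800-cc boluses at onset − 4/− 2/0 h (crossing
2400 cc/8 h at the third); two 800-cc PRBC units 6 h apart (1600 cc,
strictly exceeding the 1500-cc/24-h transfusion rule); or the 500-cc
PRBC + FFP + platelet-pheresis bundle within 6 h. Stable patients receive
no qualifying interventions but, with probability 0.3, a few 500-cc
distractor boluses spaced ≥ 10 h apart — too sparse to cross any volume
criterion, so annotation specificity is exercised honestly.

Demographics (age, gender, admission type/source, ICU type, APACHE II,
mortality by group) are drawn to match the qualitative profile of a large
mixed-ICU cohort; admission timestamps spread over 2010–2020 to support
year-by-year evaluation.

One global seed fans out to per-patient substreams keyed by a CRC-32 hash
of the patient id, so generating a subset of patients reproduces exactly
the draws those patients would have received in a larger cohort.

### What the generator does not emulate

No mechanistic cardiovascular physiology; no inter-variable correlation
beyond the shared latent signal (real labs co-move in blocks); no
informative missingness (dropout is independent of value); no
measurement-device artifacts beyond i.i.d. noise. Passing tests on this
cohort therefore demonstrate that the *harness* is correct and that a
learnable signal of known size is recovered — they say nothing about the
clinical performance of any particular score on real data.

## 2. Annotation conventions

Volume criteria use a half-open look-back window `(t − W, t]` with each
record's volume attributed wholly at its charted time; crossings are
evaluated at event times (volumes are point masses; continuous infusions
must be pre-discretized by the caller). Comparators follow the printed
rules verbatim: fluid "2400 cc in 8 h" is ≥ (reaching the stated dosage
triggers), the PRBC transfusion rule "> 1500 cc" is strict. Cumulative
sums carry a 10⁻⁶-cc tolerance so float cancellation cannot flip an exact
threshold.

After a crossing, detection re-arms only once the running window total
falls back below the threshold, so one sustained episode yields one onset.
The running total is piecewise constant and changes only when a record
enters the window or slides out of it (at `t + W`); re-arming is therefore
evaluated at both kinds of time points, while onsets can only fire at
event times. The companion rule "PRBC 500 cc in 2 h followed by fluid
therapy within 12 h" anchors the onset at the PRBC crossing `t₀` and
requires any fluid-therapy onset in `(t₀, t₀ + 12 h]`.

Consecutive onsets separated by at most `merge_gap_h` (default 1 h, the
scoring interval) form one segment; a segment's end is its last onset plus
the gap. These segment conventions are declared, configurable stand-ins:
the exact segment-construction rules of the validated score's original
study are not public.

Cohort partition: patients whose only segments begin within the first 6 h
are **excluded** rather than labeled stable — they did receive
interventions, and calling them stable would contaminate the negative
class. Inclusion requires age strictly over 20 years, a stay of at least
6 h, and a non-empty observation profile. The vasoactive agent dictionary
(brand → generic) is an editable data file, not code.

## 3. Feature registry and extraction

The default registry holds 33 variables — 11 vitals (HR, invasive and
noninvasive SBP/DBP/MAP, RR, SpO₂, temperature, CVP), 12 labs, 5 blood-gas
variables and 5 ventilation settings — each with units, a
literature-standard plausibility range, a staleness limit (vitals 4 h,
ventilation 8 h, labs/blood gas 48 h) and a fallback-imputation rule. It
ships as an editable CSV so a site can substitute its own ranges.

Processing order is fixed and tested: plausibility filter (out-of-range →
missing) → last-observation-carried-forward with expiry (the latest
observation at or before the reference time, no older than the staleness
limit; ties at one timestamp resolve to the last-written record) →
fallback imputation (noninvasive pressures fill the invasive columns;
missing FiO₂ becomes room air, 0.21; everything else stays missing).
Imputation never overwrites an observed value, and no value may originate
after the row's reference time.

Unstable patients contribute one row per integer lead 1…24 h before onset
(truncated at admission, label 1); stable patients one row at 5 h after
admission (label 0, lead 0). An hourly stable sampling mode exists for
false-alarm analyses; the pipeline instead scores explicit hourly
timelines, which serves the same purpose.

## 4. Reference scorer

A gradient-boosted ensemble of depth-limited trees
(`HistGradientBoostingClassifier`, 200 trees, depth 4, learning rate 0.1,
no early stopping) with native missing-value default branches: every
split routes missing values down a learned branch, so any subset of
missing inputs — including an all-missing row — yields a finite
probability. Training uses one randomly chosen lead row per unstable
patient plus all stable rows (onset-anchored training without leaking full
trajectories), after a canonical sort by (patient id, reference time) so
row order cannot change the fit. Train/test splits are by patient.
Features never observed in training are constant-filled at fit time only
(they carry no split information). The scorer is explicitly a retrainable
stand-in: the harness validates any conforming scorer and never claims to
reproduce a proprietary model's weights.

Baselines: shock index (HR/SBP, higher = riskier) and SBP (negated);
missing inputs give missing scores, dropped pairwise.

## 5. Evaluation statistics

* **AUROC** — Mann–Whitney with midranks (ties count ½); verified against
  exhaustive pair counting.
* **DeLong** — structural components `V10`/`V01` via midranks; variance
  `var(V10)/m + var(V01)/n`; normal CI truncated to [0, 1]; a zero-variance
  interval at AUROC 0 or 1 collapses to the point and is flagged. The
  paired test uses the component covariances; identical scores give
  z = 0, p = 1.
* **Time-varying AUROC** — unstable rows at lead t vs the single stable
  sample set reused at every lead (matching a design that extracts stable
  data once); an hour-matched stable mode is available through the
  stable-hourly sampling flag.
* **Thresholds** — alarm when score > t (strict), grid step 0.01.
  Policies: fixed (default 0.7), recall–specificity break-even, and
  max-specificity subject to a recall floor. The default mirrors the
  published choice of 0.7, which sits in the break-even region between
  recall and specificity.
* **Lead time** — per-hour fraction of unstable patients above threshold;
  first alarm = earliest crossing in the 24-h pre-onset window (reported
  as its lead, so the cumulative "alarmed ≥ k hours early" curve is
  non-increasing); stable false-alarm rate over the first 24 h of stable
  stays, per hour and overall.
* **Calibration** — equal-width probability bins (decile option via
  `n_bins`); empty bins keep zero counts.
* **Subgroups** — admission source, gender, admission type, ICU type,
  mortality, admission year (a sparse final year merges into the previous
  one); single-class groups are skipped and reported. P-values are raw, no
  multiplicity correction, and this is deliberate and documented.
* **Case mix** — per-variable medians of two cohorts and percent
  difference (B − A)/A; Kruskal–Wallis for continuous baseline
  characteristics, Fisher's exact test for categorical ones. Beyond 2×2,
  Fisher's test uses a seeded Monte Carlo estimate conditioning on the
  margins (tables sampled with fixed margins; a table counts as at least
  as extreme when its conditional probability does not exceed the observed
  one).

## 6. Problem sizes and determinism

The test suite and the acceptance script run the full pipeline at
n = 2,000 patients (the scale at which the closed-form recovery is
checked), the annotation round trip at n = 500 over five seeds, oracle
equivalence on 1,000 random logs, DeLong coverage over 500 replicates of
n = 200/200, and calibration self-consistency at n = 10,000. All
randomness derives from explicit seeds; identical configuration and seed
reproduce byte-identical tables and metrics.

## 7. Known limitations

* The annotation segment rules (merge gap, re-arm) are declared stand-ins
  where the original study's exact supplementary rules are not public;
  both are configurable.
* The stable group is summarized by a single 5-h sample in discrimination
  analyses; hourly stable behavior enters only the false-alarm analysis.
* The Monte Carlo Fisher p-value is an estimate (standard error ≈
  `√(p(1−p)/n_mc)`); increase `n_mc` where exactness matters.
* The generator's independence assumptions (noise, dropout) make the
  synthetic task easier than real EHR data in some respects (no block
  missingness, no device artifacts) and harder in others (no redundant
  correlated channels beyond the latent signal).
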