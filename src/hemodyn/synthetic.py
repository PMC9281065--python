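"""Synthetic ICU cohort generator.

Emits the three tidy tables the validation pipeline consumes — patients,
observations (long format), interventions — plus a ground-truth table, with
the statistical structure the downstream analysis assumes:

* a configurable fraction of patients (default 19%) is destined to receive a
  qualifying hemodynamic intervention (vasoactive drug, large-volume fluid
  therapy, or transfusion bundle) at an onset time drawn after the first
  6 h of the stay;
* every patient carries a latent severity process ``z(t)`` — a stationary
  unit-variance Ornstein-Uhlenbeck walk whose correlation time (default
  24 h) makes severity fluctuate over a stay instead of being frozen at
  admission; destined-unstable patients additionally accrue a linear
  deterioration ramp that lifts the latent signal by
  ``latent_separation_d`` standard deviations by one hour before onset, so
  a score that recovers the latent signal has a known closed-form AUROC of
  ``Phi(d / sqrt(2))`` at lead 1, and no combination of time-staggered
  measurements carries class information beyond that separation;
* each registry variable loads on the latent signal with a signed
  per-variable drift magnitude whose direction mirrors the clinical picture
  of impending instability (falling blood pressures, hemoglobin and
  hematocrit; rising heart rate, CVP, BUN, lactate, AST, creatinine, airway
  pressures and FiO2);
* variables are charted on category-specific schedules with per-variable
  missingness, and all emitted values lie inside the registry plausibility
  ranges.

One global seed fans out to per-patient substreams keyed by a stable hash of
the patient id, so generating a subset of patients never shifts another
patient's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .registry import FeatureRegistry, default_registry

EPOCH = pd.Timestamp("2010-01-01 00:00:00")
#: span of admission offsets (2010-01-01 .. 2020-03-31), days
ADMIT_SPAN_DAYS = 3742

#: signed drift (in SDs of the variable) per unit of latent signal
DEFAULT_DRIFT: dict[str, float] = {
    "heart_rate": 0.8,
    "sbp_invasive": -0.8,
    "dbp_invasive": -0.5,
    "map_invasive": -0.7,
    "sbp_noninvasive": -0.8,
    "dbp_noninvasive": -0.5,
    "map_noninvasive": -0.7,
    "resp_rate": 0.4,
    "spo2": -0.3,
    "temperature": 0.1,
    "cvp": 0.6,
    "glucose": 0.2,
    "bun": 0.5,
    "creatinine": 0.4,
    "ast": 0.4,
    "alt": 0.2,
    "bilirubin_total": 0.2,
    "hemoglobin": -0.6,
    "hematocrit": -0.6,
    "platelets": -0.2,
    "wbc": 0.2,
    "sodium": 0.0,
    "potassium": 0.1,
    "ph": -0.3,
    "pao2": -0.2,
    "paco2": 0.1,
    "bicarbonate": -0.3,
    "lactate": 0.7,
    "fio2": 0.5,
    "peak_airway_pressure": 0.4,
    "mean_airway_pressure": 0.4,
    "peep": 0.2,
    "tidal_volume": -0.1,
}

#: probability a scheduled sample is dropped, per variable (category default
#: unless overridden; lactate matches the reported 22.1% missing rate)
DEFAULT_CATEGORY_MISSINGNESS = {
    "vital": 0.05,
    "lab": 0.15,
    "blood_gas": 0.15,
    "ventilation": 0.30,
}
DEFAULT_MISSINGNESS_OVERRIDES = {"lactate": 0.221}

#: hours between scheduled samples, per category
DEFAULT_SAMPLING_PERIOD_H = {
    "vital": 1.0,
    "blood_gas": 8.0,
    "ventilation": 4.0,
    "lab": 24.0,
}

#: per-patient baseline offset SD and per-observation (short-term
#: physiological + measurement) noise SD, in units of each variable's
#: reference SD; chosen with the severity correlation time so the feature
#: stream carries the latent separation and little beyond it
BASELINE_SD = 0.4
OBS_NOISE_SD = 0.8

ADMISSION_SOURCES = [
    ("cardiovascular_medical", 0.079),
    ("cardiovascular_surgical", 0.019),
    ("gastrointestinal_medical", 0.107),
    ("gastrointestinal_surgical", 0.197),
    ("metabolic_endocrine_medical", 0.050),
    ("neurologic_medical", 0.002),
    ("neurologic_surgical", 0.002),
    ("others_medical", 0.367),
    ("others_surgical", 0.137),
    ("respiratory_medical", 0.001),
    ("respiratory_surgical", 0.002),
    ("trauma_surgical", 0.037),
]

TRIGGER_KINDS = ("vasoactive", "fluid_volume", "prbc", "combo_transfusion")

#: raw vasoactive names as charted (mixed brand/generic, mixed case) to
#: exercise agent normalization downstream
RAW_VASOACTIVE_NAMES = [
    "Levophed",
    "Norepinephrine",
    "Epinephrine",
    "Dopamine",
    "Dobutamine",
    "Vasopressin",
    "Phenylephrine",
]


def _substream(seed: int, patient_id: str, salt: int = 0) -> np.random.Generator:
    """Per-patient RNG keyed by a stable hash of the patient id."""
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(patient_id.encode()), salt]
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the conditions the validation assumes: 19% intervention
    prevalence, a 24 h deterioration horizon, ICU length-of-stay medians of
    5 days (stable) and 12 days (unstable), and onset times at least 8 h
    after admission.
    """

    n_patients: int = 500
    prevalence: float = 0.19
    seed: int = 0
    latent_separation_d: float = 1.5
    deterioration_horizon_h: float = 24.0
    severity_corr_time_h: float = 36.0
    drift: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRIFT))
    missingness_rates: dict[str, float] | None = None
    sampling_period_h: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLING_PERIOD_H)
    )
    los_median_h: float = 120.0
    los_median_unstable_h: float = 288.0
    los_sigma: float = 0.7
    los_cap_h: float = 720.0
    onset_min_h: float = 8.0
    onset_gamma_shape: float = 2.0
    onset_gamma_scale_h: float = 14.0
    distractor_fluid_prob: float = 0.3

    def validate(self, registry: FeatureRegistry) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.prevalence < 1.0:
            raise ValueError("prevalence must lie in [0, 1)")
        if self.latent_separation_d < 0:
            raise ValueError("latent_separation_d must be >= 0")
        if self.deterioration_horizon_h < 1:
            raise ValueError("deterioration_horizon_h must be >= 1")
        if self.severity_corr_time_h <= 0:
            raise ValueError("severity_corr_time_h must be positive")
        if self.los_median_h <= 0 or self.los_median_unstable_h <= 0:
            raise ValueError("los_median_h must be positive")
        if self.los_cap_h <= self.onset_min_h:
            raise ValueError("los_cap_h must exceed onset_min_h")
        if self.onset_min_h <= 6.0:
            raise ValueError("onset_min_h must exceed 6 h (first-segment rule)")
        if self.onset_gamma_shape <= 0 or self.onset_gamma_scale_h <= 0:
            raise ValueError("onset_gamma_shape/scale must be positive")
        if not 0.0 <= self.distractor_fluid_prob <= 1.0:
            raise ValueError("distractor_fluid_prob must lie in [0, 1]")
        unknown = set(self.drift) - set(registry.variables)
        if unknown:
            raise ValueError(f"drift keys not in registry: {sorted(unknown)}")
        for period in self.sampling_period_h.values():
            if period <= 0:
                raise ValueError("sampling_period_h values must be positive")
        if self.missingness_rates is not None:
            for var, rate in self.missingness_rates.items():
                if var not in registry:
                    raise ValueError(f"missingness_rates key not in registry: {var}")
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(f"missingness_rates[{var}] must lie in [0, 1]")

    def resolved_missingness(self, registry: FeatureRegistry) -> dict[str, float]:
        if self.missingness_rates is not None:
            return dict(self.missingness_rates)
        rates = {
            v: DEFAULT_CATEGORY_MISSINGNESS[registry.row(v)["category"]]
            for v in registry.variables
        }
        rates.update(
            {v: r for v, r in DEFAULT_MISSINGNESS_OVERRIDES.items() if v in rates}
        )
        return rates


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated tables: patients, observations, interventions, ground truth."""

    patients: pd.DataFrame
    observations: pd.DataFrame
    interventions: pd.DataFrame
    ground_truth: pd.DataFrame


def theoretical_auroc(latent_separation_d: float) -> float:
    """AUROC of a score equal to the latent Gaussian signal: Phi(d / sqrt 2).

    Positives are N(d, 1) and negatives N(0, 1) on the latent scale, so the
    probability a random positive outscores a random negative is the normal
    CDF of ``d / sqrt(2)``.
    """
    if latent_separation_d < 0:
        raise ValueError("latent separation d must be >= 0")
    return float(norm.cdf(latent_separation_d / np.sqrt(2.0)))


def deterioration_ramp(
    t: np.ndarray, onset: float, horizon_h: float
) -> np.ndarray:
    """Linear ramp from 0 (horizon hours pre-onset) to 1 (one hour pre-onset).

    Clipped to [0, 1]; held at 1 from one hour before onset onward.
    """
    t_eff = np.minimum(np.asarray(t, dtype=float), onset)
    denom = max(horizon_h - 1.0, 1e-9)
    return np.clip((t_eff - (onset - horizon_h)) / denom, 0.0, 1.0)


def _severity_path(
    rng: np.random.Generator, los_h: float, corr_time_h: float
) -> tuple[np.ndarray, np.ndarray]:
    """Stationary unit-variance OU severity process on an hourly grid."""
    grid = np.arange(0.0, np.ceil(los_h) + 2.0)
    a = np.exp(-1.0 / corr_time_h)
    innov = rng.normal(0.0, 1.0, size=grid.size)
    z = np.empty(grid.size)
    z[0] = innov[0]
    sd_step = np.sqrt(1.0 - a * a)
    for i in range(1, grid.size):
        z[i] = a * z[i - 1] + sd_step * innov[i]
    return grid, z


def _draw_patient_row(rng: np.random.Generator, pid: str, unstable: bool) -> dict:
    age = float(np.clip(rng.normal(68.0, 15.0), 20.5, 99.0))
    gender = "M" if rng.random() < 0.65 else "F"
    admission_type = ["emergency", "not_emergency", "other"][
        rng.choice(3, p=[0.44, 0.46, 0.10])
    ]
    icu_type = "surgical" if rng.random() < 0.39 else "medical"
    sources, probs = zip(*ADMISSION_SOURCES)
    admission_source = sources[rng.choice(len(sources), p=probs)]
    apache2 = int(np.clip(round(rng.normal(25.0 if unstable else 21.0, 7.0)), 0, 71))
    mortality = int(rng.random() < (0.409 if unstable else 0.107))
    admit = EPOCH + pd.Timedelta(days=float(rng.uniform(0, ADMIT_SPAN_DAYS)))
    return {
        "patient_id": pid,
        "age": round(age, 1),
        "gender": gender,
        "admission_type": admission_type,
        "icu_type": icu_type,
        "admission_source": admission_source,
        "apache2": apache2,
        "admit_time": admit.isoformat(),
        "mortality": mortality,
    }


def _category_params(
    registry: FeatureRegistry, config: GeneratorConfig
) -> dict[str, tuple]:
    """Per-category column arrays (names, ref, sd, lo, hi, drift, period)."""
    out = {}
    indexed = registry.table.set_index("variable")
    for category in ("vital", "blood_gas", "ventilation", "lab"):
        names = registry.by_category(category)
        if not names:
            continue
        sub = indexed.loc[names]
        out[category] = (
            np.array(names, dtype=object),
            sub["ref_value"].to_numpy(float)[:, None],
            sub["ref_sd"].to_numpy(float)[:, None],
            sub["lo"].to_numpy(float)[:, None],
            sub["hi"].to_numpy(float)[:, None],
            np.array([config.drift.get(v, 0.0) for v in names])[:, None],
            config.sampling_period_h.get(category, DEFAULT_SAMPLING_PERIOD_H[category]),
        )
    return out


def _patient_observations(
    rng: np.random.Generator,
    pid: str,
    params: dict[str, tuple],
    config: GeneratorConfig,
    los_h: float,
    z_grid: np.ndarray,
    z_path: np.ndarray,
    onset: float | None,
) -> tuple[list, list, list, list]:
    """Clean (pre-missingness) observation arrays for one patient."""
    pids, times, variables, values = [], [], [], []
    d = config.latent_separation_d
    for category, (names, ref, sd, lo, hi, drift, period) in params.items():
        t = np.arange(0.0, los_h + 1e-9, period)
        if t.size == 0:
            continue
        latent = np.interp(t, z_grid, z_path)
        if onset is not None:
            latent = latent + d * deterioration_ramp(
                t, onset, config.deterioration_horizon_h
            )
        baseline = rng.normal(0.0, 1.0, size=(len(names), 1))
        noise = rng.normal(0.0, 1.0, size=(len(names), t.size))
        vals = ref + sd * (
            BASELINE_SD * baseline + drift * latent[None, :] + OBS_NOISE_SD * noise
        )
        vals = np.clip(vals, lo, hi)
        pids.append(np.full(vals.size, pid, dtype=object))
        times.append(np.tile(t, len(names)))
        variables.append(np.repeat(names, t.size))
        values.append(vals.ravel())
    return pids, times, variables, values


def _intervention_bundle(
    rng: np.random.Generator, pid: str, onset: float, kind: str
) -> list[dict]:
    """Explicit intervention records whose first qualifying crossing is at onset."""
    rec = lambda time, category, agent="", volume=0.0, dose=np.nan: {
        "patient_id": pid,
        "time": round(float(time), 3),
        "category": category,
        "agent": agent,
        "volume_cc": float(volume),
        "dose": dose,
    }
    if kind == "vasoactive":
        agent = RAW_VASOACTIVE_NAMES[rng.integers(len(RAW_VASOACTIVE_NAMES))]
        return [rec(onset, "vasoactive", agent, 0.0, round(rng.uniform(2, 10), 2))]
    if kind == "fluid_volume":
        cat = "fluid_crystalloid" if rng.random() < 0.8 else "fluid_colloid"
        return [rec(onset - dt, cat, volume=800.0) for dt in (4.0, 2.0, 0.0)]
    if kind == "prbc":
        # 1600 cc in 24 h: strictly exceeds the 1500 cc transfusion threshold
        return [rec(onset - 6.0, "prbc", volume=800.0), rec(onset, "prbc", volume=800.0)]
    if kind == "combo_transfusion":
        return [
            rec(onset - 4.0, "prbc", volume=500.0),
            rec(onset - 2.0, "ffp", volume=500.0),
            rec(onset, "platelet_pheresis", volume=500.0),
        ]
    raise ValueError(f"unknown trigger kind: {kind}")


def _distractor_fluids(
    rng: np.random.Generator, pid: str, los_h: float
) -> list[dict]:
    """Sub-threshold fluid boluses (500 cc, >= 10 h apart) that must not
    trigger any volume criterion."""
    n = int(rng.integers(1, 4))
    raw = np.sort(rng.uniform(0.0, max(los_h, 1.0), size=n))
    kept: list[float] = []
    for t in raw:
        if not kept or t - kept[-1] >= 10.0:
            kept.append(float(t))
    return [
        {
            "patient_id": pid,
            "time": round(t, 3),
            "category": "fluid_crystalloid",
            "agent": "",
            "volume_cc": 500.0,
            "dose": np.nan,
        }
        for t in kept
    ]


def generate_cohort(
    config: GeneratorConfig, registry: FeatureRegistry | None = None
) -> SyntheticCohort:
    """Generate a full synthetic cohort. Deterministic given config and seed."""
    registry = registry or default_registry()
    config.validate(registry)

    width = max(4, len(str(config.n_patients - 1)))
    params = _category_params(registry, config)
    patient_rows: list[dict] = []
    gt_rows: list[dict] = []
    obs_parts: list[tuple] = []
    interv_rows: list[dict] = []

    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        rng = _substream(config.seed, pid)
        unstable = bool(rng.random() < config.prevalence)
        los_median = (
            config.los_median_unstable_h if unstable else config.los_median_h
        )
        los = float(
            np.clip(
                rng.lognormal(np.log(los_median), config.los_sigma),
                7.0,
                config.los_cap_h,
            )
        )
        onset = None
        trigger_kind = ""
        if unstable:
            onset = config.onset_min_h + float(
                rng.gamma(config.onset_gamma_shape, config.onset_gamma_scale_h)
            )
            onset = round(min(onset, config.los_cap_h - 12.0), 3)
            los = max(los, onset + 12.0)
            trigger_kind = TRIGGER_KINDS[int(rng.integers(len(TRIGGER_KINDS)))]
            interv_rows.extend(_intervention_bundle(rng, pid, onset, trigger_kind))
        elif rng.random() < config.distractor_fluid_prob:
            interv_rows.extend(_distractor_fluids(rng, pid, los))

        row = _draw_patient_row(rng, pid, unstable)
        admit = pd.Timestamp(row["admit_time"])
        row["discharge_time"] = (admit + pd.Timedelta(hours=los)).isoformat()
        patient_rows.append(row)
        z_grid, z_path = _severity_path(rng, los, config.severity_corr_time_h)
        # latent_z is the severity at the patient's reference point: one hour
        # pre-onset (unstable) or the 5-h stable sampling time
        ref_point = (onset - 1.0) if onset is not None else 5.0
        gt_rows.append(
            {
                "patient_id": pid,
                "group": "unstable" if unstable else "stable",
                "onset_time": onset if onset is not None else np.nan,
                "latent_z": round(float(np.interp(ref_point, z_grid, z_path)), 6),
                "trigger_kind": trigger_kind,
            }
        )
        obs_parts.append(
            _patient_observations(rng, pid, params, config, los, z_grid, z_path, onset)
        )

    patients = pd.DataFrame(patient_rows)[
        [
            "patient_id",
            "age",
            "gender",
            "admission_type",
            "icu_type",
            "admission_source",
            "apache2",
            "admit_time",
            "discharge_time",
            "mortality",
        ]
    ]
    ground_truth = pd.DataFrame(gt_rows)

    pid_arrs = [a for part in obs_parts for a in part[0]]
    observations = pd.DataFrame(
        {
            "patient_id": np.concatenate(pid_arrs) if pid_arrs else np.array([]),
            "time": np.concatenate([a for p in obs_parts for a in p[1]] or [[]]),
            "variable": np.concatenate([a for p in obs_parts for a in p[2]] or [[]]),
            "value": np.concatenate([a for p in obs_parts for a in p[3]] or [[]]),
        }
    )
    cat_of = dict(zip(registry.table["variable"], registry.table["category"]))
    observations["source"] = observations["variable"].map(cat_of)
    observations["value"] = observations["value"].round(4)

    miss_seed = (config.seed ^ 0x5EED5EED) & 0x7FFFFFFF
    observations = apply_missingness(
        observations, config.resolved_missingness(registry), miss_seed, registry
    )

    interventions = pd.DataFrame(
        interv_rows,
        columns=["patient_id", "time", "category", "agent", "volume_cc", "dose"],
    )
    return SyntheticCohort(patients, observations, interventions, ground_truth)


def apply_missingness(
    observations: pd.DataFrame,
    rates: dict[str, float],
    seed: int,
    registry: FeatureRegistry | None = None,
) -> pd.DataFrame:
    """Independently drop each scheduled sample with its variable's rate.

    Uses per-patient RNG substreams so subsetting patients leaves other
    patients' retained rows unchanged. Observed values are never altered.
    """
    registry = registry or default_registry()
    unknown = set(rates) - set(registry.variables)
    if unknown:
        raise ValueError(f"missingness rates for unknown variables: {sorted(unknown)}")
    if observations.empty:
        return observations.reset_index(drop=True)
    rate_per_row = (
        observations["variable"].map(rates).fillna(0.0).to_numpy(float)
    )
    keep = np.ones(len(observations), dtype=bool)
    groups = observations.groupby("patient_id", sort=True, observed=True).indices
    for pid in sorted(groups):
        sel = groups[pid]
        rng = _substream(seed, str(pid), salt=1)
        keep[sel] = rng.random(sel.size) >= rate_per_row[sel]
    return observations.loc[keep].reset_index(drop=True)


def make_config(**overrides) -> GeneratorConfig:
    """Convenience constructor applying overrides to the default conditions."""
    return replace(GeneratorConfig(), **overrides)
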