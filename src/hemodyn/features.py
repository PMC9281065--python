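"""Feature extraction: plausibility filtering, hourly sampling, imputation.

The processing order is fixed: plausibility filter first (out-of-range
values become missing), then last-observation-carried-forward with a
per-variable staleness limit, then fallback imputation (noninvasive blood
pressures fill the invasive columns; missing FiO2 becomes room air, 0.21;
everything else stays missing). Imputation never overwrites an observed
value, and no value in a sample row may come from an observation after the
row's reference time.

Unstable patients contribute one row per integer lead hour (1..horizon)
before their intervention onset, truncated at admission; stable patients
contribute a single row at the end of a 5-hour post-admission observation
window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import NIBP_PAIRS, ROOM_AIR_FIO2, FeatureRegistry

logger = logging.getLogger(__name__)

#: non-feature columns of a sample matrix frame, in order
SAMPLE_META_COLUMNS = ["patient_id", "reference_time", "lead_hours", "label"]


def apply_plausibility_filter(
    observations: pd.DataFrame, registry: FeatureRegistry
) -> pd.DataFrame:
    """Replace values outside the registry's [lo, hi] range with missing.

    In-range values pass through unchanged; variables unknown to the
    registry pass through untouched (with a logged warning). Idempotent.
    """
    out = observations.copy()
    lo = out["variable"].map(dict(zip(registry.table["variable"], registry.table["lo"])))
    hi = out["variable"].map(dict(zip(registry.table["variable"], registry.table["hi"])))
    unknown = lo.isna() & out["variable"].notna()
    if unknown.any():
        names = sorted(out.loc[unknown, "variable"].astype(str).unique())
        logger.warning("variables not in registry pass through unfiltered: %s", names)
    out_of_range = lo.notna() & (
        (out["value"] < lo.astype(float)) | (out["value"] > hi.astype(float))
    )
    out.loc[out_of_range, "value"] = np.nan
    return out


def _locf_extract(
    observations: pd.DataFrame,
    refs: pd.DataFrame,
    registry: FeatureRegistry,
) -> pd.DataFrame:
    """Latest in-staleness observation per (reference row, variable).

    ``refs`` must have columns patient_id and reference_time. Rows whose
    latest observation is older than the variable's staleness limit are
    missing. Ties at one timestamp resolve to the last-written record.
    """
    refs = refs.reset_index(drop=True)
    refs["_row"] = np.arange(len(refs))
    refs_sorted = refs.sort_values("reference_time", kind="stable")
    obs = observations.dropna(subset=["value"])
    out = pd.DataFrame(index=refs["_row"], columns=registry.variables, dtype=float)
    by_var = dict(tuple(obs.groupby("variable", observed=True))) if len(obs) else {}
    for variable in registry.variables:
        sub = by_var.get(variable)
        if sub is None or sub.empty:
            continue
        sub = sub.sort_values("time", kind="stable")  # stable: last-written wins ties
        merged = pd.merge_asof(
            refs_sorted,
            sub[["patient_id", "time", "value"]],
            left_on="reference_time",
            right_on="time",
            by="patient_id",
            direction="backward",
            tolerance=registry.staleness(variable),
        )
        out.loc[merged["_row"].to_numpy(), variable] = merged["value"].to_numpy()
    out.index = pd.RangeIndex(len(out))
    return out


def sample_at(
    patient_observations: pd.DataFrame,
    reference_time: float,
    registry: FeatureRegistry,
) -> pd.Series:
    """One sample row: per variable, the latest observation at or before the
    reference time whose age is within the staleness limit; else missing."""
    if reference_time < 0:
        raise ValueError("reference_time must be >= 0")
    pid = (
        str(patient_observations["patient_id"].iloc[0])
        if len(patient_observations)
        else "_"
    )
    refs = pd.DataFrame({"patient_id": [pid], "reference_time": [float(reference_time)]})
    row = _locf_extract(patient_observations, refs, registry).iloc[0]
    row.name = None
    return row


def impute_features(
    values: pd.Series | pd.DataFrame, registry: FeatureRegistry
) -> pd.Series | pd.DataFrame:
    """Fallback imputation after carry-forward.

    Missing invasive SBP/DBP/MAP are filled from the same-row noninvasive
    counterpart; missing FiO2 becomes room air (0.21); all other missing
    values remain missing. Observed values are never overwritten.
    """
    single = isinstance(values, pd.Series)
    frame = values.to_frame().T.copy() if single else values.copy()
    for row_ in registry.table.itertuples():
        if row_.fallback == "nibp_to_ibp":
            src = NIBP_PAIRS.get(row_.variable)
            if src and src in frame.columns and row_.variable in frame.columns:
                need = frame[row_.variable].isna()
                frame.loc[need, row_.variable] = frame.loc[need, src]
        elif row_.fallback == "fio2_room_air" and row_.variable in frame.columns:
            frame[row_.variable] = frame[row_.variable].fillna(ROOM_AIR_FIO2)
    return frame.iloc[0] if single else frame


def compute_shock_index(values: pd.Series | pd.DataFrame) -> float | pd.Series:
    """Shock index = heart rate / systolic blood pressure (post-imputation
    invasive SBP). Missing if either input is missing."""
    hr = values["heart_rate"]
    sbp = values["sbp_invasive"]
    return hr / sbp


@dataclass(frozen=True)
class SampleMatrix:
    """Lead-time-indexed feature samples plus provenance.

    ``frame`` holds :data:`SAMPLE_META_COLUMNS` followed by one column per
    registry variable. ``lead_hours`` is >= 1 for unstable rows (hours
    before onset) and 0 for stable rows.
    """

    frame: pd.DataFrame
    registry: FeatureRegistry = field(repr=False)
    provenance: dict = field(default_factory=dict)

    @property
    def feature_columns(self) -> list[str]:
        return self.registry.variables

    def features(self) -> pd.DataFrame:
        return self.frame[self.feature_columns]

    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy(int)


def build_sample_matrix(
    labels: pd.DataFrame,
    observations: pd.DataFrame,
    registry: FeatureRegistry,
    horizon_h: int = 24,
    stable_window_h: float = 5.0,
    stable_hourly: bool = False,
    prefiltered: bool = False,
) -> SampleMatrix:
    """Extract the validation sample matrix from labeled patients.

    Unstable patients get one row per integer lead ``t = 1..horizon_h`` at
    reference time ``onset - t`` while that is >= 0 (label 1). Stable
    patients get one row at ``stable_window_h`` after admission (label 0,
    lead 0) — or, with ``stable_hourly``, one row per hour of the first
    ``horizon_h`` hours for false-alarm analyses. Observations are
    plausibility-filtered, carried forward, then imputed.
    """
    if horizon_h < 1:
        raise ValueError("horizon_h must be >= 1")
    obs = observations if prefiltered else apply_plausibility_filter(observations, registry)

    ref_rows: list[pd.DataFrame] = []
    unstable = labels[labels["group"] == "unstable"]
    if unstable["onset_time"].isna().any():
        bad = unstable.loc[unstable["onset_time"].isna(), "patient_id"].tolist()
        raise ValueError(f"unstable patients lacking onset_time: {bad}")
    if len(unstable):
        leads = np.arange(1, horizon_h + 1)
        grid = unstable.loc[:, ["patient_id", "onset_time"]].merge(
            pd.DataFrame({"lead_hours": leads}), how="cross"
        )
        grid["reference_time"] = grid["onset_time"] - grid["lead_hours"]
        grid = grid[grid["reference_time"] >= 0]
        grid["label"] = 1
        ref_rows.append(grid[["patient_id", "reference_time", "lead_hours", "label"]])

    stable = labels[labels["group"] == "stable"]
    if len(stable):
        if stable_hourly:
            hours = np.arange(1, horizon_h + 1, dtype=float)
            sgrid = stable.loc[:, ["patient_id"]].merge(
                pd.DataFrame({"reference_time": hours}), how="cross"
            )
        else:
            sgrid = pd.DataFrame(
                {
                    "patient_id": stable["patient_id"].to_numpy(),
                    "reference_time": float(stable_window_h),
                }
            )
        sgrid["lead_hours"] = 0
        sgrid["label"] = 0
        ref_rows.append(sgrid[["patient_id", "reference_time", "lead_hours", "label"]])

    refs = (
        pd.concat(ref_rows, ignore_index=True)
        if ref_rows
        else pd.DataFrame(columns=SAMPLE_META_COLUMNS)
    )
    refs = refs.sort_values(
        ["patient_id", "reference_time"], kind="stable"
    ).reset_index(drop=True)

    feats = _locf_extract(obs, refs[["patient_id", "reference_time"]], registry)
    feats = impute_features(feats, registry)
    frame = pd.concat([refs.reset_index(drop=True), feats], axis=1)
    return SampleMatrix(
        frame=frame,
        registry=registry,
        provenance={
            "horizon_h": horizon_h,
            "stable_window_h": stable_window_h,
            "stable_hourly": stable_hourly,
            "registry_hash": registry.content_hash(),
        },
    )
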