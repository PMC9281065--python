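"""Rule-based annotation of hemodynamic instability from intervention logs.

Instability is operationalized as receipt of a qualifying hemodynamic
intervention: any dose of an inotrope/vasopressor, large-volume fluid
therapy, or a transfusion bundle meeting a cumulative dose/time criterion.
Two built-in rule sets are provided:

``TPEVGH``
    * any administration of dobutamine, dopamine, epinephrine,
      norepinephrine (Levophed), phenylephrine, or vasopressin;
    * fluid therapy (crystalloid or colloid) >= 2400 cc in 8 h, or
      >= 3000 cc in 12 h;
    * 25% albumin >= 200 cc in 2 h;
    * packed red blood cells (PRBC) strictly > 1500 cc in 24 h;
    * PRBC 500 cc + FFP 500 cc + platelet pheresis 500 cc within 6 h.

``US``
    * the same vasoactive list (plus the Neosynephrine brand name);
    * the same two fluid-volume criteria;
    * PRBC >= 800 cc over 24 h;
    * PRBC >= 500 cc in 2 h followed by fluid therapy within 12 h.

Volume criteria use a half-open look-back window ``(t - W, t]`` with each
record's volume attributed wholly at its charted time; crossings are
evaluated at event times. After a crossing, detection re-arms only once the
running window total falls back below the threshold (the total changes only
at record entries and window exits, and both are checked), so one sustained
episode yields one onset.

Onsets are merged into unstable segments; a patient's validation segment is
the first segment beginning more than 6 h after ICU admission. Patients
whose only segments begin within the first 6 h are excluded (they received
interventions, so labeling them stable would contaminate the negative
class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

UNRECOGNIZED = "unrecognized"

FLUID_CATEGORIES = ("fluid_crystalloid", "fluid_colloid")

VALID_CATEGORIES = {
    "vasoactive",
    "fluid_crystalloid",
    "fluid_colloid",
    "albumin25",
    "prbc",
    "ffp",
    "platelet_pheresis",
}

EXCLUSION_REASONS = ("age", "los_lt_6h", "incomplete_profile", "only_early_segments")

#: absolute tolerance (cc) for cumulative-volume comparisons
_VOL_TOL = 1e-6


class InterventionRecord(NamedTuple):
    """One timed administration driving annotation."""

    patient_id: str
    time: float
    category: str
    agent: str = ""
    volume_cc: float = 0.0
    dose: float = float("nan")


def records_to_frame(records: Iterable[InterventionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        list(records),
        columns=["patient_id", "time", "category", "agent", "volume_cc", "dose"],
    )


# ---------------------------------------------------------------------------
# agent normalization (dictionary is data, not code)
# ---------------------------------------------------------------------------

_AGENT_DICT: dict[str, str] | None = None


def load_agent_dictionary(path: str | Path | None = None) -> dict[str, str]:
    """Load the raw-name -> canonical-agent mapping (case-insensitive keys)."""
    if path is None:
        with resources.files("hemodyn.data").joinpath("agent_dictionary.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    return {
        str(r.raw_name).strip().lower(): str(r.canonical).strip().lower()
        for r in table.itertuples()
    }


def normalize_agent(raw_name: str, dictionary: dict[str, str] | None = None) -> str:
    """Map brand and generic vasoactive names to one canonical id.

    Unknown names map to the sentinel ``"unrecognized"`` and never trigger
    criteria.
    """
    global _AGENT_DICT
    if dictionary is None:
        if _AGENT_DICT is None:
            _AGENT_DICT = load_agent_dictionary()
        dictionary = _AGENT_DICT
    key = str(raw_name).strip().lower()
    if not key:
        return UNRECOGNIZED
    return dictionary.get(key, UNRECOGNIZED)


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CriterionSpec:
    """One annotation criterion.

    ``kind`` is one of:

    * ``any_administration`` — any positive dose of an eligible agent;
    * ``volume_window`` — cumulative eligible volume over ``(t - window_h, t]``
      satisfying ``comparator`` vs ``threshold_cc``;
    * ``combo_window`` — every ``components`` (category, min volume) pair met
      within one window;
    * ``volume_then_fluid`` — a volume-window crossing followed by any
      fluid-therapy onset within ``followup_window_h``.
    """

    id: str
    kind: str
    categories: tuple[str, ...] = ()
    agents: tuple[str, ...] = ()
    threshold_cc: float = 0.0
    window_h: float = 0.0
    comparator: str = "ge"  # 'ge' or 'gt'
    components: tuple[tuple[str, float], ...] = ()
    followup_window_h: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in {
            "any_administration",
            "volume_window",
            "combo_window",
            "volume_then_fluid",
        }:
            raise ValueError(f"unknown criterion kind: {self.kind}")
        if self.kind in {"volume_window", "volume_then_fluid"}:
            if self.window_h <= 0:
                raise ValueError(f"{self.id}: window_h must be positive")
            if self.threshold_cc <= 0:
                raise ValueError(f"{self.id}: threshold_cc must be positive")
        if self.kind == "combo_window":
            if self.window_h <= 0:
                raise ValueError(f"{self.id}: window_h must be positive")
            if not self.components:
                raise ValueError(f"{self.id}: combo criterion needs components")
        if self.comparator not in {"ge", "gt"}:
            raise ValueError(f"{self.id}: comparator must be 'ge' or 'gt'")


@dataclass(frozen=True)
class RuleSet:
    name: str
    criteria: tuple[CriterionSpec, ...]

    def fluid_specs(self) -> list[CriterionSpec]:
        return [
            c
            for c in self.criteria
            if c.kind == "volume_window"
            and set(c.categories) & set(FLUID_CATEGORIES + ("albumin25",))
        ]


_VASOACTIVE_AGENTS = (
    "dobutamine",
    "dopamine",
    "epinephrine",
    "norepinephrine",
    "phenylephrine",
    "vasopressin",
)

TPEVGH_RULESET = RuleSet(
    name="TPEVGH",
    criteria=(
        CriterionSpec("vaso_any", "any_administration", ("vasoactive",), _VASOACTIVE_AGENTS),
        CriterionSpec("fluid_2400_8", "volume_window", FLUID_CATEGORIES,
                      threshold_cc=2400, window_h=8, comparator="ge"),
        CriterionSpec("fluid_3000_12", "volume_window", FLUID_CATEGORIES,
                      threshold_cc=3000, window_h=12, comparator="ge"),
        CriterionSpec("albumin25_200_2", "volume_window", ("albumin25",),
                      threshold_cc=200, window_h=2, comparator="ge"),
        CriterionSpec("prbc_1500_24", "volume_window", ("prbc",),
                      threshold_cc=1500, window_h=24, comparator="gt"),
        CriterionSpec("combo_transfusion_6", "combo_window", window_h=6,
                      components=(("prbc", 500.0), ("ffp", 500.0),
                                  ("platelet_pheresis", 500.0))),
    ),
)

US_RULESET = RuleSet(
    name="US",
    criteria=(
        CriterionSpec("vaso_any", "any_administration", ("vasoactive",), _VASOACTIVE_AGENTS),
        CriterionSpec("fluid_2400_8", "volume_window", FLUID_CATEGORIES,
                      threshold_cc=2400, window_h=8, comparator="ge"),
        CriterionSpec("fluid_3000_12", "volume_window", FLUID_CATEGORIES,
                      threshold_cc=3000, window_h=12, comparator="ge"),
        CriterionSpec("prbc_800_24", "volume_window", ("prbc",),
                      threshold_cc=800, window_h=24, comparator="ge"),
        CriterionSpec("prbc500_then_fluid", "volume_then_fluid", ("prbc",),
                      threshold_cc=500, window_h=2, comparator="ge",
                      followup_window_h=12),
    ),
)

RULESETS = {"TPEVGH": TPEVGH_RULESET, "US": US_RULESET}


# ---------------------------------------------------------------------------
# onset detection
# ---------------------------------------------------------------------------


def _validate_events(events: pd.DataFrame) -> pd.DataFrame:
    if events.empty:
        return events
    if (events["time"] < 0).any():
        raise ValueError("intervention records with negative time")
    if (events["volume_cc"].fillna(0) < 0).any():
        raise ValueError("intervention records with negative volume_cc")
    return events


def _eligible_volume_events(
    events: pd.DataFrame, categories: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Sorted distinct times and per-time summed volumes for eligible rows."""
    sub = events[events["category"].isin(categories)]
    if sub.empty:
        return np.array([]), np.array([])
    agg = sub.groupby("time", sort=True)["volume_cc"].sum()
    return agg.index.to_numpy(float), agg.to_numpy(float)


def _totals_at(
    at: np.ndarray, times: np.ndarray, volumes: np.ndarray, window_h: float
) -> np.ndarray:
    """Cumulative volume over (t - W, t] for each time in ``at``.

    ``times`` must be sorted distinct event times with summed ``volumes``.
    """
    cum = np.cumsum(volumes)
    hi = np.searchsorted(times, at, side="right")
    lo = np.searchsorted(times, at - window_h, side="right")
    upper = np.where(hi > 0, cum[np.maximum(hi - 1, 0)], 0.0)
    lower = np.where(lo > 0, cum[np.maximum(lo - 1, 0)], 0.0)
    return upper - lower


def _candidate_times(times: np.ndarray, window_h: float) -> tuple[np.ndarray, np.ndarray]:
    """Event entry times plus window-exit times (where the running total can
    fall and re-arm detection); returns (candidates, is_entry mask)."""
    cand = np.unique(np.concatenate([times, times + window_h]))
    is_entry = np.isin(cand, times)
    return cand, is_entry


def _rearm_scan(
    candidate_times: np.ndarray, qualifies: np.ndarray, is_entry: np.ndarray
) -> list[float]:
    """One onset per sustained qualifying episode.

    The running window total is piecewise constant, changing only at event
    entries and exits; an onset fires at a qualifying entry while armed, and
    detection re-arms whenever the total falls below threshold at any
    candidate time.
    """
    onsets: list[float] = []
    armed = True
    for t, q, entry in zip(candidate_times, qualifies, is_entry):
        if q and entry and armed:
            onsets.append(float(t))
            armed = False
        elif not q:
            armed = True
    return onsets


def detect_any_administration_onsets(
    events: pd.DataFrame, spec: CriterionSpec
) -> list[float]:
    """Every eligible-agent administration with dose > 0 is an onset."""
    events = _validate_events(events)
    if events.empty:
        return []
    sub = events[events["category"].isin(spec.categories)].copy()
    if sub.empty:
        return []
    canon = sub["agent"].map(normalize_agent)
    dose = sub["dose"].fillna(0.0)
    hit = sub[(canon.isin(spec.agents)) & (dose > 0)]
    return sorted(float(t) for t in hit["time"])


def detect_volume_window_onsets(
    events: pd.DataFrame, spec: CriterionSpec
) -> list[float]:
    """First-crossing onsets of a cumulative-volume window criterion."""
    events = _validate_events(events)
    times, volumes = _eligible_volume_events(events, spec.categories)
    if times.size == 0:
        return []
    cand, is_entry = _candidate_times(times, spec.window_h)
    totals = _totals_at(cand, times, volumes, spec.window_h)
    # volume tolerance absorbs float cancellation in the running sums
    if spec.comparator == "ge":
        qualifies = totals >= spec.threshold_cc - _VOL_TOL
    else:
        qualifies = totals > spec.threshold_cc + _VOL_TOL
    return _rearm_scan(cand, qualifies, is_entry)


def detect_combo_window_onsets(
    events: pd.DataFrame,
    spec: CriterionSpec,
    fluid_specs: Sequence[CriterionSpec] | None = None,
) -> list[float]:
    """Multi-component window criteria, and the PRBC-then-fluid rule.

    ``combo_window``: onset at the earliest time t such that within
    ``(t - window_h, t]`` every component's cumulative volume meets its
    minimum, with episode re-arming as for volume windows.

    ``volume_then_fluid``: a base volume-window crossing at t0 qualifies if
    any fluid-therapy onset (per ``fluid_specs``) lands in
    ``(t0, t0 + followup_window_h]``; the onset is reported at t0.
    """
    events = _validate_events(events)
    if spec.kind == "volume_then_fluid":
        base = detect_volume_window_onsets(events, spec)
        if not base:
            return []
        if fluid_specs is None:
            raise ValueError(f"{spec.id}: fluid_specs required for volume_then_fluid")
        fluid_onsets = sorted(
            t for fs in fluid_specs for t in detect_volume_window_onsets(events, fs)
        )
        out = []
        for t0 in base:
            if any(t0 < f <= t0 + spec.followup_window_h for f in fluid_onsets):
                out.append(t0)
        return out

    component_cats = [c for c, _ in spec.components]
    entry_times = np.unique(
        events.loc[events["category"].isin(component_cats), "time"].to_numpy(float)
    )
    if entry_times.size == 0:
        return []
    cand, is_entry = _candidate_times(entry_times, spec.window_h)
    qualifies = np.ones(cand.size, dtype=bool)
    for category, min_cc in spec.components:
        times, volumes = _eligible_volume_events(events, [category])
        if times.size == 0:
            return []
        qualifies &= _totals_at(cand, times, volumes, spec.window_h) >= min_cc - _VOL_TOL
    return _rearm_scan(cand, qualifies, is_entry)


def detect_onsets(
    events: pd.DataFrame, ruleset: RuleSet
) -> list[tuple[float, str]]:
    """All (onset time, criterion id) pairs for one patient's log."""
    pairs: list[tuple[float, str]] = []
    fluid_specs = ruleset.fluid_specs()
    for spec in ruleset.criteria:
        if spec.kind == "any_administration":
            onsets = detect_any_administration_onsets(events, spec)
        elif spec.kind == "volume_window":
            onsets = detect_volume_window_onsets(events, spec)
        else:
            onsets = detect_combo_window_onsets(events, spec, fluid_specs)
        pairs.extend((t, spec.id) for t in onsets)
    return sorted(pairs)


# ---------------------------------------------------------------------------
# segments and cohort labels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UnstableSegment:
    patient_id: str
    onset_time: float
    end_time: float
    triggering_criteria: frozenset[str] = field(default_factory=frozenset)


def build_segments(
    onsets: Sequence[tuple[float, str]] | Sequence[float],
    merge_gap_h: float = 1.0,
    patient_id: str = "",
) -> list[UnstableSegment]:
    """Group onsets separated by <= merge_gap_h into disjoint segments.

    Segment onset is the first onset of a run; the end is the last onset of
    the run plus the merge gap.
    """
    if merge_gap_h <= 0:
        raise ValueError("merge_gap_h must be positive")
    if not len(onsets):
        return []
    pairs = [
        (float(o), "") if np.isscalar(o) else (float(o[0]), str(o[1]))
        for o in onsets
    ]
    pairs.sort()
    segments: list[UnstableSegment] = []
    run_start = pairs[0][0]
    run_last = pairs[0][0]
    run_crit = {pairs[0][1]} - {""}
    for t, crit in pairs[1:]:
        if t - run_last <= merge_gap_h:
            run_last = t
            run_crit |= {crit} - {""}
        else:
            segments.append(
                UnstableSegment(patient_id, run_start, run_last + merge_gap_h,
                                frozenset(run_crit))
            )
            run_start, run_last, run_crit = t, t, {crit} - {""}
    segments.append(
        UnstableSegment(patient_id, run_start, run_last + merge_gap_h,
                        frozenset(run_crit))
    )
    return segments


def annotate_interventions(
    interventions: pd.DataFrame,
    ruleset: RuleSet | str = "TPEVGH",
    merge_gap_h: float = 1.0,
) -> pd.DataFrame:
    """Detect onsets and build segments for every patient in a log.

    Returns a segments table (patient_id, onset_time, end_time, criteria)
    where ``criteria`` is a ';'-joined sorted list of criterion ids.
    Deterministic and invariant to input record order.
    """
    if isinstance(ruleset, str):
        ruleset = RULESETS[ruleset]
    rows = []
    if not interventions.empty:
        for pid, events in interventions.groupby("patient_id", sort=True):
            pairs = detect_onsets(events, ruleset)
            for seg in build_segments(pairs, merge_gap_h, patient_id=str(pid)):
                rows.append(
                    {
                        "patient_id": seg.patient_id,
                        "onset_time": seg.onset_time,
                        "end_time": seg.end_time,
                        "criteria": ";".join(sorted(seg.triggering_criteria)),
                    }
                )
    return pd.DataFrame(
        rows, columns=["patient_id", "onset_time", "end_time", "criteria"]
    )


def label_cohort(
    patients: pd.DataFrame,
    segments: pd.DataFrame,
    min_onset_h: float = 6.0,
) -> pd.DataFrame:
    """Partition included patients into stable / unstable / excluded.

    Segments with onset <= ``min_onset_h`` are discarded; the validation
    segment is the first surviving segment. Patients with discarded segments
    but no surviving one are excluded (reason ``only_early_segments``).

    Returns a labels table: patient_id, group, onset_time, end_time,
    criteria, exclusion_reason.
    """
    seg_by_pid: dict[str, pd.DataFrame] = (
        {str(p): g.sort_values("onset_time") for p, g in segments.groupby("patient_id")}
        if not segments.empty
        else {}
    )
    rows = []
    for pid in patients["patient_id"].astype(str):
        segs = seg_by_pid.get(pid)
        row = {
            "patient_id": pid,
            "group": "stable",
            "onset_time": np.nan,
            "end_time": np.nan,
            "criteria": "",
            "exclusion_reason": "",
        }
        if segs is not None and len(segs):
            surviving = segs[segs["onset_time"] > min_onset_h]
            if len(surviving):
                first = surviving.iloc[0]
                row.update(
                    group="unstable",
                    onset_time=float(first["onset_time"]),
                    end_time=float(first["end_time"]),
                    criteria=str(first["criteria"]),
                )
            else:
                row.update(group="excluded", exclusion_reason="only_early_segments")
        rows.append(row)
    return pd.DataFrame(rows)


def apply_inclusion_filters(
    patients: pd.DataFrame, observations: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop patients aged <= 20 y, ICU stays < 6 h, and empty data profiles.

    Age 20 exactly is excluded (inclusion is strictly greater than 20
    years). Returns the included patients and a per-reason exclusion count.
    """
    admit = pd.to_datetime(patients["admit_time"])
    discharge = pd.to_datetime(patients["discharge_time"])
    if (discharge < admit).any():
        bad = patients.loc[discharge < admit, "patient_id"].tolist()
        raise ValueError(f"discharge before admission for patients: {bad}")
    los_h = (discharge - admit).dt.total_seconds() / 3600.0

    has_obs = set(observations["patient_id"].astype(str)) if len(observations) else set()
    age_ok = patients["age"] > 20.0
    los_ok = los_h >= 6.0
    obs_ok = patients["patient_id"].astype(str).isin(has_obs)

    report = {
        "age": int((~age_ok).sum()),
        "los_lt_6h": int((age_ok & ~los_ok).sum()),
        "incomplete_profile": int((age_ok & los_ok & ~obs_ok).sum()),
    }
    included = patients[age_ok & los_ok & obs_ok].reset_index(drop=True)
    report["included"] = len(included)
    return included, report
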