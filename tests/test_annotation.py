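"""Intervention-rule engine: agent normalization, window criteria, segments,
cohort partition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemodyn as h
from hemodyn.annotation import (
    TPEVGH_RULESET,
    US_RULESET,
    CriterionSpec,
    detect_onsets,
)

from _oracles import brute_force_volume_onsets
from conftest import make_interventions

FLUID_2400_8 = next(c for c in TPEVGH_RULESET.criteria if c.id == "fluid_2400_8")
ALBUMIN = next(c for c in TPEVGH_RULESET.criteria if c.id == "albumin25_200_2")
PRBC_GT_1500 = next(c for c in TPEVGH_RULESET.criteria if c.id == "prbc_1500_24")
COMBO = next(c for c in TPEVGH_RULESET.criteria if c.id == "combo_transfusion_6")
VASO = next(c for c in TPEVGH_RULESET.criteria if c.id == "vaso_any")
PRBC_THEN_FLUID = next(
    c for c in US_RULESET.criteria if c.id == "prbc500_then_fluid"
)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Levophed", "norepinephrine"),
        ("Neosynephrine", "phenylephrine"),
        ("DOBUTamine", "dobutamine"),
        ("  vasopressin ", "vasopressin"),
        ("midodrine", "unrecognized"),
        ("", "unrecognized"),
    ],
)
def test_normalize_agent(raw, expected):
    assert h.normalize_agent(raw) == expected


class TestAnyAdministration:
    def test_single_dose_is_onset(self):
        ev = make_interventions([(10.0, "vasoactive", "Norepinephrine", 0.0, 4.0)])
        assert h.detect_any_administration_onsets(ev, VASO) == [10.0]

    def test_empty_log(self):
        ev = make_interventions([])
        assert h.detect_any_administration_onsets(ev, VASO) == []

    def test_each_dose_qualifies_independently(self):
        ev = make_interventions(
            [(t, "vasoactive", "Levophed", 0.0, 2.0) for t in (10.0, 10.5, 30.0)]
        )
        assert h.detect_any_administration_onsets(ev, VASO) == [10.0, 10.5, 30.0]

    def test_unrecognized_agent_and_zero_dose_never_trigger(self):
        ev = make_interventions(
            [
                (5.0, "vasoactive", "midodrine", 0.0, 10.0),
                (6.0, "vasoactive", "Dopamine", 0.0, 0.0),
            ]
        )
        assert h.detect_any_administration_onsets(ev, VASO) == []


class TestVolumeWindows:
    def test_three_boluses_cross_at_third(self):
        ev = make_interventions(
            [(t, "fluid_crystalloid", "", 800.0, np.nan) for t in (10.0, 12.0, 14.5)]
        )
        assert h.detect_volume_window_onsets(ev, FLUID_2400_8) == [14.5]

    def test_spread_boluses_never_cross(self):
        ev = make_interventions(
            [(t, "fluid_crystalloid", "", 800.0, np.nan) for t in (0.0, 9.0, 18.0)]
        )
        assert h.detect_volume_window_onsets(ev, FLUID_2400_8) == []

    def test_single_albumin_bolus(self):
        ev = make_interventions([(3.0, "albumin25", "", 200.0, np.nan)])
        assert h.detect_volume_window_onsets(ev, ALBUMIN) == [3.0]

    def test_exact_fluid_threshold_triggers(self):
        # 'reaching the stated dosage' is read as >=
        ev = make_interventions(
            [(1.0, "fluid_crystalloid", "", 1200.0, np.nan),
             (5.0, "fluid_colloid", "", 1200.0, np.nan)]
        )
        assert h.detect_volume_window_onsets(ev, FLUID_2400_8) == [5.0]

    def test_exact_prbc_threshold_does_not_trigger(self):
        # transfusion rule is printed with a strict '>'
        ev = make_interventions(
            [(2.0, "prbc", "", 700.0, np.nan), (20.0, "prbc", "", 800.0, np.nan)]
        )
        assert h.detect_volume_window_onsets(ev, PRBC_GT_1500) == []
        ev2 = make_interventions(
            [(2.0, "prbc", "", 700.0, np.nan), (20.0, "prbc", "", 801.0, np.nan)]
        )
        assert h.detect_volume_window_onsets(ev2, PRBC_GT_1500) == [20.0]

    def test_negative_volume_rejected(self):
        ev = make_interventions([(2.0, "prbc", "", -5.0, np.nan)])
        with pytest.raises(ValueError, match="negative volume"):
            h.detect_volume_window_onsets(ev, PRBC_GT_1500)

    def test_rearm_one_onset_per_sustained_episode(self):
        # continuous accumulation: only the first crossing is an onset until
        # the running total falls back below threshold
        rows = [(t, "fluid_crystalloid", "", 900.0, np.nan) for t in (1.0, 2.0, 3.0, 4.0)]
        rows += [(30.0, "fluid_crystalloid", "", 2500.0, np.nan)]
        ev = make_interventions(rows)
        assert h.detect_volume_window_onsets(ev, FLUID_2400_8) == [3.0, 30.0]


class TestComboWindows:
    def test_all_components_within_window(self):
        ev = make_interventions(
            [
                (1.0, "prbc", "", 500.0, np.nan),
                (3.0, "ffp", "", 500.0, np.nan),
                (5.0, "platelet_pheresis", "", 500.0, np.nan),
            ]
        )
        assert h.detect_combo_window_onsets(ev, COMBO) == [5.0]

    def test_missing_component(self):
        ev = make_interventions(
            [(1.0, "prbc", "", 500.0, np.nan), (8.0, "ffp", "", 500.0, np.nan)]
        )
        assert h.detect_combo_window_onsets(ev, COMBO) == []

    def test_component_outside_window(self):
        ev = make_interventions(
            [
                (1.0, "prbc", "", 500.0, np.nan),
                (3.0, "ffp", "", 500.0, np.nan),
                (9.5, "platelet_pheresis", "", 500.0, np.nan),
            ]
        )
        assert h.detect_combo_window_onsets(ev, COMBO) == []

    def test_prbc_then_fluid_rule(self):
        rows = [(2.0, "prbc", "", 500.0, np.nan)]
        rows += [(t, "fluid_crystalloid", "", 800.0, np.nan) for t in (10.0, 11.0, 12.0)]
        ev = make_interventions(rows)
        onsets = h.detect_combo_window_onsets(
            ev, PRBC_THEN_FLUID, US_RULESET.fluid_specs()
        )
        assert onsets == [2.0]  # reported at the PRBC crossing

    def test_prbc_without_followup_fluid(self):
        ev = make_interventions([(2.0, "prbc", "", 500.0, np.nan)])
        assert (
            h.detect_combo_window_onsets(ev, PRBC_THEN_FLUID, US_RULESET.fluid_specs())
            == []
        )


class TestSegments:
    def test_merge_within_gap(self):
        segs = h.build_segments([10.0, 10.5, 11.2], merge_gap_h=1.0)
        assert len(segs) == 1
        assert segs[0].onset_time == 10.0
        assert segs[0].end_time == pytest.approx(12.2)

    def test_separate_runs(self):
        segs = h.build_segments([10.0, 20.0], merge_gap_h=1.0)
        assert [s.onset_time for s in segs] == [10.0, 20.0]

    def test_empty(self):
        assert h.build_segments([]) == []

    def test_criteria_union(self):
        segs = h.build_segments([(10.0, "a"), (10.5, "b")], merge_gap_h=1.0)
        assert segs[0].triggering_criteria == frozenset({"a", "b"})


class TestLabelCohort:
    @staticmethod
    def _patients(pids):
        return pd.DataFrame({"patient_id": pids})

    @staticmethod
    def _segments(rows):
        return pd.DataFrame(
            rows, columns=["patient_id", "onset_time", "end_time", "criteria"]
        )

    def test_first_segment_after_6h_is_validation_segment(self):
        segs = self._segments([("P1", 4.0, 5.0, "x"), ("P1", 30.0, 31.0, "x")])
        labels = h.label_cohort(self._patients(["P1"]), segs)
        assert labels.loc[0, "group"] == "unstable"
        assert labels.loc[0, "onset_time"] == 30.0

    def test_only_early_segments_excluded_not_stable(self):
        segs = self._segments([("P1", 4.0, 5.0, "x")])
        labels = h.label_cohort(self._patients(["P1"]), segs)
        assert labels.loc[0, "group"] == "excluded"
        assert labels.loc[0, "exclusion_reason"] == "only_early_segments"

    def test_no_segments_is_stable(self):
        labels = h.label_cohort(self._patients(["P1"]), self._segments([]))
        assert labels.loc[0, "group"] == "stable"

    def test_partition_is_exhaustive_and_exclusive(self, labels400):
        assert set(labels400["group"]) <= {"stable", "unstable", "excluded"}
        assert labels400["patient_id"].is_unique


class TestInclusionFilters:
    @staticmethod
    def _patients(age, los_h):
        admit = pd.Timestamp("2015-06-01")
        return pd.DataFrame(
            {
                "patient_id": ["P1"],
                "age": [age],
                "admit_time": [admit.isoformat()],
                "discharge_time": [(admit + pd.Timedelta(hours=los_h)).isoformat()],
            }
        )

    @staticmethod
    def _obs():
        return pd.DataFrame({"patient_id": ["P1"], "time": [1.0],
                             "variable": ["heart_rate"], "value": [80.0],
                             "source": ["t"]})

    def test_age_20_exactly_excluded(self):
        included, report = h.apply_inclusion_filters(self._patients(20.0, 48), self._obs())
        assert included.empty and report["age"] == 1

    def test_short_stay_excluded(self):
        included, report = h.apply_inclusion_filters(self._patients(45.0, 5.9), self._obs())
        assert included.empty and report["los_lt_6h"] == 1

    def test_empty_profile_excluded(self):
        obs = self._obs().iloc[:0]
        included, report = h.apply_inclusion_filters(self._patients(45.0, 48), obs)
        assert included.empty and report["incomplete_profile"] == 1

    def test_valid_patient_included(self):
        included, report = h.apply_inclusion_filters(self._patients(21.0, 48), self._obs())
        assert len(included) == 1 and report["included"] == 1

    def test_discharge_before_admit_rejected(self):
        pats = self._patients(45.0, -2)
        with pytest.raises(ValueError, match="discharge before admission"):
            h.apply_inclusion_filters(pats, self._obs())


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

_volume_events = st.lists(
    st.tuples(
        st.floats(0, 48).map(lambda x: round(x, 2)),
        st.sampled_from(["fluid_crystalloid", "fluid_colloid", "prbc"]),
        st.sampled_from([200.0, 500.0, 800.0, 1200.0, 2400.0]),
    ),
    min_size=0,
    max_size=15,
)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(_volume_events, st.randoms(use_true_random=False))
def test_permutation_invariance(rows, rnd):
    """Shuffling record order never changes detected onsets."""
    ev = make_interventions([(t, c, "", v, np.nan) for t, c, v in rows])
    shuffled = ev.sample(frac=1.0, random_state=rnd.randrange(2**16)).reset_index(drop=True)
    for spec in (FLUID_2400_8, PRBC_GT_1500):
        assert h.detect_volume_window_onsets(ev, spec) == h.detect_volume_window_onsets(
            shuffled, spec
        )


@settings(derandomize=True, max_examples=60, deadline=None)
@given(_volume_events)
def test_matches_brute_force_enumeration(rows):
    """Sliding-window detection equals naive window enumeration."""
    ev = make_interventions([(t, c, "", v, np.nan) for t, c, v in rows])
    for spec in (FLUID_2400_8, PRBC_GT_1500):
        assert h.detect_volume_window_onsets(ev, spec) == brute_force_volume_onsets(
            ev, spec.categories, spec.threshold_cc, spec.window_h, spec.comparator
        )


@settings(derandomize=True, max_examples=60, deadline=None)
@given(_volume_events, st.integers(0, 14), st.sampled_from([100.0, 900.0]))
def test_adding_volume_never_delays_earliest_onset(rows, idx, extra):
    """More eligible volume can only move the earliest onset earlier; an
    added non-eligible record changes nothing."""
    ev = make_interventions([(t, c, "", v, np.nan) for t, c, v in rows])
    spec = FLUID_2400_8
    base = h.detect_volume_window_onsets(ev, spec)
    if len(ev):
        bigger = ev.copy()
        i = idx % len(bigger)
        if bigger.loc[i, "category"] in spec.categories:
            bigger.loc[i, "volume_cc"] += extra
            more = h.detect_volume_window_onsets(bigger, spec)
            if base:
                assert more and min(more) <= min(base)
    with_noise = pd.concat(
        [ev, make_interventions([(5.0, "ffp", "", 500.0, np.nan)])],
        ignore_index=True,
    )
    assert h.detect_volume_window_onsets(with_noise, spec) == base


def test_detect_onsets_reports_criterion_ids():
    rows = [(10.0, "vasoactive", "Levophed", 0.0, 3.0)]
    rows += [(t, "fluid_crystalloid", "", 800.0, np.nan) for t in (20.0, 21.0, 22.0)]
    pairs = detect_onsets(make_interventions(rows), TPEVGH_RULESET)
    assert (10.0, "vaso_any") in pairs
    assert (22.0, "fluid_2400_8") in pairs
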