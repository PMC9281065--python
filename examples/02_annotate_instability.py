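"""Annotate hemodynamic instability from an intervention log.

Instability onsets are detected by the rule set in use (any vasoactive
dose; cumulative fluid-volume windows; transfusion criteria), merged into
segments, and the cohort is partitioned into stable / unstable / excluded.
"""

import numpy as np
import pandas as pd

import hemodyn as h

# a hand-written log: one patient on pressors, one with a fluid episode,
# one with only a sub-threshold bolus
log = pd.DataFrame(
    {
        "patient_id": ["A", "B", "B", "B", "C"],
        "time": [12.0, 20.0, 22.0, 24.0, 9.0],
        "category": ["vasoactive"] + ["fluid_crystalloid"] * 3 + ["fluid_crystalloid"],
        "agent": ["Levophed", "", "", "", ""],
        "volume_cc": [0.0, 800.0, 800.0, 800.0, 500.0],
        "dose": [4.0, np.nan, np.nan, np.nan, np.nan],
    }
)

segments = h.annotate_interventions(log, ruleset="TPEVGH", merge_gap_h=1.0)
print(segments.to_string(index=False))
# Patient A triggers the any-vasoactive criterion at 12 h (Levophed is
# normalized to norepinephrine); patient B crosses 2400 cc within 8 h at the
# third bolus (24 h); patient C's single 500 cc bolus triggers nothing.

patients = pd.DataFrame(
    {"patient_id": ["A", "B", "C"]}
)
labels = h.label_cohort(patients, segments)
print()
print(labels[["patient_id", "group", "onset_time"]].to_string(index=False))
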