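"""Independent brute-force oracles used by the tests.

These deliberately use naive O(n^2) enumeration and exhaustive pair
counting, sharing no code with the package implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_force_volume_onsets(
    events: pd.DataFrame,
    categories,
    threshold_cc: float,
    window_h: float,
    comparator: str = "ge",
) -> list[float]:
    """Test every window ending at every event time; first crossings per
    episode (re-arming when an event-time total falls back below)."""
    rows = [
        (float(t), float(v))
        for t, v, c in zip(events["time"], events["volume_cc"], events["category"])
        if c in set(categories)
    ]
    entries = sorted({t for t, _ in rows})
    # window totals change only at entries and exits; re-arm can happen at
    # either, onsets only at entries
    candidates = sorted({t for t, _ in rows} | {t + window_h for t, _ in rows})
    onsets: list[float] = []
    armed = True
    for t in candidates:
        total = sum(v for s, v in rows if t - window_h < s <= t)
        ok = total >= threshold_cc if comparator == "ge" else total > threshold_cc
        if ok and t in entries and armed:
            onsets.append(t)
            armed = False
        elif not ok:
            armed = True
    return onsets


def brute_force_combo_onsets(
    events: pd.DataFrame, components, window_h: float
) -> list[float]:
    """Naive multi-component window check at every component event time."""
    comp = {c: float(m) for c, m in components}
    rows = [
        (float(t), float(v), c)
        for t, v, c in zip(events["time"], events["volume_cc"], events["category"])
        if c in comp
    ]
    entries = {t for t, _, _ in rows}
    candidates = sorted(entries | {t + window_h for t, _, _ in rows})
    onsets: list[float] = []
    armed = True
    for t in candidates:
        ok = all(
            sum(v for s, v, c2 in rows if c2 == c and t - window_h < s <= t) >= m
            for c, m in comp.items()
        )
        if ok and t in entries and armed:
            onsets.append(t)
            armed = False
        elif not ok:
            armed = True
    return onsets


def brute_force_volume_then_fluid(
    events: pd.DataFrame,
    base_categories,
    base_threshold: float,
    base_window: float,
    fluid_specs,
    followup_window: float,
) -> list[float]:
    """Base volume crossing followed by any fluid onset within the window."""
    base = brute_force_volume_onsets(
        events, base_categories, base_threshold, base_window, "ge"
    )
    fluids = sorted(
        t
        for fs in fluid_specs
        for t in brute_force_volume_onsets(
            events, fs.categories, fs.threshold_cc, fs.window_h, fs.comparator
        )
    )
    return [
        t0 for t0 in base if any(t0 < f <= t0 + followup_window for f in fluids)
    ]


def pair_counting_auroc(scores, labels) -> float:
    """Exhaustive pairwise concordance with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_intervention_log(rng: np.random.Generator, max_events: int = 20) -> pd.DataFrame:
    """Random small event log mixing categories and near-threshold volumes."""
    n = int(rng.integers(1, max_events + 1))
    categories = rng.choice(
        [
            "fluid_crystalloid",
            "fluid_colloid",
            "albumin25",
            "prbc",
            "ffp",
            "platelet_pheresis",
        ],
        size=n,
    )
    anchor_volumes = np.array([100.0, 200.0, 500.0, 800.0, 1200.0, 1500.0, 2400.0])
    volumes = np.where(
        rng.random(n) < 0.6,
        rng.choice(anchor_volumes, size=n),
        np.round(rng.uniform(50, 2600, size=n), 1),
    )
    times = np.round(rng.uniform(0, 48, size=n), 2)
    return pd.DataFrame(
        {
            "patient_id": "PX",
            "time": times,
            "category": categories,
            "agent": "",
            "volume_cc": volumes,
            "dose": np.nan,
        }
    )
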