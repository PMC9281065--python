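"""Validation statistics: discrimination, thresholds, lead time, calibration.

AUROC uses the Mann-Whitney formulation (ties count one half); confidence
intervals and paired score comparisons use DeLong's nonparametric structural
components with midranks. Threshold analyses alarm on ``score > threshold``
(strict). The lead-time analysis reports, per pre-onset hour, the fraction
of unstable patients already above threshold, the distribution of the
first (earliest) alarm, and the stable-cohort false-alarm rate. Case-mix
reports compare per-variable medians between two cohorts and test baseline
characteristics with Kruskal-Wallis (continuous) and Fisher's exact test
(categorical; Monte Carlo beyond 2x2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from scipy.stats import rankdata

from .registry import FeatureRegistry

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# AUROC and DeLong inference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscriminationResult:
    auroc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    alpha: float = 0.05
    degenerate: bool = False


def _clean_pair(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    keep = ~np.isnan(scores)
    return scores[keep], labels[keep]


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(random positive > random negative), ties 1/2.

    Missing scores are dropped pairwise. Raises if only one class remains.
    """
    s, y = _clean_pair(scores, labels)
    m = int((y == 1).sum())
    n = int((y == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("auroc requires both classes present")
    ranks = rankdata(s)  # midranks
    return float((ranks[y == 1].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - rankdata(neg)) / m
    auc = float(v10.mean())
    return auc, v10, v01


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an AUROC estimate."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def delong_ci(scores, labels, alpha: float = 0.05) -> DiscriminationResult:
    """AUROC with a DeLong normal-approximation CI, truncated to [0, 1].

    A zero-variance estimate at AUROC 0 or 1 (perfect separation) collapses
    the interval to the point and is flagged ``degenerate``.
    """
    s, y = _clean_pair(scores, labels)
    m = int((y == 1).sum())
    n = int((y == 0).sum())
    if m < 2 or n < 2:
        raise ValueError("delong_ci requires >= 2 samples per class")
    auc, v10, v01 = _delong_components(s, y)
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    degenerate = bool(var <= 0 and auc in (0.0, 1.0))
    if var <= 0:
        lo = hi = auc
    else:
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(var)
        lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    return DiscriminationResult(auc, float(lo), float(hi), m, n, alpha, degenerate)


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided paired DeLong test comparing two scorers on the same samples.

    Returns (z, p). Identical score vectors give z = 0, p = 1. Swapping the
    scorers negates z.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    keep = ~np.isnan(sa) & ~np.isnan(sb)
    sa, sb, y = sa[keep], sb[keep], y[keep]
    m = int((y == 1).sum())
    n = int((y == 0).sum())
    if m < 2 or n < 2:
        raise ValueError("delong_paired_test requires >= 2 samples per class")
    auc_a, v10_a, v01_a = _delong_components(sa, y)
    auc_b, v10_b, v01_b = _delong_components(sb, y)
    var = (
        v10_a.var(ddof=1) / m
        + v10_b.var(ddof=1) / m
        - 2 * np.cov(v10_a, v10_b, ddof=1)[0, 1] / m
        + v01_a.var(ddof=1) / n
        + v01_b.var(ddof=1) / n
        - 2 * np.cov(v01_a, v01_b, ddof=1)[0, 1] / n
    )
    if var <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def time_varying_auroc(
    samples: pd.DataFrame,
    scores: dict[str, np.ndarray] | np.ndarray,
    leads: range | list[int] = range(1, 25),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-lead discrimination: unstable rows at lead t vs all stable rows.

    ``samples`` must carry ``lead_hours`` (>= 1 unstable, 0 stable) and
    ``label``; ``scores`` maps scorer name to a row-aligned array (a bare
    array is treated as one scorer named "model"). The single stable-group
    sample set is reused at every lead. Leads with no positive rows are
    omitted with a warning.
    """
    if not isinstance(scores, dict):
        scores = {"model": np.asarray(scores)}
    lead_col = samples["lead_hours"].to_numpy()
    labels = samples["label"].to_numpy(int)
    neg_mask = labels == 0
    rows = []
    for lead in leads:
        pos_mask = (labels == 1) & (lead_col == lead)
        if not pos_mask.any():
            logger.warning("no positive rows at lead %s; omitted", lead)
            continue
        mask = pos_mask | neg_mask
        for name, vec in scores.items():
            res = delong_ci(np.asarray(vec)[mask], labels[mask], alpha=alpha)
            rows.append(
                {
                    "lead_hours": int(lead),
                    "scorer": name,
                    "auroc": res.auroc,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n_pos": res.n_pos,
                    "n_neg": res.n_neg,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["lead_hours", "scorer", "auroc", "ci_low", "ci_high", "n_pos", "n_neg"],
    )


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------


def threshold_sweep(
    scores, labels, grid_step: float = 0.01
) -> pd.DataFrame:
    """Confusion-matrix metrics over a threshold grid; alarm = score > t."""
    s, y = _clean_pair(scores, labels)
    if s.size == 0:
        raise ValueError("threshold_sweep on empty score set")
    thresholds = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    rows = []
    for t in thresholds:
        alarm = s > t
        tp = int((alarm & (y == 1)).sum())
        fp = int((alarm & (y == 0)).sum())
        fn = n_pos - tp
        tn = n_neg - fp
        rows.append(
            {
                "threshold": float(t),
                "tp": tp,
                "fp": fp,
                "tn": tn,
                "fn": fn,
                "recall": tp / n_pos if n_pos else np.nan,
                "precision": tp / (tp + fp) if tp + fp else np.nan,
                "specificity": tn / n_neg if n_neg else np.nan,
            }
        )
    return pd.DataFrame(rows)


def select_threshold(
    sweep: pd.DataFrame,
    policy: str = "fixed",
    value: float = 0.7,
    min_recall: float = 0.5,
) -> float:
    """Pick an alarm threshold from a sweep.

    Policies: ``fixed`` (default 0.7), ``break_even`` (minimize
    |recall - specificity|), ``min_recall`` (max specificity subject to
    recall >= min_recall).
    """
    if sweep.empty:
        raise ValueError("empty threshold sweep")
    if policy == "fixed":
        return float(value)
    if policy == "break_even":
        gap = (sweep["recall"] - sweep["specificity"]).abs()
        return float(sweep.loc[gap.idxmin(), "threshold"])
    if policy == "min_recall":
        ok = sweep[sweep["recall"] >= min_recall]
        if ok.empty:
            raise ValueError(f"no threshold achieves recall >= {min_recall}")
        return float(ok.loc[ok["specificity"].idxmax(), "threshold"])
    raise ValueError(f"unknown threshold policy: {policy!r}")


# ---------------------------------------------------------------------------
# lead time and alarms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LeadTimeResult:
    """Alarm timing summary for a threshold.

    ``first_alarms`` has one row per unstable patient with a score series
    (first_alarm_lead_h is NaN when no crossing occurred in the window);
    ``true_alarm_by_lead`` is the per-hour fraction of unstable patients
    above threshold; ``lead_coverage`` is the non-increasing fraction of
    unstable patients whose first alarm came at least k hours early;
    ``false_alarm_by_hour``/``false_alarm_rate`` cover the stable cohort.
    """

    threshold: float
    first_alarms: pd.DataFrame
    quantiles: dict[str, float]
    lead_coverage: pd.DataFrame
    true_alarm_by_lead: pd.DataFrame
    false_alarm_by_hour: pd.DataFrame
    false_alarm_rate: float
    missed_fraction: float
    n_unstable_scored: int
    n_unstable_missing_series: int


def lead_time_analysis(
    series: pd.DataFrame,
    labels: pd.DataFrame,
    threshold: float,
    window_h: int = 24,
) -> LeadTimeResult:
    """Alarm lead-time analysis from hourly score series.

    ``series`` holds (patient_id, reference_time, score) rows; ``labels``
    supplies each patient's group and, for unstable patients, the onset
    time. Unstable rows are indexed by integer lead = onset - time within
    ``(0, window_h]``; stable rows by hour of stay within the same horizon.
    """
    lab = labels.set_index(labels["patient_id"].astype(str))
    unstable_ids = lab.index[lab["group"] == "unstable"]
    stable_ids = set(lab.index[lab["group"] == "stable"])

    series = series.copy()
    series["patient_id"] = series["patient_id"].astype(str)
    by_pid = dict(tuple(series.groupby("patient_id")))

    first_rows = []
    alarm_counts = {k: [0, 0] for k in range(1, window_h + 1)}  # lead -> [alarms, n]
    n_missing = 0
    for pid in unstable_ids:
        sub = by_pid.get(pid)
        onset = float(lab.loc[pid, "onset_time"])
        if sub is None or sub.empty:
            n_missing += 1
            continue
        lead = onset - sub["reference_time"].to_numpy(float)
        lead_int = np.rint(lead).astype(int)
        in_win = (lead > 0) & (lead_int >= 1) & (lead_int <= window_h)
        if not in_win.any():
            n_missing += 1
            continue
        sc = sub["score"].to_numpy(float)[in_win]
        li = lead_int[in_win]
        for k, s_val in zip(li, sc):
            alarm_counts[int(k)][1] += 1
            if s_val > threshold:
                alarm_counts[int(k)][0] += 1
        crossing = li[sc > threshold]
        first = float(crossing.max()) if crossing.size else np.nan
        first_rows.append({"patient_id": pid, "first_alarm_lead_h": first})
    if n_missing:
        logger.warning("%d unstable patients lacked a usable score series", n_missing)

    first_alarms = pd.DataFrame(
        first_rows, columns=["patient_id", "first_alarm_lead_h"]
    )
    leads_obs = first_alarms["first_alarm_lead_h"].dropna().to_numpy(float)
    n_scored = len(first_alarms)
    missed = 1.0 - len(leads_obs) / n_scored if n_scored else np.nan
    quantiles = {
        q: (float(np.quantile(leads_obs, float(q))) if leads_obs.size else np.nan)
        for q in ("0.05", "0.25", "0.5", "0.75", "0.95")
    }
    coverage = pd.DataFrame(
        {
            "lead_hours": np.arange(1, window_h + 1),
            "fraction_alarmed": [
                (leads_obs >= k).sum() / n_scored if n_scored else np.nan
                for k in range(1, window_h + 1)
            ],
        }
    )
    true_alarm = pd.DataFrame(
        {
            "lead_hours": list(alarm_counts),
            "fraction": [
                a / n if n else np.nan for a, n in alarm_counts.values()
            ],
            "n_patients": [n for _, n in alarm_counts.values()],
        }
    )

    fa_rows = []
    fa_alarms = fa_total = 0
    stable_series = series[series["patient_id"].isin(stable_ids)]
    if len(stable_series):
        hour = np.rint(stable_series["reference_time"].to_numpy(float)).astype(int)
        sc = stable_series["score"].to_numpy(float)
        for k in range(1, window_h + 1):
            m = hour == k
            n_k = int(m.sum())
            a_k = int((sc[m] > threshold).sum())
            fa_rows.append(
                {"hour": k, "fraction": a_k / n_k if n_k else np.nan, "n": n_k}
            )
            fa_alarms += a_k
            fa_total += n_k
    false_alarm_by_hour = pd.DataFrame(fa_rows, columns=["hour", "fraction", "n"])
    fa_rate = fa_alarms / fa_total if fa_total else np.nan

    return LeadTimeResult(
        threshold=float(threshold),
        first_alarms=first_alarms,
        quantiles=quantiles,
        lead_coverage=coverage,
        true_alarm_by_lead=true_alarm,
        false_alarm_by_hour=false_alarm_by_hour,
        false_alarm_rate=float(fa_rate) if fa_total else np.nan,
        missed_fraction=float(missed) if n_scored else np.nan,
        n_unstable_scored=n_scored,
        n_unstable_missing_series=n_missing,
    )


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def calibration_table(scores, labels, n_bins: int = 10) -> pd.DataFrame:
    """Equal-width probability bins with mean prediction and observed rate.

    Empty bins are reported with zero count (NaN mean/observed); counts sum
    to the number of scored samples.
    """
    s, y = _clean_pair(scores, labels)
    if len(s) < n_bins:
        raise ValueError("calibration requires n >= n_bins")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(s, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        count = int(m.sum())
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "mean_predicted": float(s[m].mean()) if count else np.nan,
                "observed_rate": float(y[m].mean()) if count else np.nan,
                "count": count,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subgroups
# ---------------------------------------------------------------------------


def subgroup_metrics(
    scores,
    labels,
    groups,
    threshold: float = 0.7,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-group AUROC/CI and threshold metrics.

    ``groups`` is a row-aligned array of group names. Groups lacking both
    classes (or with < 2 samples in a class) are skipped and returned in the
    second element.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    g = np.asarray(groups)
    rows, skipped = [], []
    for name in pd.unique(g):
        m = (g == name) & ~np.isnan(s)
        if (y[m] == 1).sum() < 2 or (y[m] == 0).sum() < 2:
            skipped.append(str(name))
            continue
        res = delong_ci(s[m], y[m], alpha=alpha)
        alarm = s[m] > threshold
        tp = int((alarm & (y[m] == 1)).sum())
        fp = int((alarm & (y[m] == 0)).sum())
        fn = int(((~alarm) & (y[m] == 1)).sum())
        tn = int(((~alarm) & (y[m] == 0)).sum())
        rows.append(
            {
                "group": str(name),
                "n": int(m.sum()),
                "auroc": res.auroc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "recall": tp / (tp + fn) if tp + fn else np.nan,
                "precision": tp / (tp + fp) if tp + fp else np.nan,
                "specificity": tn / (tn + fp) if tn + fp else np.nan,
            }
        )
    if skipped:
        logger.warning("subgroups skipped for lacking both classes: %s", skipped)
    return pd.DataFrame(rows), skipped


def year_groups(
    patients: pd.DataFrame, min_count: int = 50
) -> pd.Series:
    """Admission-year grouping; a sparse final year merges into the previous.

    Returns a Series of year labels indexed like ``patients``.
    """
    years = pd.to_datetime(patients["admit_time"]).dt.year
    labels = years.astype(str)
    counts = years.value_counts().sort_index()
    if len(counts) >= 2 and counts.iloc[-1] < min_count:
        last, prev = counts.index[-1], counts.index[-2]
        labels[years == last] = f"{prev}-{last}"
        labels[years == prev] = f"{prev}-{last}"
    return labels


# ---------------------------------------------------------------------------
# case mix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaseMixReport:
    feature_medians: pd.DataFrame
    continuous_tests: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variable", "p_value"])
    )
    categorical_tests: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variable", "p_value"])
    )


def fisher_exact_p(
    table: np.ndarray, n_mc: int = 20000, seed: int = 0
) -> float:
    """Fisher's exact p for an r x c contingency table.

    2x2 tables use the exact test; larger tables use a seeded Monte Carlo
    estimate conditioning on the margins (tables are sampled with fixed
    margins and counted as at least as extreme when their conditional
    probability does not exceed the observed table's).
    """
    table = np.asarray(table, dtype=int)
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table)[1])
    logp_obs = -gammaln(table + 1).sum()
    sampler = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    rng = np.random.default_rng(seed)
    draws = sampler.rvs(n_mc, random_state=rng)
    logp = -gammaln(draws + 1).sum(axis=(1, 2))
    hits = int((logp <= logp_obs + 1e-9).sum())
    return float((hits + 1) / (n_mc + 1))


def case_mix_report(
    samples_a: pd.DataFrame,
    samples_b: pd.DataFrame,
    registry: FeatureRegistry,
    baseline_a: pd.DataFrame | None = None,
    baseline_b: pd.DataFrame | None = None,
    continuous: tuple[str, ...] = ("age", "apache2"),
    categorical: tuple[str, ...] = ("gender", "admission_type", "icu_type", "mortality"),
    seed: int = 0,
) -> CaseMixReport:
    """Median shift of every registry variable between two cohorts.

    Percent difference is ``(median_b - median_a) / median_a * 100``.
    Variables absent (or all-missing) in a cohort are flagged not
    comparable. When baseline patient tables are supplied, continuous
    characteristics are tested with Kruskal-Wallis and categorical ones with
    Fisher's exact test, reported raw (no multiplicity correction).
    """
    rows = []
    for variable in registry.variables:
        in_a = variable in samples_a.columns and samples_a[variable].notna().any()
        in_b = variable in samples_b.columns and samples_b[variable].notna().any()
        med_a = float(samples_a[variable].median()) if in_a else np.nan
        med_b = float(samples_b[variable].median()) if in_b else np.nan
        comparable = in_a and in_b and med_a != 0
        rows.append(
            {
                "variable": variable,
                "median_a": med_a,
                "median_b": med_b,
                "pct_diff": (med_b - med_a) / med_a * 100.0 if comparable else np.nan,
                "comparable": comparable,
            }
        )
    medians = pd.DataFrame(rows)

    cont_rows, cat_rows = [], []
    if baseline_a is not None and baseline_b is not None:
        for variable in continuous:
            if variable not in baseline_a.columns or variable not in baseline_b.columns:
                continue
            a = baseline_a[variable].dropna().to_numpy(float)
            b = baseline_b[variable].dropna().to_numpy(float)
            if len(a) and len(b):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = stats.kruskal(a, b).pvalue
                cont_rows.append({"variable": variable, "p_value": float(p)})
        for variable in categorical:
            if variable not in baseline_a.columns or variable not in baseline_b.columns:
                continue
            levels = sorted(
                set(baseline_a[variable].dropna().astype(str))
                | set(baseline_b[variable].dropna().astype(str))
            )
            if len(levels) < 2:
                continue
            tab = np.array(
                [
                    [int((baseline_a[variable].astype(str) == lv).sum()) for lv in levels],
                    [int((baseline_b[variable].astype(str) == lv).sum()) for lv in levels],
                ]
            )
            cat_rows.append(
                {"variable": variable, "p_value": fisher_exact_p(tab, seed=seed)}
            )
    return CaseMixReport(
        feature_medians=medians,
        continuous_tests=pd.DataFrame(cont_rows, columns=["variable", "p_value"]),
        categorical_tests=pd.DataFrame(cat_rows, columns=["variable", "p_value"]),
    )
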