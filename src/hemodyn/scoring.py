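"""Retrainable tree-ensemble risk score and single-parameter baselines.

The proprietary hemodynamic-stability score being validated is an ensemble
of depth-limited decision trees over 33 physiological variables that emits
an hourly instability probability and tolerates missing inputs. This module
provides a retrainable stand-in with the same contract — gradient-boosted
depth-limited trees with native missing-value default branches — plus the
two single-parameter baselines (systolic blood pressure and shock index).
Any conforming scorer (a callable mapping a sample frame to probabilities)
can be plugged into the evaluation harness in its place; the stand-in never
claims to reproduce the original model's weights.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier

from .features import SampleMatrix, compute_shock_index
from .registry import FeatureRegistry

SERIALIZATION_VERSION = 1

DEFAULT_HYPERPARAMS = {"n_trees": 200, "max_depth": 4, "learning_rate": 0.1}

BASELINES = ("sbp", "shock_index")


@dataclass
class RiskModel:
    """A trained instability scorer: probability in [0, 1] per sample row.

    Wraps a fitted gradient-boosted tree ensemble whose every split carries
    a learned default branch for missing values, so rows with any subset of
    missing features — including all-missing rows — still receive a finite
    score. Metadata pins the feature schema and training conditions.
    """

    estimator: HistGradientBoostingClassifier
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)

    def predict(self, samples: pd.DataFrame) -> np.ndarray:
        return predict_risk(self, samples)


def _training_rows(
    samples: SampleMatrix, seed: int, one_row_per_patient: bool
) -> pd.DataFrame:
    # canonical order first, so a permutation of input rows changes nothing
    frame = samples.frame.sort_values(
        ["patient_id", "reference_time"], kind="stable"
    ).reset_index(drop=True)
    if not one_row_per_patient:
        return frame
    # one randomly chosen lead row per unstable patient + all stable rows,
    # to mimic onset-anchored training without leaking full trajectories
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    pos = frame[frame["label"] == 1]
    neg = frame[frame["label"] == 0]
    picks = []
    for _, grp in pos.groupby("patient_id", sort=True):
        picks.append(grp.index[rng.integers(len(grp))])
    return pd.concat([pos.loc[picks], neg]) if picks else neg


def train_reference_model(
    samples: SampleMatrix,
    hyperparams: dict | None = None,
    seed: int = 0,
    one_row_per_patient: bool = True,
) -> RiskModel:
    """Fit the stand-in ensemble. Deterministic given seed.

    Training rows are canonically pre-sorted by (patient_id, reference_time)
    so a permutation of the input rows yields an identical model. Raises on
    a single-class training set.
    """
    hp = {**DEFAULT_HYPERPARAMS, **(hyperparams or {})}
    rows = _training_rows(samples, seed, one_row_per_patient)
    rows = rows.sort_values(["patient_id", "reference_time"], kind="stable")
    y = rows["label"].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    X = rows[samples.feature_columns].to_numpy(float)
    # a feature never observed in training carries no split information;
    # fill it with a constant so the binner accepts it
    all_nan = np.isnan(X).all(axis=0)
    X[:, all_nan] = 0.0
    est = HistGradientBoostingClassifier(
        max_iter=hp["n_trees"],
        max_depth=hp["max_depth"],
        learning_rate=hp["learning_rate"],
        early_stopping=False,
        random_state=seed & 0x7FFFFFFF,
    )
    est.fit(X, y)
    return RiskModel(
        estimator=est,
        feature_names=list(samples.feature_columns),
        metadata={
            "seed": seed,
            "hyperparams": hp,
            "registry_hash": samples.registry.content_hash(),
            "class_prior": float(y.mean()),
            "n_training_rows": int(len(y)),
            "serialization_version": SERIALIZATION_VERSION,
        },
    )


def predict_risk(model: RiskModel, samples: pd.DataFrame | SampleMatrix) -> np.ndarray:
    """Instability probability per row; pure function of (model, row)."""
    frame = samples.frame if isinstance(samples, SampleMatrix) else samples
    missing = [c for c in model.feature_names if c not in frame.columns]
    if missing:
        raise ValueError(f"sample frame missing model feature columns: {missing}")
    X = frame[model.feature_names].to_numpy(float)
    return model.estimator.predict_proba(X)[:, 1]


def baseline_score(
    samples: pd.DataFrame | SampleMatrix, which: str
) -> np.ndarray:
    """Single-parameter baseline, oriented so higher = riskier.

    ``sbp`` is the negated (post-imputation) invasive systolic pressure;
    ``shock_index`` is heart rate / SBP. Missing inputs give missing scores,
    to be dropped pairwise by the evaluation.
    """
    frame = samples.frame if isinstance(samples, SampleMatrix) else samples
    if which == "sbp":
        return -frame["sbp_invasive"].to_numpy(float)
    if which == "shock_index":
        return compute_shock_index(frame).to_numpy(float)
    raise ValueError(f"unknown baseline: {which!r} (expected one of {BASELINES})")


def score_timeline(
    model: RiskModel,
    patient_observations: pd.DataFrame,
    registry: FeatureRegistry,
    end_time_h: float,
    grid_step_h: float = 1.0,
) -> pd.DataFrame:
    """Hourly score series over one stay: (reference_time, score) rows."""
    if end_time_h < grid_step_h or patient_observations.empty:
        return pd.DataFrame(columns=["patient_id", "reference_time", "score"])
    pid = str(patient_observations["patient_id"].iloc[0])
    times = np.arange(grid_step_h, end_time_h + 1e-9, grid_step_h)
    refs = pd.DataFrame({"patient_id": pid, "reference_time": times})
    return score_at_times(model, patient_observations, registry, refs)


def score_at_times(
    model: RiskModel,
    observations: pd.DataFrame,
    registry: FeatureRegistry,
    refs: pd.DataFrame,
) -> pd.DataFrame:
    """Score arbitrary (patient_id, reference_time) grid rows in one pass."""
    from .features import _locf_extract, apply_plausibility_filter, impute_features

    obs = apply_plausibility_filter(observations, registry)
    refs = refs[["patient_id", "reference_time"]].sort_values(
        ["patient_id", "reference_time"], kind="stable"
    ).reset_index(drop=True)
    feats = impute_features(_locf_extract(obs, refs, registry), registry)
    out = refs.copy()
    out["score"] = model.estimator.predict_proba(
        feats[model.feature_names].to_numpy(float)
    )[:, 1]
    return out


def save_model(model: RiskModel, path: str | Path) -> None:
    """Serialize a model (versioned container with embedded registry hash)."""
    payload = {
        "version": SERIALIZATION_VERSION,
        "feature_names": model.feature_names,
        "metadata": model.metadata,
        "estimator": model.estimator,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path) -> RiskModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != SERIALIZATION_VERSION:
        raise ValueError(f"unsupported model container version: {payload.get('version')}")
    return RiskModel(
        estimator=payload["estimator"],
        feature_names=payload["feature_names"],
        metadata=payload["metadata"],
    )
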