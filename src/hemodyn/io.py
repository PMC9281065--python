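"""Table schemas, CSV readers/writers, run configuration and manifest.

CSV is the canonical interchange format (EHR extracts are tabular). Missing
values are encoded as empty fields. Patient admission/discharge stamps are
ISO-8601; event times are numeric hours from ICU admission.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

SCHEMAS: dict[str, list[str]] = {
    "patients": [
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
    ],
    "observations": ["patient_id", "time", "variable", "value", "source"],
    "interventions": ["patient_id", "time", "category", "agent", "volume_cc", "dose"],
    "ground_truth": ["patient_id", "group", "onset_time", "latent_z", "trigger_kind"],
    "segments": ["patient_id", "onset_time", "end_time", "criteria"],
    "labels": [
        "patient_id",
        "group",
        "onset_time",
        "end_time",
        "criteria",
        "exclusion_reason",
    ],
    "scores": ["patient_id", "reference_time", "score"],
}


def read_table(path: str | Path, schema_id: str) -> pd.DataFrame:
    """Read a CSV whose header must match the published schema exactly."""
    expected = SCHEMAS[schema_id]
    table = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in expected if c not in table.columns]
    extra = [c for c in table.columns if c not in expected]
    if missing or extra:
        raise ValueError(
            f"{path}: schema mismatch for '{schema_id}' "
            f"(missing columns: {missing}, extra columns: {extra})"
        )
    return table[expected]


def write_table(table: pd.DataFrame, path: str | Path, schema_id: str) -> None:
    expected = SCHEMAS[schema_id]
    missing = [c for c in expected if c not in table.columns]
    if missing:
        raise ValueError(f"cannot write '{schema_id}': missing columns {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table[expected].to_csv(path, index=False)


def write_samples(frame: pd.DataFrame, path: str | Path, variables: list[str]) -> None:
    """Write a wide sample matrix with explicit per-variable missing masks."""
    out = frame.copy()
    for v in variables:
        out[f"{v}__missing"] = out[v].isna().astype(int)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def read_samples(path: str | Path, variables: list[str]) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"patient_id": str})
    meta = ["patient_id", "reference_time", "lead_hours", "label"]
    missing = [c for c in meta + list(variables) if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: samples file missing columns {missing}")
    return table[meta + list(variables)]


@dataclass
class RunConfig:
    """End-to-end run configuration.

    Either ``generator`` (synthetic conditions) or explicit input table
    paths must be provided. All randomness fans out from ``seed``.
    """

    out_dir: str = "run_out"
    seed: int = 0
    generator: dict = field(default_factory=dict)
    patients_path: str | None = None
    observations_path: str | None = None
    interventions_path: str | None = None
    registry_path: str | None = None
    ruleset: str = "TPEVGH"
    merge_gap_h: float = 1.0
    horizon_h: int = 24
    stable_window_h: float = 5.0
    threshold_policy: str = "fixed"
    threshold_value: float = 0.7
    train_fraction: float = 0.5
    write_input_tables: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.ruleset not in {"TPEVGH", "US"}:
            raise ValueError(f"unknown ruleset: {self.ruleset}")
        paths = (self.patients_path, self.observations_path, self.interventions_path)
        if any(paths) and not all(paths):
            raise ValueError(
                "patients_path, observations_path and interventions_path "
                "must be given together"
            )

    @property
    def uses_generator(self) -> bool:
        return self.patients_path is None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    """Per-run accounting: config hash, seed, stage row counts, checksums."""

    config_hash: str
    seed: int
    software_version: str
    counts: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    status: str = "running"

    def reconcile(self) -> None:
        """Assert the row-count ledger is internally consistent."""
        c = self.counts
        if "n_patients_input" in c and "included" in c:
            excluded = (
                c.get("excluded_age", 0)
                + c.get("excluded_los_lt_6h", 0)
                + c.get("excluded_incomplete_profile", 0)
            )
            if c["included"] + excluded != c["n_patients_input"]:
                raise RuntimeError("manifest: inclusion counts do not reconcile")
        if {"included", "stable", "unstable", "excluded_only_early_segments"} <= set(c):
            part = (
                c["stable"] + c["unstable"] + c["excluded_only_early_segments"]
            )
            if part != c["included"]:
                raise RuntimeError("manifest: cohort partition does not reconcile")
        if {"n_samples", "expected_samples"} <= set(c):
            if c["n_samples"] != c["expected_samples"]:
                raise RuntimeError("manifest: sample row counts do not reconcile")

    def write(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
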