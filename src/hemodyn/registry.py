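"""Feature registry: the physiological variables a risk score consumes.

The registry is an editable data table, one row per variable, carrying the
variable's category (vital / lab / blood_gas / ventilation), units,
plausibility range ``[lo, hi]``, staleness limit (how many hours a last
observation remains usable for carry-forward), and a fallback-imputation
rule id. The default registry ships with the package and holds 33 routinely
measured ICU variables; a deployment can substitute its own table.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

#: Columns a registry table must provide, in canonical order.
REGISTRY_COLUMNS = [
    "variable",
    "category",
    "units",
    "lo",
    "hi",
    "staleness_h",
    "fallback",
    "ref_value",
    "ref_sd",
]

VALID_CATEGORIES = {"vital", "lab", "blood_gas", "ventilation"}
VALID_FALLBACKS = {"none", "nibp_to_ibp", "fio2_room_air"}

#: invasive pressure -> noninvasive counterpart used by the nibp_to_ibp rule
NIBP_PAIRS = {
    "sbp_invasive": "sbp_noninvasive",
    "dbp_invasive": "dbp_noninvasive",
    "map_invasive": "map_noninvasive",
}

ROOM_AIR_FIO2 = 0.21


@dataclass(frozen=True)
class FeatureRegistry:
    """Immutable wrapper around the registry table.

    Parameters
    ----------
    table:
        Registry rows with :data:`REGISTRY_COLUMNS`. Validated on
        construction: ``lo < hi``, positive staleness, known categories and
        fallback rule ids, unique variable names.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in REGISTRY_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"registry missing columns: {missing}")
        if t["variable"].duplicated().any():
            dupes = t.loc[t["variable"].duplicated(), "variable"].tolist()
            raise ValueError(f"duplicate registry variables: {dupes}")
        if not (t["lo"] < t["hi"]).all():
            bad = t.loc[~(t["lo"] < t["hi"]), "variable"].tolist()
            raise ValueError(f"registry rows with lo >= hi: {bad}")
        if not (t["staleness_h"] > 0).all():
            raise ValueError("registry staleness_h must be positive")
        bad_cat = set(t["category"]) - VALID_CATEGORIES
        if bad_cat:
            raise ValueError(f"unknown registry categories: {sorted(bad_cat)}")
        bad_fb = set(t["fallback"]) - VALID_FALLBACKS
        if bad_fb:
            raise ValueError(f"unknown fallback rules: {sorted(bad_fb)}")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def variables(self) -> list[str]:
        return self.table["variable"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, variable: str) -> bool:
        return variable in set(self.table["variable"])

    def row(self, variable: str) -> pd.Series:
        hit = self.table[self.table["variable"] == variable]
        if hit.empty:
            raise KeyError(f"unknown registry variable: {variable}")
        return hit.iloc[0]

    def plausibility_range(self, variable: str) -> tuple[float, float]:
        r = self.row(variable)
        return float(r["lo"]), float(r["hi"])

    def staleness(self, variable: str) -> float:
        return float(self.row(variable)["staleness_h"])

    def by_category(self, category: str) -> list[str]:
        return self.table.loc[
            self.table["category"] == category, "variable"
        ].tolist()

    def content_hash(self) -> str:
        """Stable hash of the registry content, embedded in trained models."""
        payload = self.table[REGISTRY_COLUMNS].to_csv(index=False).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_registry(path: str | Path) -> FeatureRegistry:
    """Load a registry from a CSV file (see :data:`REGISTRY_COLUMNS`)."""
    return FeatureRegistry(pd.read_csv(path))


def default_registry() -> FeatureRegistry:
    """The packaged 33-variable default registry."""
    with resources.files("hemodyn.data").joinpath("feature_registry.csv").open() as fh:
        reg = FeatureRegistry(pd.read_csv(fh))
    if len(reg) != 33:
        raise RuntimeError(
            f"default registry must have exactly 33 variables, found {len(reg)}"
        )
    return reg
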