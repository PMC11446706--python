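"""Long-format measurement tables and analysis configuration.

The measurement table is the carrier between the image-level stages and the
statistics layer: one row per (subject, session, muscle, side, metric)
observation. Values are finite or explicitly missing (empty CSV cell).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TABLE_COLUMNS",
    "KEY_COLUMNS",
    "GROUPS",
    "SESSIONS",
    "SIDES",
    "METRICS",
    "validate_table",
    "read_table",
    "write_table",
    "AnalysisConfig",
]

TABLE_COLUMNS = [
    "subject_id", "group", "session", "muscle", "side", "metric", "value",
]
KEY_COLUMNS = TABLE_COLUMNS[:-1]

GROUPS = ("patient", "control")
SESSIONS = ("baseline", "week1", "month9", "month18")
SIDES = ("left", "right")
METRICS = ("stiffness_kPa", "pdff_fraction", "volume_cc")


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check column schema, key uniqueness and value finiteness."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    table = table[TABLE_COLUMNS].copy()
    dup = table.duplicated(subset=KEY_COLUMNS, keep=False)
    if dup.any():
        first = table.loc[dup, KEY_COLUMNS].iloc[0].tolist()
        raise ValueError(f"duplicate measurement key: {first}")
    values = pd.to_numeric(table["value"], errors="coerce")
    bad = values.notna() & ~np.isfinite(values)
    if bad.any():
        raise ValueError("non-finite measurement values present")
    table["value"] = values
    return table


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={c: str for c in KEY_COLUMNS})
    return validate_table(table)


def write_table(table: pd.DataFrame, path) -> None:
    validate_table(table).to_csv(path, index=False)


@dataclasses.dataclass
class AnalysisConfig:
    """Acquisition and analysis constants shared across the pipeline.

    Defaults follow the study protocol this pipeline targets: a 60 Hz
    pneumatic driver, muscle density taken as 1000 kg/m^3 by convention,
    a symmetric 5% trim of per-muscle stiffness-map voxels, and exclusion
    of measured wavelengths above 50 mm as likely artefacts.
    """

    frequency_hz: float = 60.0
    density_kg_m3: float = 1000.0
    trim_fraction: float = 0.05
    max_wavelength_mm: float = 50.0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if self.density_kg_m3 <= 0:
            raise ValueError("density_kg_m3 must be positive")
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.max_wavelength_mm <= 0:
            raise ValueError("max_wavelength_mm must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))
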