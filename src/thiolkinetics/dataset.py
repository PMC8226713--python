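"""Data model and I/O for thiol (SH) storage-study measurements.

A study observes the free-thiol content of minced meat samples — a marker of
protein oxidation — across treatments (a control plus plant-extract
additions), raw and cooked preparations, storage temperatures and storage
times, in replicate. Observations live in a long-format table; analysis is
done on the percent-of-day-0 scale, where every group's day-0 mean is 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    DatasetFormatError,
    DatasetParseError,
    MissingBaselineError,
    GroupNotFoundError,
)

#: Canonical long-format column order; fixed so CSV round trips are bit-exact.
COLUMNS = (
    "treatment",
    "heat_state",
    "temperature_c",
    "time_days",
    "replicate",
    "sh_value",
)

#: The study's treatment vocabulary: an un-supplemented control plus thirteen
#: plant extracts added at 0.5% (m/m).
TREATMENTS = (
    "control",
    "allspice",
    "basil",
    "bay_leaf",
    "black_seed",
    "caraway",
    "cardamom",
    "clove",
    "garlic",
    "nutmeg",
    "onion",
    "oregano",
    "rosemary",
    "thyme",
)

HEAT_STATES = ("raw", "cooked")

#: Grouping key for normalization and per-condition fits.
GROUP_COLUMNS = ("treatment", "heat_state", "temperature_c")

#: Units of the sh_value column.
UNIT_RAW = "raw_units"  # nmol cysteine / mg protein
UNIT_PERCENT = "percent"  # percent of the group's day-0 mean

_NUMERIC_COLUMNS = ("temperature_c", "time_days", "replicate", "sh_value")


def celsius_to_kelvin(temperature_c):
    """Convert °C to K without rounding (T(K) = T(°C) + 273.15)."""
    return np.asarray(temperature_c, dtype=float) + 273.15


@dataclass
class StudyDataset:
    """A collection of SH observations with a unit tag and provenance.

    Parameters
    ----------
    data
        Long-format table with the canonical :data:`COLUMNS`.
    unit
        ``"raw_units"`` (nmol cysteine/mg protein) or ``"percent"``
        (percent of the group day-0 mean).
    metadata
        Free-form provenance: source file, generator seed, config hash.
    """

    data: pd.DataFrame
    unit: str = UNIT_PERCENT
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise DatasetFormatError(f"missing required columns: {missing}")
        if self.unit not in (UNIT_RAW, UNIT_PERCENT):
            raise DatasetFormatError(f"unknown unit tag {self.unit!r}")
        self.data = self.data.loc[:, list(COLUMNS)].reset_index(drop=True)

    def __len__(self):
        return len(self.data)

    @property
    def temperatures_c(self) -> np.ndarray:
        return np.sort(self.data["temperature_c"].unique())

    def group(self, treatment: str, heat_state: str) -> pd.DataFrame:
        """All observations for one (treatment, heat_state) cell."""
        mask = (self.data["treatment"] == treatment) & (
            self.data["heat_state"] == heat_state
        )
        if not mask.any():
            raise GroupNotFoundError(
                f"group ({treatment!r}, {heat_state!r}) not in dataset"
            )
        return self.data.loc[mask]

    def select(
        self,
        treatment: str | None = None,
        heat_state: str | None = None,
        temperatures_c: Iterable[float] | None = None,
    ) -> "StudyDataset":
        """Subset by treatment, heat state and/or temperatures."""
        mask = pd.Series(True, index=self.data.index)
        if treatment is not None:
            mask &= self.data["treatment"] == treatment
        if heat_state is not None:
            mask &= self.data["heat_state"] == heat_state
        if temperatures_c is not None:
            mask &= self.data["temperature_c"].isin(list(temperatures_c))
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))


def read_dataset(path, unit: str = UNIT_PERCENT) -> StudyDataset:
    """Read a long-format storage-study CSV.

    Raises
    ------
    DatasetFormatError
        If a required column is absent.
    DatasetParseError
        If a numeric field does not parse; the message names the CSV rows
        (1-based, counting the header as row 1).
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing required columns {missing}")
    parsed = frame.copy()
    bad_rows: list[int] = []
    for col in _NUMERIC_COLUMNS:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna() & frame[col].notna() | frame[col].isna()
        bad_rows.extend((frame.index[bad] + 2).tolist())
        parsed[col] = values
    if bad_rows:
        rows = sorted(set(bad_rows))
        raise DatasetParseError(f"{path}: non-numeric values in rows {rows}")
    parsed["replicate"] = parsed["replicate"].astype(int)
    return StudyDataset(parsed, unit=unit, metadata={"source": str(path)})


def write_dataset(dataset: StudyDataset, path) -> None:
    """Write a dataset as canonical CSV (full float precision, fixed order)."""
    if len(dataset) == 0:
        raise DatasetFormatError("refusing to write an empty dataset")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dataset.data.loc[:, list(COLUMNS)].to_csv(path, index=False)


def normalize_to_percent(dataset: StudyDataset) -> StudyDataset:
    """Rescale each observation to percent of its group's day-0 mean.

    The baseline is the arithmetic mean of all replicate day-0 values within
    each (treatment, heat_state, temperature) group, so after normalization
    every group's mean at day 0 is exactly 100. Idempotent on data already on
    the percent scale.
    """
    frame = dataset.data.copy()
    baselines = (
        frame.loc[frame["time_days"] == 0]
        .groupby(list(GROUP_COLUMNS))["sh_value"]
        .mean()
    )
    groups = frame.groupby(list(GROUP_COLUMNS)).groups
    missing = [key for key in groups if key not in baselines.index]
    if missing:
        raise MissingBaselineError(
            f"groups without a day-0 observation: {sorted(missing)}"
        )
    keys = pd.MultiIndex.from_frame(frame[list(GROUP_COLUMNS)])
    frame["sh_value"] = 100.0 * frame["sh_value"].to_numpy() / baselines.loc[
        keys
    ].to_numpy()
    meta = dict(dataset.metadata, normalized=True)
    return StudyDataset(frame, unit=UNIT_PERCENT, metadata=meta)
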