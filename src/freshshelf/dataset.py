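"""Tidy storage-trial dataset container.

A storage trial is carried as a tidy table with exactly five columns:
``treatment, time_d, attribute, replicate, value``.  Attribute names come
from a controlled vocabulary with units baked in, which prevents silent
unit mix-ups between percent, Newton and mg/kg scales.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["ATTRIBUTES", "COLUMNS", "StorageDataset"]

#: Controlled attribute vocabulary (units embedded in the names).
ATTRIBUTES = (
    "tbc_log_cfu_g",
    "sensory",
    "weight_loss_pct",
    "firmness_n",
    "l_star",
    "a_star",
    "b_star",
    "ascorbic_mg_kg",
    "tpc_mg_kg",
    "dpph_pct",
)

COLUMNS = ("treatment", "time_d", "attribute", "replicate", "value")


class StorageDataset:
    """Replicate-level storage-trial measurements in tidy form.

    Wraps a validated :class:`pandas.DataFrame` with the five schema
    columns.  Construct via :meth:`from_frame`, :meth:`from_records` or
    :meth:`read_csv`.
    """

    def __init__(self, frame: pd.DataFrame):
        self._frame = frame.reset_index(drop=True)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StorageDataset":
        """Validate ``frame`` against the record schema and wrap it."""
        problems: list[str] = []
        if list(frame.columns) != list(COLUMNS):
            raise SchemaError(
                f"header must be exactly {list(COLUMNS)}, got {list(frame.columns)}"
            )
        out = frame.copy()
        out["treatment"] = out["treatment"].astype(str)
        out["attribute"] = out["attribute"].astype(str)
        for idx, row in out.iterrows():
            rowno = int(idx) + 1
            if row["attribute"] not in ATTRIBUTES:
                problems.append(
                    f"row {rowno}: unknown attribute {row['attribute']!r}; "
                    f"vocabulary: {', '.join(ATTRIBUTES)}"
                )
            try:
                t = float(row["time_d"])
                if not np.isfinite(t) or t < 0:
                    problems.append(f"row {rowno}: time_d must be >= 0, got {row['time_d']}")
            except (TypeError, ValueError):
                problems.append(f"row {rowno}: time_d not numeric: {row['time_d']!r}")
            try:
                rep = float(row["replicate"])
                if rep != int(rep) or rep < 1:
                    problems.append(
                        f"row {rowno}: replicate must be a positive integer, got {row['replicate']}"
                    )
            except (TypeError, ValueError):
                problems.append(f"row {rowno}: replicate not numeric: {row['replicate']!r}")
            try:
                float(row["value"])
            except (TypeError, ValueError):
                problems.append(f"row {rowno}: value not numeric: {row['value']!r}")
        if problems:
            raise SchemaError(f"{len(problems)} malformed row(s)", problems)
        out["time_d"] = out["time_d"].astype(float)
        out["replicate"] = out["replicate"].astype(int)
        out["value"] = out["value"].astype(float)
        dup = out.duplicated(subset=["treatment", "time_d", "attribute", "replicate"])
        if dup.any():
            rows = [str(i + 1) for i in out.index[dup]]
            raise SchemaError(
                "duplicate (treatment, time_d, attribute, replicate) keys",
                [f"row {r}" for r in rows],
            )
        return cls(out)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "StorageDataset":
        frame = pd.DataFrame(list(records), columns=list(COLUMNS))
        return cls.from_frame(frame)

    @classmethod
    def read_csv(cls, path) -> "StorageDataset":
        """Read and validate a tidy CSV file."""
        frame = pd.read_csv(path, float_precision="round_trip")
        return cls.from_frame(frame)

    def write_csv(self, path) -> None:
        self._frame.to_csv(path, index=False)

    # -- access ------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """The underlying tidy DataFrame (a copy)."""
        return self._frame.copy()

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def treatments(self) -> list[str]:
        seen: list[str] = []
        for t in self._frame["treatment"]:
            if t not in seen:
                seen.append(t)
        return seen

    @property
    def attributes(self) -> list[str]:
        present = set(self._frame["attribute"])
        return [a for a in ATTRIBUTES if a in present]

    @property
    def sampling_days(self) -> np.ndarray:
        return np.sort(self._frame["time_d"].unique())

    def means(self) -> pd.DataFrame:
        """Per-(treatment, time, attribute) replicate means, tidy."""
        return (
            self._frame.groupby(["treatment", "time_d", "attribute"], as_index=False)[
                "value"
            ]
            .mean()
            .sort_values(["treatment", "attribute", "time_d"])
            .reset_index(drop=True)
        )

    def trajectory(self, treatment: str, attribute: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, replicate-mean values) for one treatment and attribute."""
        sub = self._frame[
            (self._frame["treatment"] == treatment)
            & (self._frame["attribute"] == attribute)
        ]
        if sub.empty:
            raise KeyError(f"no data for treatment={treatment!r}, attribute={attribute!r}")
        g = sub.groupby("time_d")["value"].mean().sort_index()
        return g.index.to_numpy(dtype=float), g.to_numpy(dtype=float)
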