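"""Cohort contact tables: long-format visit records with projected coordinates.

A contact is one observation of one person at one location type
(residence or day care) at one visit wave.  The table is keyed on
``(person_id, wave, location_type)`` and carries the calendar year of the
visit plus projected planar x/y in the same units as the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ContactTable", "read_contacts", "LOCATION_TYPES"]

LOCATION_TYPES = ("residence", "daycare")

REQUIRED_COLUMNS = ["person_id", "wave", "year", "location_type", "x", "y"]
KEY = ["person_id", "wave", "location_type"]


@dataclass
class ContactTable:
    """Validated long-format cohort contact records.

    Wraps a DataFrame with columns ``person_id, wave, year, location_type,
    x, y`` and optionally ``state``.  ``(person_id, wave, location_type)``
    must be unique, coordinates finite, and ``location_type`` one of
    ``residence``/``daycare``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"contact table missing columns {missing}")
        bad_types = set(df["location_type"].unique()) - set(LOCATION_TYPES)
        if bad_types:
            raise ValueError(
                f"unknown location_type values {sorted(bad_types)}; "
                f"expected one of {LOCATION_TYPES}"
            )
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValueError("non-finite coordinates in contact table")
        dup = df.duplicated(subset=KEY)
        if dup.any():
            first = df.loc[dup, KEY].iloc[0].tolist()
            raise ValueError(f"duplicate contact key {tuple(first)}")
        if "state" not in df.columns:
            df = df.copy()
            df["state"] = pd.NA
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_persons(self) -> int:
        return self.df["person_id"].nunique()

    def residences(self) -> pd.DataFrame:
        return self.df[self.df["location_type"] == "residence"]

    def daycares(self) -> pd.DataFrame:
        return self.df[self.df["location_type"] == "daycare"]

    def to_csv(self, path: str) -> None:
        self.df.to_csv(path, index=False)


def read_contacts(path: str) -> ContactTable:
    """Read and validate a cohort contact CSV.

    The file must have a header row with at least ``person_id, wave, year,
    location_type, x, y``; a ``state`` column is carried through if present.
    """
    df = pd.read_csv(path)
    return ContactTable(df)
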