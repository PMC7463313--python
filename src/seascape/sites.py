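"""Sampling-site tables: locations, settlement radii, CSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_SETTLEMENT_RADIUS_KM = 10.0


@dataclass
class SiteTable:
    """Settlement/sampling sites with coordinates in degrees.

    Columns of ``table``: site_id, name, lon, lat, settlement_radius_km.
    Site ids must be unique; radii strictly positive.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("site_id", "lon", "lat")

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"site table missing required column {col!r}")
        if "name" not in df.columns:
            df["name"] = df["site_id"]
        if "settlement_radius_km" not in df.columns:
            df["settlement_radius_km"] = DEFAULT_SETTLEMENT_RADIUS_KM
        if df["site_id"].duplicated().any():
            dupes = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
            raise ValueError(f"duplicate site ids: {dupes}")
        if (df["settlement_radius_km"] <= 0).any():
            raise ValueError("settlement_radius_km must be > 0")
        self.table = df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------
    @property
    def site_ids(self) -> list[str]:
        return list(self.table["site_id"])

    @property
    def lon(self) -> np.ndarray:
        return self.table["lon"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.table["lat"].to_numpy(dtype=float)

    @property
    def radius_km(self) -> np.ndarray:
        return self.table["settlement_radius_km"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_records(cls, records) -> "SiteTable":
        return cls(pd.DataFrame.from_records(records))

    @classmethod
    def read_csv(cls, path) -> "SiteTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
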