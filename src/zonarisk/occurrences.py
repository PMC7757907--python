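"""Occurrence-record handling: loading, cleaning, deduplication, spatial thinning.

Presence records (e.g. confirmed detections of *Bactrocera zonata*) arrive as
CSV with columns ``id,lon,lat,status,source``. Cleaning removes rows with
unparseable or out-of-range coordinates; deduplication removes exact
coordinate repeats; spatial thinning enforces a minimum great-circle distance
between retained records (10 km by default) to reduce spatial sampling bias.
Every filter appends a reconciliation entry to the set's provenance log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius

REQUIRED_COLUMNS = ["id", "lon", "lat", "status", "source"]
VALID_STATUS = {"native", "invaded"}


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between WGS84 points, vectorized."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class FilterStep:
    """One provenance entry: a named filter and its record accounting."""

    step: str
    n_in: int
    n_kept: int

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_kept


@dataclass
class OccurrenceSet:
    """Ordered presence records plus the provenance of applied filters.

    ``records`` is a DataFrame with columns ``id,lon,lat,status,source``;
    row order is meaningful (thinning is a greedy pass in this order).
    """

    records: pd.DataFrame
    provenance: list[FilterStep] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns: {missing}")
        if self.records["id"].duplicated().any():
            dupes = self.records.loc[self.records["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate occurrence ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lon(self) -> np.ndarray:
        return self.records["lon"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.records["lat"].to_numpy(dtype=float)

    def _derive(self, kept: pd.DataFrame, step: str) -> "OccurrenceSet":
        entry = FilterStep(step=step, n_in=len(self.records), n_kept=len(kept))
        logger.info("%s: %d in, %d kept, %d removed", step, entry.n_in, entry.n_kept, entry.n_removed)
        return OccurrenceSet(records=kept.reset_index(drop=True), provenance=[*self.provenance, entry])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.records.to_csv(path, index=False)
        return path


def load_occurrences(path: str | Path) -> OccurrenceSet:
    """Parse an occurrence CSV, dropping rows with bad coordinates.

    Rows whose lon/lat are unparseable, missing, or outside
    [-180, 180] x [-90, 90] are removed and logged (the pipeline's analogue
    of visually screening records for obvious georeferencing errors).
    Duplicate coordinates are *retained* here; deduplication is explicit.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: no occurrence rows")
    n_in = len(df)
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    ok = (
        df["lon"].notna()
        & df["lat"].notna()
        & df["lon"].between(-180.0, 180.0)
        & df["lat"].between(-90.0, 90.0)
    )
    dropped = df.loc[~ok]
    if len(dropped):
        logger.warning("dropping %d rows with invalid coordinates: ids %s",
                       len(dropped), dropped["id"].tolist()[:10])
    kept = df.loc[ok].reset_index(drop=True)
    step = FilterStep(step="coordinate_filter", n_in=n_in, n_kept=len(kept))
    return OccurrenceSet(records=kept, provenance=[step])


def deduplicate(occ: OccurrenceSet) -> OccurrenceSet:
    """Keep the first record of every exactly identical (lon, lat) pair.

    Near-duplicates (differing by any nonzero amount) are left for spatial
    thinning; no fuzz radius is applied here.
    """
    kept = occ.records.drop_duplicates(subset=["lon", "lat"], keep="first")
    return occ._derive(kept, "deduplicate")


def thin_spatial(occ: OccurrenceSet, min_km: float = 10.0) -> OccurrenceSet:
    """Greedy spatial thinning: enforce a minimum distance between records.

    A single pass in record order keeps a record iff its great-circle
    distance to every previously kept record is >= ``min_km``. The result is
    deterministic given the input order and satisfies the pairwise-distance
    guarantee exactly.
    """
    if min_km <= 0:
        raise ValueError(f"min_km must be positive, got {min_km}")
    lon, lat = occ.lon, occ.lat
    keep_idx: list[int] = []
    for i in range(len(occ)):
        if not keep_idx:
            keep_idx.append(i)
            continue
        d = haversine_km(lon[i], lat[i], lon[keep_idx], lat[keep_idx])
        if np.all(d >= min_km):
            keep_idx.append(i)
    kept = occ.records.iloc[keep_idx]
    return occ._derive(kept, f"thin_spatial_{min_km}km")


def pairwise_min_distance_km(occ: OccurrenceSet) -> float:
    """Smallest great-circle distance over all record pairs (inf if < 2)."""
    n = len(occ)
    if n < 2:
        return float("inf")
    lon, lat = occ.lon, occ.lat
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    iu = np.triu_indices(n, k=1)
    return float(d[iu].min())
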